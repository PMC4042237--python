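"""Check the cleavage rules against the shipped published peptide set.

The package ships the 19 fusion + 4 splicing peptides characterized in a
pooled lung-cancer study together with their reliability classes
(A: fully tryptic, no missed cleavage; B: fully tryptic, one missed
cleavage; C: semi-tryptic). The internal-missed-cleavage predicate must
agree with every printed class.
"""

from juncpep.benchmark import load_characterized_benchmark
from juncpep.insilico_digest import classify_digestion, internal_missed_cleavages

df = load_characterized_benchmark()
print(f"{len(df)} published peptides "
      f"({(df.kind == 'fusion').sum()} fusion, {(df.kind == 'splicing').sum()} splicing)")

agree = 0
for _, row in df.iterrows():
    missed = internal_missed_cleavages(row.sequence)
    if row.digestion_class in ("A", "B"):
        prev, nxt = "K", "A"  # fully tryptic flanking context
    elif row.sequence[-1] in "KR":
        prev, nxt = "A", "A"  # semi-tryptic N-terminus
    else:
        prev, nxt = "K", "A"  # its own C-terminus is non-tryptic
    label = classify_digestion(row.sequence, prev, nxt)
    agree += label == row.digestion_class
    print(f"  {row.digestion_class}/{label} missed={missed} {row.sequence}")

print(f"\nlabels reproduced: {agree}/{len(df)}")
fusion = df[df.kind == "fusion"]
print("class-A fusion peptides with zero internal missed cleavages:",
      sum(internal_missed_cleavages(s) == 0
          for s in fusion[fusion.digestion_class == 'A'].sequence), "/ 12")
print("class-B fusion peptides with exactly one:",
      sum(internal_missed_cleavages(s) == 1
          for s in fusion[fusion.digestion_class == 'B'].sequence), "/ 5")
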