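"""Backtrack an identified junction peptide to the DNA that encodes it.

The junction of two exon sequences is translated, digested, and the
junction-crossing peptide is mapped back to its exact codon span —
the evidence trail from peptide to genomic sequence.
"""

from juncpep.insilico_digest import digest_junction
from juncpep.junction_builder import (
    JunctionNucSeq,
    reconstruct_dna,
    translate_junction,
    translate_nt,
)

junction = JunctionNucSeq(
    upstream_exon_id="ENSE_A", downstream_exon_id="ENSE_B",
    upstream_gene="DONOR", downstream_gene="ACCEPTOR", kind="fusion",
    sequence="ATGGCTGCAAAA" + "GGTGGAGGCTTTTTCGATGATAAG",  # MAAK | GGGFFDDK
    junction_nt=12,
)

for protein in translate_junction(junction):
    print(f"frame {protein.frame}: {protein.aa_sequence} "
          f"(left={protein.junction_left_aa}, right={protein.junction_right_aa}, "
          f"straddle={protein.straddle})")
    for pep in digest_junction(protein):
        dna, (up, down, frame) = reconstruct_dna(pep)
        print(f"  peptide {pep.sequence} <- {dna}")
        print(f"  encoded across {up}|{down} in frame {frame}; "
              f"re-translation: {translate_nt(dna)}")

# The returned span re-translates to the peptide exactly: frames whose
# stop codons fall at or before the junction were already discarded.
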