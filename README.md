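# juncpep

Proteogenomics of gene fusions: build a junction-peptide search database
and identify fusion/splicing peptides from tandem-MS search results.

Gene fusions (e.g. *BCR:ABL*, *EML4:ALK*) can produce proteins containing
a peptide that spans the breakpoint between two genes. Such peptides are
absent from reference proteomes, so ordinary database searches cannot see
them. `juncpep` is for proteomics researchers who want to mine existing
MS/MS datasets for fusion evidence: it enumerates candidate junction
peptides from a curated list of fusion gene pairs (assuming intronic
breakpoints, so junctions are exon-boundary joins), and post-processes the
search results of two engines with very stringent target-decoy control.

## What it computes

**Database construction.** For each gene pair, every exon of one gene is
concatenated to every exon of the other (both orientations; within-gene
exon pairs give splicing candidates), translated in three frames — frames
with a stop at or before the junction are discarded, a downstream stop
truncates — and digested with trypsin (cleave after K/R except before P,
≤ 1 missed cleavage per junction side, length ≥ 6, must cross the
junction). Merged peptides are written as a five-component FASTA:
Fusion, Splicing, Annotated (known proteome), Contaminated, and Reversal
(character-reversed decoys).

**Identification.** Per raw file and engine, PSMs are score-ranked and the
largest prefix with

    FDR(k) = 2·F/(T+F) ≤ 1e-6

is accepted (F = decoy hits, T = target hits among the top k) — at this
threshold the accepted set provably contains no decoy. Accepted peptides
are categorized with the precedence Contaminated/Annotated > Splicing >
Fusion, must span their junction with ≥ 3 residues on each side, and are
reported only when both engines identified them through at least one
common spectrum, or when an input table flags them as conserved in
another species. Reported peptides carry a reliability class
(A: fully tryptic / no missed cleavage, B: one missed cleavage,
C: semi-tryptic) and per-sample-group spectrum counts with an
exclusivity label (SCC/ADC/Normal).

See `docs/methods.md` for the full model and its assumptions.

## Worked example

`examples/02_postprocess_search_results.py` simulates a small study
(8 genes, 3 planted fusion + 1 planted splicing peptide, two mock
engines) and runs the full pipeline:

```text
planted ground truth:
  fusion   QAQRCTPPGPR  (GENE07>GENE04)
  fusion   LLVVSSPMAR  (GENE08>GENE06)
  fusion   HPLATLEDSCLPFSFDCRYCHYGFILSLR  (GENE05>GENE04)
  splicing GNPHLVALHSLIMHPGPRHR  (GENE04>GENE04)

reported peptides (spectrum counts per sample group):
                     sequence category         genes digestion_class  SCC  ADC  Normal exclusivity
HPLATLEDSCLPFSFDCRYCHYGFILSLR   Fusion GENE05:GENE04               B    0    0       4 Normal_only
                   LLVVSSPMAR   Fusion GENE08:GENE06               A    0    4       0    ADC_only
                  QAQRCTPPGPR   Fusion GENE07:GENE04               B    4    0       0    SCC_only
         GNPHLVALHSLIMHPGPRHR Splicing GENE04:GENE04               B    4    0       0    SCC_only

decoy PSMs surviving FDR control: 0
```

The reported set equals the planted truth: each row shows the peptide's
category, its reliability class, and which sample groups its accepted
spectra came from. The other examples build a database by hand
(`01_…`), backtrack an identified peptide to the DNA encoding it
(`03_…`), and check the cleavage rules against the shipped set of 23
published lung-cancer fusion/splicing peptides (`04_…`).

The same workflow is available from the shell:

```bash
juncpep simulate --seed 3 --out-dir fixtures/
juncpep build-db --exons fixtures/exons.tsv --exon-fasta fixtures/exons.fa \
    --pairs fixtures/pairs.tsv --proteome fixtures/proteome.fa \
    --contaminants fixtures/contaminants.fa --out db.fa
juncpep postprocess --db db.fa --psms-a fixtures/psms_xtandem.tsv \
    --psms-b fixtures/psms_omssa.tsv --groups fixtures/groups.tsv \
    --conservation fixtures/conservation.tsv --out characterized.tsv
```

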