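# Methods

## The problem

A standard MS/MS database search can only identify peptides that exist in
the searched FASTA. Peptides created by gene fusion (an exon of one gene
spliced onto an exon of another after a structural rearrangement) or by
unannotated alternative splicing are absent from reference proteomes, so
they are invisible unless the search database is extended with candidate
junction sequences. Enumerating every possible breakpoint is intractable;
`juncpep` restricts the space to a curated list of fusion gene pairs and
assumes breakpoints fall in introns, so that the expressed junction is
always an exon boundary join. Under that assumption a junction candidate
is fully determined by an ordered exon pair.

## Database construction

For each gene pair (A, B) every exon of A is concatenated to every exon
of B and vice versa (2·|A|·|B| junction sequences per pair); for each
paired gene, every within-gene exon pair (i, j) with rank(i) < rank(j)
is concatenated (C(n, 2) per gene). Exon sequences are stored in coding
orientation, so three reading frames suffice.

Each junction sequence is translated in frames 0/1/2 with the standard
genetic code. A frame is discarded if a stop codon lies at or before the
junction codon (including a stop in a codon straddling the junction);
a stop strictly downstream truncates the protein there, modelling
fusions that truncate translation. A retained frame must encode at least
one residue entirely from the downstream exon. Codons containing N
translate to X, which never matches a stop.

Retained junction proteins are digested in silico with trypsin (cleave
after K/R except before P). A peptide enters the database if it is
bounded by cleavage sites or protein termini, contains at least one
residue encoded purely by each side of the junction, carries at most one
missed cleavage on each side of the junction, and is at least 6 residues
long. A residue whose codon straddles the junction counts to neither
side; an uncut site at that residue is attributed to the upstream side.
The stricter requirement of ≥ 3 residues per side is applied at
identification time, not at build time, so that semi-tryptic matches to
sub-sequences remain findable.

Identical junction peptides are merged into one entry per component
(fusion and splicing copies of the same sequence are both kept — the
conflict is resolved at identification). The database has five
components: **Fusion**, **Splicing**, **Annotated** (the known proteome,
stored as whole proteins), **Contaminated** (contaminant proteins) and
**Reversal** — one character-reversed decoy per forward entry, used for
FDR control. FASTA headers record the junction position, genes, exons,
frame and merged-provenance count, so identifications can be traced back
to DNA (`reconstruct_dna` returns the exact codon span encoding any
junction peptide).

## Identification

Per-engine PSM tables are processed per raw file. PSMs are ranked by
score (hyperscore descending for X!Tandem-like engines, e-value
ascending for OMSSA-like ones; decoys after targets on exact ties) and
the accepted set is the largest prefix with

    FDR(k) = 2·F / (T + F) ≤ α,      α = 1e-6 by default,

where F and T are cumulative decoy and target counts at rank k. The
factor 2 reflects that a decoy hit estimates one matching false target
hit. At α = 1e-6 a single decoy at rank k forces FDR ≥ 2/k, which
exceeds α for any k below two million; the accepted set therefore
provably contains no decoy at realistic per-file spectrum counts. This
is deliberate: the search space inflation caused by millions of
hypothetical junction sequences makes conventional 1% FDR unsafe.

Accepted peptides are categorized by substring membership with
precedence **Contaminated/Annotated > Splicing > Fusion**: a peptide
explainable by a known protein is never reported as a discovery, and a
peptide formable both by fusion of two homologous genes and by splicing
within one gene is reported as the more parsimonious splicing event.
Fusion/Splicing membership additionally requires the match to span the
entry's junction; reported peptides must cover ≥ `min_side_aa`
(default 3) residues on each pure side.

A candidate is retained only with corroborating evidence: identified by
both engines *and* sharing at least one (raw file, spectrum id) — two
engines agreeing on a sequence via entirely different spectra is treated
as coincidence and ruled out — or flagged conserved in another species
(an input table standing for a cross-species homology search; in
practice this rescue fires for splicing peptides, since fusion junctions
are not expected to be conserved). Each reported peptide is graded
A (fully tryptic, no internal missed cleavage), B (fully tryptic, one
missed cleavage) or C (semi-tryptic) from its flanking residues in the
matched entry, and its accepted spectra are counted per sample group
(SCC/ADC/Normal) to yield an exclusivity label (`SCC_only`, …, `mixed`).

A fully tryptic peptide with two or more internal missed cleavages falls
outside the A/B/C taxonomy; it is mapped to C as the least-reliable
bucket so classification is total (such peptides can arise because the
build allows one missed cleavage per junction side).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_len` | 6 aa | minimum junction-peptide length at build time |
| `max_misc_per_side` | 1 | missed cleavages allowed per junction side |
| `fdr_alpha` | 1e-6 | per-raw-file target-decoy threshold on 2F/(T+F) |
| `min_side_aa` | 3 aa | pure residues required on each side at identification |
| `require_shared_spectrum` | true | both-engine retention needs a common spectrum |

## The synthetic-data generator

`synth_fixtures` fabricates the complete study: genes whose coding
sequences are drawn codon-wise from the 61 non-stop codons (so every
frame-0 gene translation is an open reading frame), a proteome holding
each gene's translation plus unrelated proteins, planted fusion and
splicing peptides, and two mock engines' PSM tables. Planting runs the
*real* enumeration/translation/digestion machinery and keeps a candidate
only if it passes every build- and identification-time filter, is absent
from the proteome and contaminants, and — verified against the fully
built database — categorizes to its own kind. Scores are drawn from
well-separated distributions (true hyperscore N(75, 6) vs noise
N(22, 6); true e-value 10^U(−12,−7) vs noise 10^U(−3,0)); one engine is
higher-better and one lower-better to exercise both sort directions.
Noise spectra hit random annotated peptides or, at `decoy_hit_rate`,
reversal decoys; a handful of strong annotated hits exercise the
precedence exclusion. Default study sizes (8 genes, 2–4 exons of
30–90 nt, 3 fusion + 1 splicing truths, 30 noise spectra per group) keep
a full run under a second while every pipeline branch stays populated.

What the generator does **not** emulate: physical spectra (scores are
abstract, no m/z, retention time or mass accuracy), score correlation
between engines beyond the planted structure, homologous sequence
families, shared exons between paired genes, or incorrect-but-plausible
near-miss peptides. Passing recovery tests therefore demonstrates the
correctness of the bookkeeping, filtering and integration logic — not
search-engine-level discrimination on real spectra.

`benchmark.py` ships the published set of 19 fusion + 4 splicing
peptides from a pooled lung-tumour study (20 SCC, 20 ADC, 39 normal
samples; two engines) with their reliability classes, and a simulation
scenario whose planted evidence structure mirrors that study's
bookkeeping: 25 fusion and 5 splicing both-engine candidates, one
conservation-rescued splicing candidate, 6 + 2 candidates excluded for
disjoint spectra, and group profiles consistent with the published
8 SCC-only / 2 ADC-only / 3 Normal-only peptides and 11 fusion events
absent from normal tissue. The per-peptide group assignment behind those
aggregates is not public; the shipped profile is one concrete assignment
consistent with every published aggregate, chosen once.

## Numerical and design choices

- Gene pairs are unordered; both fusion orientations are enumerated
  downstream. Self-pairs are rejected. Exons are the union over
  transcripts, deduplicated by coordinates, ordered by coding-strand rank.
- Splicing enumeration includes rank-adjacent exon pairs; those
  reproduce annotated junctions and are absorbed by Annotated precedence.
  Database-build splicing covers genes referenced by at least one pair.
- Acceptance is largest-passing-prefix, not stop-at-first-failure,
  matching standard target-decoy practice; with the factor-2 estimator
  FDR(k) is not monotone in k, and the prefix rule makes the accepted
  set monotone in α.
- Ties are broken deterministically everywhere (decoys after targets;
  entries ordered by component then id; matches by entry id then offset),
  so rebuilding a database or rerunning a simulation is byte-identical.
- Degenerate inputs: single-exon genes yield no splicing junctions;
  junction sequences shorter than one codon per side can lose all
  frames; empty components are written as valid empty FASTA sections.

## Limitations

- Breakpoints inside exons (which would shift frames per-breakpoint) are
  out of scope by design, as is any frame-compatibility reasoning beyond
  the three-frame scan.
- Search engines are external; the package only documents the
  recommended ±10 Da parent-mass window in a shipped X!Tandem input
  template and parses engine outputs.
- Conservation evidence is consumed as a table, not computed; no
  BLAST-style homology search is performed.
- No peptide masses, modifications, protein-level inference or spectrum
  handling.
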