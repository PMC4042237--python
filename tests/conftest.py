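"""Shared fixtures: hand-built toy genes and a session-scoped simulated study."""

from __future__ import annotations

import pytest

from juncpep.annotation_io import ExonRecord, GeneModel
from juncpep.junction_builder import CODON_AA
from juncpep.synth_fixtures import SimulationConfig, generate_dataset

# one fixed codon per amino acid (alphabetically first) for encoding test peptides
CODON_OF: dict[str, str] = {}
for codon in sorted(CODON_AA):
    CODON_OF.setdefault(CODON_AA[codon], codon)


def encode(aa_seq: str) -> str:
    """Deterministic nucleotide encoding of an amino-acid string."""
    return "".join(CODON_OF[aa] for aa in aa_seq)


def make_exon(
    exon_id: str,
    sequence: str,
    rank: int = 1,
    gene_id: str = "g1",
    symbol: str = "GENEA",
    strand: str = "+",
    start: int = 1000,
) -> ExonRecord:
    return ExonRecord(
        exon_id=exon_id,
        gene_id=gene_id,
        gene_symbol=symbol,
        chrom="chr1",
        strand=strand,
        start=start,
        end=start + len(sequence) - 1,
        rank=rank,
        sequence=sequence,
    )


def make_gene(symbol: str, exon_seqs: list[str], gene_id: str | None = None) -> GeneModel:
    gene_id = gene_id or symbol.lower()
    pos = 1000
    exons = []
    for i, seq in enumerate(exon_seqs, start=1):
        exons.append(
            make_exon(
                f"{gene_id}e{i}",
                seq,
                rank=i,
                gene_id=gene_id,
                symbol=symbol,
                start=pos,
            )
        )
        pos += len(seq) + 100
    return GeneModel(gene_id=gene_id, gene_symbol=symbol, strand="+", exons=tuple(exons))


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated study reused across read-only tests."""
    return generate_dataset(SimulationConfig(seed=7))
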