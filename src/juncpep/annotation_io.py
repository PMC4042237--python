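"""Reading and validating exon annotations, exon sequences and gene-pair lists.

The annotation contract mirrors a BioMart-style export: a TSV of exon
coordinates plus a FASTA of exon nucleotide sequences keyed by exon id.
Sequences are stored in coding (5'->3' sense) orientation, so downstream
junction construction never needs reverse-complement logic; the ``rank``
column gives the ordinal position of each exon along the coding strand.

Gene pairs are unordered: ``(A, B)`` and ``(B, A)`` rows collapse to one
pair with their provenance tags unioned. Rows naming unknown symbols or
pairing a gene with itself are dropped and counted in a rejection report.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ExonRecord",
    "GeneModel",
    "GenePair",
    "RejectionReport",
    "AnnotationError",
    "read_exon_table",
    "attach_sequences",
    "read_gene_pairs",
    "write_gene_models",
    "write_gene_pairs",
    "read_protein_fasta",
    "EXON_COLUMNS",
]

EXON_COLUMNS = [
    "exon_id",
    "gene_id",
    "gene_symbol",
    "chrom",
    "strand",
    "start",
    "end",
    "rank",
]

_NUC_ALPHABET = set("ACGTN")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class ExonRecord:
    """One annotated exon; ``sequence`` (coding orientation) may be attached later."""

    exon_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    rank: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"exon {self.exon_id}: unknown strand symbol {self.strand!r}"
            )
        if self.end < self.start:
            raise AnnotationError(
                f"exon {self.exon_id}: end ({self.end}) < start ({self.start})"
            )
        if self.sequence is not None:
            if len(self.sequence) != self.span:
                raise AnnotationError(
                    f"exon {self.exon_id}: sequence length {len(self.sequence)} "
                    f"!= coordinate span {self.span}"
                )
            bad = set(self.sequence) - _NUC_ALPHABET
            if bad:
                raise AnnotationError(
                    f"exon {self.exon_id}: non-ACGTN characters {sorted(bad)}"
                )

    @property
    def span(self) -> int:
        """Genomic span in nucleotides (coordinates are 1-based inclusive)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon list of one gene; exons deduplicated by coordinates."""

    gene_id: str
    gene_symbol: str
    strand: str
    exons: tuple[ExonRecord, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        for ex in self.exons:
            if ex.gene_id != self.gene_id or ex.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon {ex.exon_id} has inconsistent "
                    "gene_id or strand"
                )
        ranks = [ex.rank for ex in self.exons]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise AnnotationError(
                f"gene {self.gene_id}: exon ranks not strictly increasing: {ranks}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def coding_sequence(self) -> str:
        """Concatenation of exon sequences in rank order (the mRNA sense CDS)."""
        if any(ex.sequence is None for ex in self.exons):
            raise AnnotationError(f"gene {self.gene_id}: exon sequences not attached")
        return "".join(ex.sequence for ex in self.exons)  # type: ignore[misc]


@dataclass(frozen=True)
class GenePair:
    """Unordered pair of gene symbols with provenance tags.

    Symbols are stored in lexicographic order so that ``pair(A, B)`` and
    ``pair(B, A)`` compare equal; both fusion orientations are enumerated
    downstream regardless of storage order.
    """

    symbol_a: str
    symbol_b: str
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.symbol_a == self.symbol_b:
            raise AnnotationError(f"self-pair not allowed: {self.symbol_a}")
        if self.symbol_a > self.symbol_b:
            a, b = self.symbol_a, self.symbol_b
            object.__setattr__(self, "symbol_a", b)
            object.__setattr__(self, "symbol_b", a)
        if not isinstance(self.sources, frozenset):
            object.__setattr__(self, "sources", frozenset(self.sources))

    @staticmethod
    def make(symbol_a: str, symbol_b: str, sources: Iterable[str] = ()) -> "GenePair":
        a, b = sorted((symbol_a, symbol_b))
        return GenePair(a, b, frozenset(sources))

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.symbol_a, self.symbol_b))


@dataclass
class RejectionReport:
    """Counts of gene-pair rows dropped or merged during normalization."""

    counts: collections.Counter = field(default_factory=collections.Counter)
    rows: list[tuple[int, str, str]] = field(default_factory=list)

    def add(self, reason: str, row_index: int, detail: str = "") -> None:
        self.counts[reason] += 1
        self.rows.append((row_index, reason, detail))

    @property
    def n_rejected(self) -> int:
        return sum(
            n for reason, n in self.counts.items() if reason != "duplicate_merged"
        )


def read_exon_table(path: str | Path) -> list[ExonRecord]:
    """Parse an exon-annotation TSV into validated :class:`ExonRecord` rows.

    Verbatim duplicate rows collapse to one record. Raises
    :class:`AnnotationError` for missing columns, bad coordinates or bad
    strand symbols (naming the offending row).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in EXON_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing required column(s) {missing}")
    df = df.drop_duplicates()
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ExonRecord(
                    exon_id=row["exon_id"],
                    gene_id=row["gene_id"],
                    gene_symbol=row["gene_symbol"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    rank=int(row["rank"]),
                )
            )
        except (AnnotationError, ValueError) as exc:
            raise AnnotationError(f"{path}: row {idx}: {exc}") from exc
    seen: dict[str, ExonRecord] = {}
    for rec in records:
        if rec.exon_id in seen and seen[rec.exon_id] != rec:
            raise AnnotationError(
                f"{path}: exon_id {rec.exon_id} occurs with conflicting fields"
            )
        seen[rec.exon_id] = rec
    return list(seen.values())


def attach_sequences(
    exons: list[ExonRecord], fasta: str | Path
) -> list[GeneModel]:
    """Attach FASTA sequences (keyed by exon id) and group exons into genes.

    Exons are deduplicated by (start, end) within a gene — the union over
    transcripts — and ordered by rank. A missing FASTA entry or a length
    mismatch against the coordinates raises :class:`AnnotationError`.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    by_gene: dict[str, list[ExonRecord]] = collections.defaultdict(list)
    for ex in exons:
        if ex.exon_id not in seqs:
            raise AnnotationError(f"exon {ex.exon_id}: no sequence in {fasta}")
        by_gene[ex.gene_id].append(replace(ex, sequence=seqs[ex.exon_id]))

    models = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        dedup: dict[tuple[int, int], ExonRecord] = {}
        for ex in sorted(group, key=lambda e: (e.rank, e.start, e.exon_id)):
            dedup.setdefault((ex.start, ex.end), ex)
        ordered = sorted(dedup.values(), key=lambda e: e.rank)
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_symbol=ordered[0].gene_symbol,
                strand=ordered[0].strand,
                exons=tuple(ordered),
            )
        )
    return models


def read_gene_pairs(
    path: str | Path, models: Mapping[str, GeneModel]
) -> tuple[list[GenePair], RejectionReport]:
    """Read a two-column (plus optional ``source``) gene-pair TSV.

    Keeps pairs whose two symbols both resolve in ``models``; merges
    unordered duplicates (unioning sources); drops self-pairs and pairs
    with unknown symbols, counting each dropped row in the report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("symbol_a", "symbol_b"):
        if col not in df.columns:
            raise AnnotationError(f"{path}: missing required column {col!r}")
    has_source = "source" in df.columns

    report = RejectionReport()
    merged: dict[frozenset[str], set[str]] = {}
    order: list[frozenset[str]] = []
    for idx, row in df.iterrows():
        a, b = row["symbol_a"], row["symbol_b"]
        src = {row["source"]} if has_source and pd.notna(row.get("source")) else set()
        if a == b:
            report.add("self_pair", idx, a)
            continue
        unknown = [s for s in (a, b) if s not in models]
        if unknown:
            report.add("unknown_symbol", idx, ",".join(unknown))
            continue
        key = frozenset((a, b))
        if key in merged:
            report.add("duplicate_merged", idx, f"{a}-{b}")
            merged[key] |= src
        else:
            merged[key] = set(src)
            order.append(key)
    pairs = [GenePair.make(*sorted(key), merged[key]) for key in order]
    return pairs, report


def write_gene_models(
    models: Iterable[GeneModel], tsv_path: str | Path, fasta_path: str | Path
) -> None:
    """Write gene models back to the TSV + FASTA pair (round-trip inverse)."""
    rows = []
    fasta_records = []
    for gm in models:
        for ex in gm.exons:
            rows.append(
                {
                    "exon_id": ex.exon_id,
                    "gene_id": ex.gene_id,
                    "gene_symbol": ex.gene_symbol,
                    "chrom": ex.chrom,
                    "strand": ex.strand,
                    "start": ex.start,
                    "end": ex.end,
                    "rank": ex.rank,
                }
            )
            if ex.sequence is not None:
                fasta_records.append(
                    SeqRecord(Seq(ex.sequence), id=ex.exon_id, description="")
                )
    pd.DataFrame(rows, columns=EXON_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    SeqIO.write(fasta_records, str(fasta_path), "fasta")


def write_gene_pairs(pairs: Iterable[GenePair], path: str | Path) -> None:
    """Write normalized pairs; one row per pair, sources joined with ';'."""
    rows = [
        {
            "symbol_a": p.symbol_a,
            "symbol_b": p.symbol_b,
            "source": ";".join(sorted(p.sources)),
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=["symbol_a", "symbol_b", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA (proteome or contaminants) into an id->sequence map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise AnnotationError(f"{path}: duplicate protein id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out
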