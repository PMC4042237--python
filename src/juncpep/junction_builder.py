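"""Exon-exon junction enumeration, three-frame translation, DNA backtracking.

A junction sequence is the plain concatenation of two exon sequences held
in coding orientation: fusion junctions join exons of the two genes of a
pair (both upstream/downstream orientations), splicing junctions join two
exons of one gene in coding-strand order. Because exon sequences are
already sense-oriented, three reading frames suffice — no six-frame scan.

Translation keeps a frame only if it is stop-free up to and including the
codon at the junction; a stop strictly downstream truncates the protein
(some fusions truncate translation), and a frame whose first downstream
codon is a stop is discarded because it encodes nothing of the partner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from Bio.Data import CodonTable

from .annotation_io import GeneModel, GenePair

if TYPE_CHECKING:  # pragma: no cover
    from .insilico_digest import PeptideRecord

__all__ = [
    "JunctionNucSeq",
    "JunctionProtein",
    "make_junction",
    "enumerate_fusion_junctions",
    "enumerate_splicing_junctions",
    "translate_junction",
    "reconstruct_dna",
    "translate_nt",
    "CODON_AA",
]


def _codon_map() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
    m = dict(table.forward_table)
    for stop in table.stop_codons:
        m[stop] = "*"
    return m


#: codon -> amino acid for the standard code; stops map to '*'. Codons with
#: N (or any symbol outside the map) translate to 'X' and never match a stop.
CODON_AA: Mapping[str, str] = _codon_map()

_NUC = set("ACGTN")


@dataclass(frozen=True)
class JunctionNucSeq:
    """Concatenated two-exon nucleotide sequence with the junction offset.

    ``junction_nt`` counts nucleotides contributed by the upstream exon;
    the junction lies between 0-based positions ``junction_nt - 1`` and
    ``junction_nt``.
    """

    upstream_exon_id: str
    downstream_exon_id: str
    upstream_gene: str
    downstream_gene: str
    kind: str  # "fusion" | "splicing"
    sequence: str
    junction_nt: int

    def __post_init__(self) -> None:
        if self.kind not in ("fusion", "splicing"):
            raise ValueError(f"unknown junction kind {self.kind!r}")
        if not 0 < self.junction_nt < len(self.sequence):
            raise ValueError(
                f"junction_nt {self.junction_nt} outside sequence of length "
                f"{len(self.sequence)}"
            )
        if self.kind == "splicing" and self.upstream_gene != self.downstream_gene:
            raise ValueError("splicing junction must stay within one gene")


@dataclass(frozen=True)
class JunctionProtein:
    """A retained frame of a junction sequence.

    ``junction_left_aa`` / ``junction_right_aa`` count residues encoded
    entirely by upstream / downstream nucleotides; a codon straddling the
    junction contributes one residue counted to neither side
    (``straddle``). The sequence never contains a stop symbol.
    """

    source: JunctionNucSeq
    frame: int
    aa_sequence: str
    junction_left_aa: int
    junction_right_aa: int
    straddle: bool


def make_junction(
    up_exon, down_exon, *, kind: str, up_gene: str, down_gene: str
) -> JunctionNucSeq:
    """Concatenate two sequence-bearing exons into a junction sequence."""
    if up_exon.sequence is None or down_exon.sequence is None:
        raise ValueError("exon sequences must be attached before joining")
    return JunctionNucSeq(
        upstream_exon_id=up_exon.exon_id,
        downstream_exon_id=down_exon.exon_id,
        upstream_gene=up_gene,
        downstream_gene=down_gene,
        kind=kind,
        sequence=up_exon.sequence + down_exon.sequence,
        junction_nt=len(up_exon.sequence),
    )


def enumerate_fusion_junctions(
    pair: GenePair, models: Mapping[str, GeneModel]
) -> list[JunctionNucSeq]:
    """All exon-by-exon joins of a gene pair, in both orientations.

    Returns ``2 * |exons_A| * |exons_B|`` junction sequences. Raises
    ``KeyError`` when a symbol does not resolve in ``models``.
    """
    for sym in (pair.symbol_a, pair.symbol_b):
        if sym not in models:
            raise KeyError(f"gene symbol {sym!r} not found in annotation")
    ga, gb = models[pair.symbol_a], models[pair.symbol_b]
    out = []
    for up_gene, down_gene in ((ga, gb), (gb, ga)):
        for up_ex in up_gene.exons:
            for down_ex in down_gene.exons:
                out.append(
                    make_junction(
                        up_ex,
                        down_ex,
                        kind="fusion",
                        up_gene=up_gene.gene_symbol,
                        down_gene=down_gene.gene_symbol,
                    )
                )
    return out


def enumerate_splicing_junctions(model: GeneModel) -> list[JunctionNucSeq]:
    """Within-gene exon joins (i, j) with rank(i) < rank(j); C(n, 2) pairs.

    Rank-adjacent joins are included — they reproduce annotated junctions
    and are absorbed later by the Annotated-precedence rule. Single-exon
    genes yield an empty list.
    """
    out = []
    for i, up_ex in enumerate(model.exons):
        for down_ex in model.exons[i + 1 :]:
            out.append(
                make_junction(
                    up_ex,
                    down_ex,
                    kind="splicing",
                    up_gene=model.gene_symbol,
                    down_gene=model.gene_symbol,
                )
            )
    return out


def translate_nt(seq: str) -> str:
    """Frame-0 translation of a sense nucleotide string, stops as '*'."""
    return "".join(
        CODON_AA.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def translate_junction(jn: JunctionNucSeq) -> list[JunctionProtein]:
    """Translate a junction sequence in frames 0/1/2 under the stop rules.

    A frame dies if any stop codon ends at or before the junction or sits
    in the straddling codon; a stop strictly downstream truncates (stop
    excluded). Frames with no retained pure-downstream residue are
    discarded. Returns 0-3 proteins.
    """
    seq = jn.sequence.upper()
    bad = set(seq) - _NUC
    if bad:
        raise ValueError(f"junction sequence contains non-ACGTN: {sorted(bad)}")

    proteins = []
    for frame in (0, 1, 2):
        n_codons = (len(seq) - frame) // 3
        residues: list[str] = []
        left = right = 0
        straddle = False
        killed = False
        for c in range(n_codons):
            s = frame + 3 * c
            aa = CODON_AA.get(seq[s : s + 3], "X")
            if s + 3 <= jn.junction_nt:
                side = "up"
            elif s >= jn.junction_nt:
                side = "down"
            else:
                side = "straddle"
            if aa == "*":
                if side == "down":
                    break  # truncation at first downstream stop
                killed = True  # stop at/before the junction codon
                break
            residues.append(aa)
            if side == "up":
                left += 1
            elif side == "down":
                right += 1
            else:
                straddle = True
        if killed or right == 0:
            continue
        proteins.append(
            JunctionProtein(
                source=jn,
                frame=frame,
                aa_sequence="".join(residues),
                junction_left_aa=left,
                junction_right_aa=right,
                straddle=straddle,
            )
        )
    return proteins


def reconstruct_dna(pep: "PeptideRecord") -> tuple[str, tuple[str, str, int]]:
    """Backtrack a junction peptide to the exact codon span encoding it.

    Returns ``(dna, (upstream_exon_id, downstream_exon_id, frame))`` where
    frame-0 translation of ``dna`` reproduces ``pep.sequence``. Requires
    the peptide's provenance to reference its source junction protein.
    """
    if not pep.provenance:
        raise ValueError("peptide has no provenance; cannot backtrack")
    prov = pep.provenance[0]
    jp = prov.protein
    if jp is None:
        raise ValueError("provenance lacks the source junction protein")
    start, length = prov.start_res, len(pep.sequence)
    if start < 0 or start + length > len(jp.aa_sequence):
        raise ValueError(
            f"residue span [{start}, {start + length}) outside translated "
            f"region of length {len(jp.aa_sequence)}"
        )
    if jp.aa_sequence[start : start + length] != pep.sequence:
        raise ValueError("provenance span does not encode the peptide sequence")
    nt0 = jp.frame + 3 * start
    dna = jp.source.sequence[nt0 : nt0 + 3 * length]
    return dna, (
        jp.source.upstream_exon_id,
        jp.source.downstream_exon_id,
        jp.frame,
    )
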