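"""In-silico trypsin digestion and digestion-class (A/B/C) assignment.

Trypsin cuts after K or R except when the next residue is proline. For
junction proteins the digest keeps only peptides that cross the junction
(at least one residue encoded purely by each side), allowing at most one
missed cleavage on each side of the junction and a minimum total length
(default 6). Identified peptides are later graded by reliability:

  A  both termini tryptic, no internal missed cleavage (most reliable)
  B  both termini tryptic, exactly one internal missed cleavage
  C  semi-tryptic (one terminus not generated by trypsin)

A fully-tryptic peptide with two or more internal missed cleavages falls
outside this taxonomy and is mapped to C, the least-reliable bucket.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .junction_builder import JunctionProtein

__all__ = [
    "PeptideProvenance",
    "PeptideRecord",
    "cleavage_sites",
    "internal_missed_cleavages",
    "digest_junction",
    "digest_annotated",
    "classify_digestion",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class PeptideProvenance:
    """Where a junction peptide came from: genes, exons, frame, start residue."""

    gene_up: str
    gene_down: str
    exon_up: str
    exon_down: str
    frame: int
    start_res: int
    protein: JunctionProtein | None = None


@dataclass(frozen=True)
class PeptideRecord:
    """A junction-crossing tryptic peptide with per-side bookkeeping.

    ``left_aa`` / ``right_aa`` count residues of the peptide encoded
    entirely upstream / downstream of the junction; a straddling residue
    (codon spanning the junction) counts to neither side. ``misc_left`` /
    ``misc_right`` count missed cleavages on each side of the junction,
    with a cleavage site at the straddling residue attributed to the left.
    """

    sequence: str
    kind: str  # "fusion" | "splicing" | "annotated"
    left_aa: int
    right_aa: int
    straddle_in_peptide: bool
    misc_left: int
    misc_right: int
    provenance: tuple[PeptideProvenance, ...] = ()


def cleavage_sites(seq: str) -> list[int]:
    """0-based positions i such that trypsin cleaves after residue i.

    ``i`` is a site iff ``seq[i]`` is K or R and it is the last residue or
    not followed by P.
    """
    if not seq:
        raise ValueError("empty sequence")
    last = len(seq) - 1
    return [
        i
        for i, aa in enumerate(seq)
        if aa in "KR" and (i == last or seq[i + 1] != "P")
    ]


def internal_missed_cleavages(seq: str) -> int:
    """Number of uncut tryptic sites strictly inside the peptide."""
    last = len(seq) - 1
    return sum(1 for i in cleavage_sites(seq) if i != last)


def _cut_points(seq: str) -> list[int]:
    """Sorted cut positions (between-residue indices) incl. both termini."""
    pts = [0] + [i + 1 for i in cleavage_sites(seq) if i + 1 < len(seq)] + [len(seq)]
    return pts


def digest_junction(
    jp: JunctionProtein, max_misc_per_side: int = 1, min_len: int = 6
) -> list[PeptideRecord]:
    """Fully-tryptic junction-crossing peptides of a junction protein.

    Keeps peptides bounded by cleavage sites or protein termini that
    (i) contain at least one pure-upstream and one pure-downstream
    residue, (ii) have at most ``max_misc_per_side`` missed cleavages on
    each side of the junction, and (iii) have length >= ``min_len``.
    """
    seq = jp.aa_sequence
    if not seq:
        return []
    left = jp.junction_left_aa
    straddle = jp.straddle
    # residue index of the first pure-downstream residue
    down0 = left + (1 if straddle else 0)
    cuts = _cut_points(seq)
    inner = cuts[1:-1]

    out = []
    for ai, a in enumerate(cuts[:-1]):
        for b in cuts[ai + 1 :]:
            if b - a < min_len:
                continue
            n_up = max(0, min(b, left) - a)
            n_down = max(0, b - max(a, down0))
            if n_up < 1 or n_down < 1:
                continue
            misc_l = misc_r = 0
            for c in inner:
                if a < c < b:
                    r = c - 1  # residue carrying the uncut site
                    if r < left or (straddle and r == left):
                        misc_l += 1
                    else:
                        misc_r += 1
            if misc_l > max_misc_per_side or misc_r > max_misc_per_side:
                continue
            out.append(
                PeptideRecord(
                    sequence=seq[a:b],
                    kind=jp.source.kind,
                    left_aa=n_up,
                    right_aa=n_down,
                    straddle_in_peptide=straddle and a <= left < b,
                    misc_left=misc_l,
                    misc_right=misc_r,
                    provenance=(
                        PeptideProvenance(
                            gene_up=jp.source.upstream_gene,
                            gene_down=jp.source.downstream_gene,
                            exon_up=jp.source.upstream_exon_id,
                            exon_down=jp.source.downstream_exon_id,
                            frame=jp.frame,
                            start_res=a,
                            protein=jp,
                        ),
                    ),
                )
            )
    return out


def digest_annotated(protein: str, max_misc: int = 1) -> list[str]:
    """All fully-tryptic peptides of a protein with <= ``max_misc`` missed cleavages.

    Supports membership checks against the Annotated component; no length
    floor is applied. Duplicate sequences are returned once, in order of
    first occurrence.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    cuts = _cut_points(protein)
    seen: dict[str, None] = {}
    for ai, a in enumerate(cuts[:-1]):
        for nb, b in enumerate(cuts[ai + 1 :]):
            if nb > max_misc:  # nb internal sites spanned
                break
            seen.setdefault(protein[a:b])
    return list(seen)


def classify_digestion(
    seq: str, prev_aa: str | None, next_aa: str | None
) -> str:
    """Grade a peptide A/B/C from its sequence and flanking residues.

    ``prev_aa`` / ``next_aa`` are the residues flanking the peptide in its
    parent database entry; ``None`` marks a protein terminus, which counts
    as tryptic. The N-terminus is tryptic when the preceding residue is
    K/R and the peptide does not start with P; the C-terminus when the
    peptide ends in K/R not followed by P.
    """
    residues = set(seq) | {r for r in (prev_aa, next_aa) if r is not None}
    bad = residues - _AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue symbol(s): {sorted(bad)}")

    n_tryptic = prev_aa is None or (prev_aa in "KR" and seq[0] != "P")
    c_tryptic = next_aa is None or (seq[-1] in "KR" and next_aa != "P")
    if not (n_tryptic and c_tryptic):
        return "C"
    n_missed = internal_missed_cleavages(seq)
    if n_missed == 0:
        return "A"
    if n_missed == 1:
        return "B"
    return "C"  # outside the fully/once-cleaved taxonomy: least reliable


def digest_peptides(proteins: Iterable[JunctionProtein], **kw) -> list[PeptideRecord]:
    """Convenience: junction-digest every protein of an iterable."""
    out: list[PeptideRecord] = []
    for jp in proteins:
        out.extend(digest_junction(jp, **kw))
    return out
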