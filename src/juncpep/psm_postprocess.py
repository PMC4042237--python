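"""Post-search identification of fusion and splicing peptides.

Per-engine PSM tables are filtered per raw file with the target-decoy
rule FDR(k) = 2F/(T+F) over the score-ranked list (hyperscore descending
for X!Tandem-like engines, e-value ascending for OMSSA-like ones); the
accepted set is the largest prefix whose FDR stays at or below alpha
(default 1e-6 — at that stringency any decoy in the prefix is fatal, so
the accepted set provably contains no decoy for fewer than two million
PSMs per file).

Accepted peptides are then categorized against the database with the
precedence Contaminated/Annotated > Splicing > Fusion, required to span
their junction with at least ``min_side_aa`` residues on each side, and
retained only with corroborating evidence: identified by both engines
with at least one shared (raw_file, spectrum_id), or flagged conserved
in another species (the rescue path, relevant to splicing peptides).
Finally each reported peptide is assigned its sample-group spectrum
counts and an exclusivity label.
"""

from __future__ import annotations

import collections
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .db_assembler import PeptideDatabase, DatabaseEntry
from .insilico_digest import classify_digestion

__all__ = [
    "PSM",
    "EngineProfile",
    "XTANDEM",
    "OMSSA",
    "PostprocessConfig",
    "EvidenceFlags",
    "CharacterizedPeptide",
    "load_psms",
    "fdr_filter",
    "categorize_peptide",
    "junction_span_ok",
    "integrate_evidence",
    "group_distribution",
    "read_group_map",
    "read_conservation",
    "run_postprocess",
]

PSM_COLUMNS = ["spectrum_id", "raw_file", "peptide", "score"]


@dataclass(frozen=True)
class PSM:
    """One spectrum-to-peptide match from one engine."""

    spectrum_id: str
    raw_file: str
    peptide: str
    score: float
    engine: str
    is_decoy: bool = False
    matched_entry_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("PSM with empty peptide")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for spectrum {self.spectrum_id}")


@dataclass(frozen=True)
class EngineProfile:
    name: str
    higher_better: bool


XTANDEM = EngineProfile("xtandem", higher_better=True)   # hyperscore
OMSSA = EngineProfile("omssa", higher_better=False)      # e-value

_PROFILES = {"xtandem": XTANDEM, "omssa": OMSSA}


def engine_profile(name: str) -> EngineProfile:
    try:
        return _PROFILES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown engine {name!r}; known: {sorted(_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class PostprocessConfig:
    fdr_alpha: float = 1e-6
    min_side_aa: int = 3
    require_shared_spectrum: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.min_side_aa < 1:
            raise ValueError("min_side_aa must be >= 1")


@dataclass(frozen=True)
class EvidenceFlags:
    both_engines: bool
    shared_spectrum: bool
    conserved: bool


@dataclass
class CharacterizedPeptide:
    """A final reported fusion/splicing peptide with its evidence."""

    sequence: str
    category: str  # "Fusion" | "Splicing"
    digestion_class: str  # "A" | "B" | "C"
    genes: tuple[str, str]
    exons: tuple[str, str]
    engines: frozenset[str]
    spectrum_counts: dict[str, int]  # per engine
    evidence: EvidenceFlags
    group_counts: dict[str, int] = field(default_factory=dict)
    exclusivity: str | None = None
    entry_id: str | None = None


def load_psms(
    path: str | Path | pd.DataFrame, profile: EngineProfile, db: PeptideDatabase
) -> list[PSM]:
    """Read a PSM TSV (spectrum_id, raw_file, peptide, score[, matched_entry_id]).

    ``is_decoy`` is set from the matched entry id when present, otherwise
    from peptide membership in the Reversal component. Rows with
    non-numeric scores are dropped with a warning reporting the count.
    A pre-parsed DataFrame with the same columns is accepted directly.
    """
    if isinstance(path, pd.DataFrame):
        df = path.astype(str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    n_bad = int(scores.isna().sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} row(s) with non-numeric score")
        df = df[scores.notna()]
        scores = scores[scores.notna()]
    has_entry = "matched_entry_id" in df.columns
    psms = []
    for (_, row), score in zip(df.iterrows(), scores):
        entry_id = row["matched_entry_id"] if has_entry and pd.notna(row.get("matched_entry_id")) else None
        if entry_id is not None:
            decoy = db.is_decoy_entry(entry_id)
        else:
            decoy = db.is_decoy_peptide(row["peptide"])
        psms.append(
            PSM(
                spectrum_id=row["spectrum_id"],
                raw_file=row["raw_file"],
                peptide=row["peptide"],
                score=float(score),
                engine=profile.name,
                is_decoy=decoy,
                matched_entry_id=entry_id,
            )
        )
    return psms


def fdr_filter(
    psms: Sequence[PSM], profile: EngineProfile, config: PostprocessConfig
) -> list[PSM]:
    """Accept the largest score-ranked prefix with FDR = 2F/(T+F) <= alpha.

    All PSMs must come from one raw file (the control is per raw file).
    Decoys sort after targets on exact score ties.
    """
    if not psms:
        return []
    raw_files = {p.raw_file for p in psms}
    if len(raw_files) > 1:
        raise ValueError(
            f"fdr_filter expects one raw file, got {sorted(raw_files)}"
        )
    sign = -1.0 if profile.higher_better else 1.0
    ranked = sorted(psms, key=lambda p: (sign * p.score, p.is_decoy))
    best_k = 0
    n_decoys = 0
    for k, psm in enumerate(ranked, start=1):
        if psm.is_decoy:
            n_decoys += 1
        if 2.0 * n_decoys / k <= config.fdr_alpha:
            best_k = k
    return ranked[:best_k]


def categorize_peptide(seq: str, db: PeptideDatabase) -> str:
    """Database category of a peptide under the precedence rule.

    Contaminated/Annotated beat Splicing, which beats Fusion; ``"none"``
    when the peptide matches no component.
    """
    m = db.membership(seq)
    for comp in ("Contaminated", "Annotated", "Splicing", "Fusion"):
        if comp in m:
            return comp
    return "none"


def junction_span_ok(
    seq: str, entry: DatabaseEntry, config: PostprocessConfig
) -> bool:
    """True when some occurrence of ``seq`` in ``entry`` has >= min_side_aa
    pure residues on each side of the junction (a straddling residue
    counts to neither side)."""
    if entry.meta is None:
        raise ValueError(f"entry {entry.entry_id} carries no junction metadata")
    left = entry.meta.junction_left_aa
    down0 = left + (1 if entry.meta.straddle else 0)
    start = entry.sequence.find(seq)
    while start != -1:
        end = start + len(seq)
        n_up = max(0, min(end, left) - start)
        n_down = max(0, end - max(start, down0))
        if n_up >= config.min_side_aa and n_down >= config.min_side_aa:
            return True
        start = entry.sequence.find(seq, start + 1)
    return False


def _best_match(
    seq: str, db: PeptideDatabase, category: str, config: PostprocessConfig
) -> tuple[DatabaseEntry, int] | None:
    """First (by entry id, then offset) junction-spanning match passing
    the per-side rule."""
    hits = [
        (e, off)
        for e, off in db.junction_matches(seq, category)
        if junction_span_ok(seq, e, config)
    ]
    if not hits:
        return None
    return min(hits, key=lambda t: (t[0].entry_id, t[1]))


def integrate_evidence(
    accepted: Mapping[str, Sequence[PSM]],
    conservation: Mapping[str, bool],
    db: PeptideDatabase,
    config: PostprocessConfig = PostprocessConfig(),
) -> list[CharacterizedPeptide]:
    """Cross-engine evidence integration over FDR-accepted PSMs.

    Candidates are accepted peptides categorized Fusion or Splicing whose
    match spans the junction with at least ``min_side_aa`` residues per
    side. A candidate is retained when it was identified by both engines
    sharing at least one (raw_file, spectrum_id) — engines agreeing on
    disjoint spectra are ruled out — or when it is flagged conserved.
    """
    per_pep_engines: dict[str, set[str]] = collections.defaultdict(set)
    per_pep_spectra: dict[str, dict[str, set[tuple[str, str]]]] = collections.defaultdict(
        lambda: collections.defaultdict(set)
    )
    per_pep_counts: dict[str, collections.Counter] = collections.defaultdict(
        collections.Counter
    )
    categories: dict[str, str] = {}
    matches: dict[str, tuple[DatabaseEntry, int]] = {}

    for engine, psms in accepted.items():
        for psm in psms:
            if psm.is_decoy:
                continue
            seq = psm.peptide
            if seq not in categories:
                categories[seq] = categorize_peptide(seq, db)
                if categories[seq] in ("Fusion", "Splicing"):
                    m = _best_match(seq, db, categories[seq], config)
                    if m is not None:
                        matches[seq] = m
            if categories[seq] not in ("Fusion", "Splicing") or seq not in matches:
                continue
            per_pep_engines[seq].add(engine)
            per_pep_spectra[seq][engine].add((psm.raw_file, psm.spectrum_id))
            per_pep_counts[seq][engine] += 1

    unknown_conserved = set(conservation) - set(categories)
    if unknown_conserved:
        warnings.warn(
            f"conservation table lists {len(unknown_conserved)} peptide(s) "
            "absent from the accepted PSMs; ignored"
        )

    out = []
    for seq in sorted(per_pep_engines):
        engines = per_pep_engines[seq]
        both = len(engines) >= 2
        spectra_sets = list(per_pep_spectra[seq].values())
        shared = both and bool(set.intersection(*spectra_sets))
        conserved = bool(conservation.get(seq, False))
        keep = conserved or (
            both and (shared or not config.require_shared_spectrum)
        )
        if not keep:
            continue
        entry, offset = matches[seq]
        prev_aa = entry.sequence[offset - 1] if offset > 0 else None
        end = offset + len(seq)
        next_aa = entry.sequence[end] if end < len(entry.sequence) else None
        out.append(
            CharacterizedPeptide(
                sequence=seq,
                category=categories[seq],
                digestion_class=classify_digestion(seq, prev_aa, next_aa),
                genes=entry.meta.genes,  # type: ignore[union-attr]
                exons=entry.meta.exons,  # type: ignore[union-attr]
                engines=frozenset(engines),
                spectrum_counts=dict(per_pep_counts[seq]),
                evidence=EvidenceFlags(both, shared, conserved),
                entry_id=entry.entry_id,
            )
        )
    out.sort(key=lambda c: (c.category, c.sequence))
    return out


def group_distribution(
    characterized: Sequence[CharacterizedPeptide],
    psms: Iterable[PSM],
    file_group_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-peptide sample-group spectrum counts and exclusivity labels.

    Counts accepted PSMs per group for each reported peptide; a peptide
    whose spectra all come from one group gets ``"<group>_only"``, else
    ``"mixed"``. Every raw file must be mapped; unmapped files raise with
    the file list. Mutates ``group_counts``/``exclusivity`` on the input
    records and returns a tidy DataFrame.
    """
    psms = list(psms)
    unmapped = sorted({p.raw_file for p in psms} - set(file_group_map))
    if unmapped:
        raise ValueError(f"raw file(s) not in group map: {unmapped}")

    groups = list(dict.fromkeys(file_group_map.values()))
    preferred = [g for g in ("SCC", "ADC", "Normal") if g in groups]
    groups = preferred + sorted(set(groups) - set(preferred))

    by_pep: dict[str, collections.Counter] = collections.defaultdict(
        collections.Counter
    )
    wanted = {c.sequence for c in characterized}
    for p in psms:
        if not p.is_decoy and p.peptide in wanted:
            by_pep[p.peptide][file_group_map[p.raw_file]] += 1

    rows = []
    for c in characterized:
        counts = {g: by_pep[c.sequence].get(g, 0) for g in groups}
        positive = [g for g in groups if counts[g] > 0]
        label = f"{positive[0]}_only" if len(positive) == 1 else "mixed"
        c.group_counts = counts
        c.exclusivity = label
        rows.append(
            {
                "sequence": c.sequence,
                "category": c.category,
                "genes": ":".join(c.genes),
                "digestion_class": c.digestion_class,
                **counts,
                "exclusivity": label,
            }
        )
    columns = ["sequence", "category", "genes", "digestion_class", *groups, "exclusivity"]
    return pd.DataFrame(rows, columns=columns)


def read_group_map(path: str | Path) -> dict[str, str]:
    """raw_file -> sample group TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("raw_file", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return dict(zip(df["raw_file"], df["group"]))


def read_conservation(path: str | Path) -> dict[str, bool]:
    """peptide -> conserved(0/1) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("peptide", "conserved"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return {p: bool(int(v)) for p, v in zip(df["peptide"], df["conserved"])}


def run_postprocess(
    db: PeptideDatabase,
    engine_tables: Mapping[str, str | Path | pd.DataFrame],
    group_map: Mapping[str, str],
    conservation: Mapping[str, bool] | None = None,
    config: PostprocessConfig = PostprocessConfig(),
) -> tuple[list[CharacterizedPeptide], pd.DataFrame, dict[str, list[PSM]]]:
    """Full post-search pipeline over per-engine PSM TSVs.

    ``engine_tables`` maps engine name (``xtandem``/``omssa``) to a PSM
    TSV path or DataFrame. FDR filtering runs per raw file within each
    engine; the
    accepted sets are unioned, evidence-integrated and distributed over
    sample groups. Returns (characterized peptides, distribution table,
    accepted PSMs per engine).
    """
    conservation = conservation or {}
    accepted: dict[str, list[PSM]] = {}
    for name, path in engine_tables.items():
        profile = engine_profile(name)
        psms = load_psms(path, profile, db)
        by_file: dict[str, list[PSM]] = collections.defaultdict(list)
        for p in psms:
            by_file[p.raw_file].append(p)
        acc: list[PSM] = []
        for raw_file in sorted(by_file):
            acc.extend(fdr_filter(by_file[raw_file], profile, config))
        accepted[profile.name] = acc

    characterized = integrate_evidence(accepted, conservation, db, config)
    all_accepted = [p for psms in accepted.values() for p in psms]
    table = group_distribution(characterized, all_accepted, group_map)
    return characterized, table, accepted
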