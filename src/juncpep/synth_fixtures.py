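"""Deterministic synthetic annotations, planted truth and mock PSM tables.

Every other module is testable without downloads: this module fabricates
a small genome of multi-exon genes whose frame-0 translations are
stop-free, plants fusion and splicing junction peptides by running the
real enumeration/translation/digestion machinery and keeping candidates
that satisfy every build- and identification-time filter, and simulates
two search engines (a hyperscore-like higher-is-better engine and an
e-value-like lower-is-better one) scoring true hits well apart from
noise and decoy hits.

Planted peptides are verified to be absent from the synthetic proteome
and to categorize correctly against the fully built database, so
end-to-end recovery tests have an exact expected answer. All outputs are
byte-reproducible from the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    ExonRecord,
    GeneModel,
    GenePair,
    write_gene_models,
    write_gene_pairs,
)
from .db_assembler import (
    DatabaseManifest,
    PeptideDatabase,
    build_database,
    write_database,
)
from .insilico_digest import digest_annotated, digest_junction
from .junction_builder import (
    CODON_AA,
    make_junction,
    translate_junction,
    translate_nt,
)
from .psm_postprocess import PostprocessConfig

__all__ = [
    "SimulationConfig",
    "TruthProfile",
    "PlantedPeptide",
    "GroundTruth",
    "SyntheticAnnotation",
    "SimulatedSearch",
    "Dataset",
    "GenerationError",
    "gen_annotation",
    "plant_truth",
    "simulate_search",
    "generate_dataset",
    "write_dataset",
]

NONSTOP_CODONS = sorted(c for c, aa in CODON_AA.items() if aa != "*")

DEFAULT_GROUPS = ("SCC", "ADC", "Normal")


class GenerationError(RuntimeError):
    """The generator could not satisfy the requested constraints."""


@dataclass(frozen=True)
class TruthProfile:
    """Evidence structure given to one planted peptide.

    ``groups`` maps sample group to the number of spectra generated for
    the peptide; ``engines`` lists the engines that identify it;
    ``shared_fraction`` overrides the config-level probability that a
    spectrum is shared (same spectrum id in both engines); ``conserved``
    marks the peptide in the conservation evidence table.
    """

    groups: Mapping[str, int]
    engines: tuple[str, ...] = ("xtandem", "omssa")
    shared_fraction: float | None = None
    conserved: bool = False


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; identical seed means identical bytes."""

    seed: int = 0
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len_range: tuple[int, int] = (30, 90)  # nucleotides
    n_fusion_truth: int = 3
    n_splicing_truth: int = 1
    fusion_profiles: Sequence[TruthProfile] | None = None
    splicing_profiles: Sequence[TruthProfile] | None = None
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_noise_spectra_per_group: int = 30
    n_strong_annotated: int = 6
    n_extra_pairs: int = 2
    n_extra_proteins: int = 3
    n_contaminants: int = 4
    decoy_hit_rate: float = 0.05
    shared_spectrum_fraction: float = 1.0
    # engine score models: true hits and noise are well separated
    xtandem_true: tuple[float, float] = (75.0, 6.0)   # mean, sd hyperscore
    xtandem_noise: tuple[float, float] = (22.0, 6.0)
    omssa_true_log10: tuple[float, float] = (-12.0, -7.0)  # uniform range
    omssa_noise_log10: tuple[float, float] = (-3.0, 0.0)
    min_len: int = 6
    max_misc_per_side: int = 1
    min_side_aa: int = 3

    def __post_init__(self) -> None:
        if self.exon_len_range[0] < 3:
            raise GenerationError("exon lengths must be at least 3 nt")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise GenerationError("invalid exons_per_gene range")
        for p in (self.decoy_hit_rate, self.shared_spectrum_fraction):
            if not 0.0 <= p <= 1.0:
                raise GenerationError("probabilities must lie in [0, 1]")
        counts = (
            self.n_genes,
            self.n_fusion_truth,
            self.n_splicing_truth,
            self.n_noise_spectra_per_group,
        )
        if any(c < 0 for c in counts):
            raise GenerationError("counts must be non-negative")
        if self.n_effective_splicing > 0 and self.exons_per_gene[1] < 3:
            raise GenerationError(
                "splicing truth requires genes with at least 3 exons "
                "(a non-adjacent exon pair)"
            )
        if self.n_effective_fusion > 0 and self.n_genes < 2:
            raise GenerationError("fusion truth requires at least 2 genes")

    @property
    def n_effective_fusion(self) -> int:
        return (
            len(self.fusion_profiles)
            if self.fusion_profiles is not None
            else self.n_fusion_truth
        )

    @property
    def n_effective_splicing(self) -> int:
        return (
            len(self.splicing_profiles)
            if self.splicing_profiles is not None
            else self.n_splicing_truth
        )


@dataclass
class PlantedPeptide:
    """One ground-truth junction peptide with its realized evidence."""

    sequence: str
    kind: str  # "fusion" | "splicing"
    gene_up: str
    gene_down: str
    exon_up: str
    exon_down: str
    frame: int
    profile: TruthProfile
    entry_id: str | None = None
    realized_shared: bool | None = None  # set by simulate_search

    @property
    def expected_category(self) -> str:
        return "Fusion" if self.kind == "fusion" else "Splicing"

    @property
    def expected_reported(self) -> bool:
        if self.profile.conserved:
            return True
        if len(self.profile.engines) < 2:
            return False
        if self.realized_shared is None:
            raise ValueError("run simulate_search before asking for expectations")
        return self.realized_shared

    @property
    def expected_exclusivity(self) -> str:
        positive = [g for g, c in self.profile.groups.items() if c > 0]
        return f"{positive[0]}_only" if len(positive) == 1 else "mixed"


@dataclass
class GroundTruth:
    peptides: list[PlantedPeptide]

    def expected_reported_sequences(self) -> dict[str, PlantedPeptide]:
        return {p.sequence: p for p in self.peptides if p.expected_reported}

    def of_kind(self, kind: str) -> list[PlantedPeptide]:
        return [p for p in self.peptides if p.kind == kind]


@dataclass
class SyntheticAnnotation:
    models: dict[str, GeneModel]  # keyed by gene symbol
    proteome: dict[str, str]
    contaminants: dict[str, str]


@dataclass
class SimulatedSearch:
    tables: dict[str, pd.DataFrame]  # engine name -> PSM table
    group_map: dict[str, str]
    conservation: dict[str, bool]


@dataclass
class Dataset:
    """Everything one simulated study produces, in memory."""

    config: SimulationConfig
    annotation: SyntheticAnnotation
    pairs: list[GenePair]
    truth: GroundTruth
    database: PeptideDatabase
    manifest: DatabaseManifest
    search: SimulatedSearch


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), n_codons)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def gen_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticAnnotation:
    """Fabricate genes with stop-free frame-0 exon chains plus proteins.

    Each gene's coding sequence is drawn codon-wise from the 61 non-stop
    codons and split into exons with lengths in ``exon_len_range`` (the
    last exon absorbs the remainder to keep the total a codon multiple),
    so the gene's frame-0 translation is an open reading frame. The
    proteome contains every gene's translation plus unrelated proteins.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo_ex, hi_ex = config.exons_per_gene
    lo_len, hi_len = config.exon_len_range

    models: dict[str, GeneModel] = {}
    proteome: dict[str, str] = {}
    for i in range(config.n_genes):
        symbol = f"GENE{i + 1:02d}"
        gene_id = f"g{i + 1:02d}"
        n_ex = int(rng.integers(lo_ex, hi_ex + 1))
        lengths = [int(rng.integers(lo_len, hi_len + 1)) for _ in range(n_ex)]
        rem = sum(lengths) % 3
        if rem:
            lengths[-1] += 3 - rem  # keep the gene frame a codon multiple
        cds = _random_cds(rng, sum(lengths) // 3)
        strand = "+" if i % 2 == 0 else "-"
        chrom = f"chr{1 + i % 4}"
        # cosmetic but self-consistent coordinates (span == sequence length);
        # on '-' ranks ascend while genomic starts descend
        genomic_order = range(n_ex) if strand == "+" else range(n_ex - 1, -1, -1)
        span_of = {}
        pos = 10_000 + i * 100_000
        for k in genomic_order:
            span_of[k] = (pos, pos + lengths[k] - 1)
            pos += lengths[k] + int(rng.integers(80, 600))
        spans = [span_of[k] for k in range(n_ex)]
        exons = []
        offset = 0
        for j, (length, (start, end)) in enumerate(zip(lengths, spans), start=1):
            exons.append(
                ExonRecord(
                    exon_id=f"{gene_id}e{j}",
                    gene_id=gene_id,
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    rank=j,
                    sequence=cds[offset : offset + length],
                )
            )
            offset += length
        models[symbol] = GeneModel(
            gene_id=gene_id, gene_symbol=symbol, strand=strand, exons=tuple(exons)
        )
        proteome[f"PROT_{symbol}"] = translate_nt(cds)

    for i in range(config.n_extra_proteins):
        n = int(rng.integers(80, 200))
        proteome[f"PROT_EXTRA{i + 1:02d}"] = translate_nt(_random_cds(rng, n))
    contaminants = {
        f"CONT{i + 1:02d}": translate_nt(_random_cds(rng, int(rng.integers(60, 150))))
        for i in range(config.n_contaminants)
    }
    return SyntheticAnnotation(models=models, proteome=proteome, contaminants=contaminants)


def _auto_profiles(n: int, groups: tuple[str, ...]) -> list[TruthProfile]:
    """Deterministic cycle of group profiles: exclusives first, then mixed."""
    cycle = [
        *({g: 2} for g in groups),
        {groups[0]: 2, groups[1]: 1},
        {g: 1 for g in groups},
    ]
    return [TruthProfile(groups=cycle[i % len(cycle)]) for i in range(n)]


def _qualifying_peptides(jn, config: SimulationConfig):
    """Junction peptides passing both build- and identification-time filters."""
    out = []
    for jp in translate_junction(jn):
        for pep in digest_junction(jp, config.max_misc_per_side, config.min_len):
            if pep.left_aa >= config.min_side_aa and pep.right_aa >= config.min_side_aa:
                out.append(pep)
    return out


def plant_truth(
    annotation: SyntheticAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GroundTruth, list[GenePair]]:
    """Select gene pairs and exon joins carrying valid ground-truth peptides.

    Fusion truths use distinct gene pairs; splicing truths use
    non-adjacent exon pairs (so the peptide is not an annotated junction).
    Every candidate peptide is produced by the real translation/digestion
    machinery and must be absent from the proteome and contaminants and
    distinct from all other planted peptides. Raises
    :class:`GenerationError` when the constraints cannot be met.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    models = annotation.models
    blob = "|".join(
        itertools.chain(annotation.proteome.values(), annotation.contaminants.values())
    )
    fusion_profiles = (
        list(config.fusion_profiles)
        if config.fusion_profiles is not None
        else _auto_profiles(config.n_effective_fusion, config.groups)
    )
    splicing_profiles = (
        list(config.splicing_profiles)
        if config.splicing_profiles is not None
        else _auto_profiles(config.n_effective_splicing, config.groups)
    )

    planted: list[PlantedPeptide] = []
    used_seqs: set[str] = set()
    pairs: list[GenePair] = []

    def try_plant(jn, kind, profile) -> PlantedPeptide | None:
        cands = _qualifying_peptides(jn, config)
        order = rng.permutation(len(cands))
        for k in order:
            pep = cands[int(k)]
            seq = pep.sequence
            if seq in used_seqs or seq in blob:
                continue
            if any(seq in p.sequence or p.sequence in seq for p in planted):
                continue
            prov = pep.provenance[0]
            used_seqs.add(seq)
            return PlantedPeptide(
                sequence=seq,
                kind=kind,
                gene_up=prov.gene_up,
                gene_down=prov.gene_down,
                exon_up=prov.exon_up,
                exon_down=prov.exon_down,
                frame=prov.frame,
                profile=profile,
            )
        return None

    # --- fusion truths: one peptide per distinct unordered gene pair
    symbols = sorted(models)
    all_pairs = list(itertools.combinations(symbols, 2))
    rng.shuffle(all_pairs)
    pair_iter = iter(all_pairs)
    for profile in fusion_profiles:
        found = None
        for a, b in pair_iter:
            joins = [
                (up_ex, down_ex, up, down)
                for up, down in ((a, b), (b, a))
                for up_ex in models[up].exons
                for down_ex in models[down].exons
            ]
            for j in rng.permutation(len(joins)):
                up_ex, down_ex, up, down = joins[int(j)]
                jn = make_junction(
                    up_ex, down_ex, kind="fusion", up_gene=up, down_gene=down
                )
                found = try_plant(jn, "fusion", profile)
                if found:
                    break
            if found:
                pairs.append(GenePair.make(a, b, {"planted"}))
                break
        if not found:
            raise GenerationError(
                "could not plant the requested number of fusion peptides; "
                "increase n_genes or exon sizes"
            )
        planted.append(found)

    # --- splicing truths: non-adjacent exon pairs within one gene
    spliceable = [s for s in symbols if models[s].n_exons >= 3]
    rng.shuffle(spliceable)
    gene_cycle = itertools.cycle(spliceable) if spliceable else None
    used_joins: set[tuple[str, str]] = set()
    for profile in splicing_profiles:
        if gene_cycle is None:
            raise GenerationError("no gene has >= 3 exons for splicing truth")
        found = None
        for _ in range(len(spliceable) * 4):
            sym = next(gene_cycle)
            gm = models[sym]
            joins = [
                (gm.exons[i], gm.exons[j])
                for i in range(gm.n_exons)
                for j in range(i + 2, gm.n_exons)
                if (gm.exons[i].exon_id, gm.exons[j].exon_id) not in used_joins
            ]
            for j in rng.permutation(len(joins)):
                up_ex, down_ex = joins[int(j)]
                jn = make_junction(
                    up_ex, down_ex, kind="splicing", up_gene=sym, down_gene=sym
                )
                found = try_plant(jn, "splicing", profile)
                if found:
                    used_joins.add((up_ex.exon_id, down_ex.exon_id))
                    break
            if found:
                break
        if not found:
            raise GenerationError(
                "could not plant the requested number of splicing peptides"
            )
        planted.append(found)

    # every splicing-truth gene must be referenced by some pair, since the
    # database enumerates splicing junctions for paired genes only
    covered = {s for p in pairs for s in (p.symbol_a, p.symbol_b)}
    existing = {p.key for p in pairs}
    for pp in planted:
        if pp.kind == "splicing" and pp.gene_up not in covered:
            partner = next(s for s in symbols if s != pp.gene_up)
            pair = GenePair.make(pp.gene_up, partner, {"filler"})
            if pair.key not in existing:
                pairs.append(pair)
                existing.add(pair.key)
                covered |= {pair.symbol_a, pair.symbol_b}

    for _ in range(config.n_extra_pairs):
        for _try in range(20):
            a, b = (symbols[int(i)] for i in rng.choice(len(symbols), 2, replace=False))
            pair = GenePair.make(a, b, {"extra"})
            if pair.key not in existing:
                pairs.append(pair)
                existing.add(pair.key)
                break

    return GroundTruth(peptides=planted), pairs


def _annotated_peptide_pool(
    proteome: Mapping[str, str], min_len: int
) -> list[tuple[str, str]]:
    pool = []
    for pid in sorted(proteome):
        for pep in digest_annotated(proteome[pid], max_misc=1):
            if len(pep) >= min_len:
                pool.append((pid, pep))
    return pool


def simulate_search(
    db: PeptideDatabase,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedSearch:
    """Fabricate per-engine PSM tables, the group map and conservation table.

    True peptides score from the engines' high-separation distributions
    with spectrum sharing controlled per peptide; noise spectra hit
    random annotated peptides or (at ``decoy_hit_rate``) reversal decoys
    with low scores; a handful of strong annotated hits exercise the
    Annotated-precedence exclusion. Sets ``realized_shared`` on each
    planted peptide.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)

    raw_of = {g: f"{g.lower()}_pool.raw" for g in config.groups}
    sid_counter: dict[str, int] = {rf: 0 for rf in raw_of.values()}

    def next_sid(raw_file: str) -> str:
        sid_counter[raw_file] += 1
        return f"spec{sid_counter[raw_file]:05d}"

    def xt_true() -> float:
        return float(rng.normal(*config.xtandem_true))

    def xt_noise() -> float:
        return max(1.0, float(rng.normal(*config.xtandem_noise)))

    def om_true() -> float:
        return float(10.0 ** rng.uniform(*config.omssa_true_log10))

    def om_noise() -> float:
        return float(10.0 ** rng.uniform(*config.omssa_noise_log10))

    true_score = {"xtandem": xt_true, "omssa": om_true}
    noise_score = {"xtandem": xt_noise, "omssa": om_noise}
    rows: dict[str, list[dict]] = {"xtandem": [], "omssa": []}

    def emit(engine, raw_file, sid, peptide, score, entry_id) -> None:
        rows[engine].append(
            {
                "spectrum_id": sid,
                "raw_file": raw_file,
                "peptide": peptide,
                "score": score,
                "matched_entry_id": entry_id,
            }
        )

    # --- planted true hits
    for pp in truth.peptides:
        if pp.entry_id is None:
            raise ValueError(
                "planted peptide has no database entry id; run generate_dataset"
            )
        frac = (
            pp.profile.shared_fraction
            if pp.profile.shared_fraction is not None
            else config.shared_spectrum_fraction
        )
        any_shared = False
        for group, count in pp.profile.groups.items():
            raw_file = raw_of[group]
            for _ in range(count):
                engines = pp.profile.engines
                if len(engines) >= 2 and rng.random() < frac:
                    sid = next_sid(raw_file)
                    any_shared = True
                    for eng in engines:
                        emit(eng, raw_file, sid, pp.sequence, true_score[eng](), pp.entry_id)
                else:
                    for eng in engines:
                        emit(
                            eng,
                            raw_file,
                            next_sid(raw_file),
                            pp.sequence,
                            true_score[eng](),
                            pp.entry_id,
                        )
        pp.realized_shared = any_shared

    # --- strong annotated hits (shared spectra, both engines)
    annotated_pool = _annotated_peptide_pool(
        {e.entry_id: e.sequence for e in db.component("Annotated")}, config.min_len
    )
    if annotated_pool:
        for _ in range(config.n_strong_annotated):
            pid, pep = annotated_pool[int(rng.integers(0, len(annotated_pool)))]
            group = config.groups[int(rng.integers(0, len(config.groups)))]
            raw_file = raw_of[group]
            sid = next_sid(raw_file)
            for eng in ("xtandem", "omssa"):
                emit(eng, raw_file, sid, pep, true_score[eng](), pid)

    # --- noise spectra: low-scoring annotated or decoy matches
    decoys = db.component("Reversal")
    for group in config.groups:
        raw_file = raw_of[group]
        for _ in range(config.n_noise_spectra_per_group):
            sid = next_sid(raw_file)
            eng = ("xtandem", "omssa")[int(rng.integers(0, 2))]
            if decoys and rng.random() < config.decoy_hit_rate:
                entry = decoys[int(rng.integers(0, len(decoys)))]
                length = min(len(entry.sequence), int(rng.integers(8, 16)))
                start = int(rng.integers(0, len(entry.sequence) - length + 1))
                emit(
                    eng,
                    raw_file,
                    sid,
                    entry.sequence[start : start + length],
                    noise_score[eng](),
                    entry.entry_id,
                )
            elif annotated_pool:
                pid, pep = annotated_pool[int(rng.integers(0, len(annotated_pool)))]
                emit(eng, raw_file, sid, pep, noise_score[eng](), pid)

    tables = {}
    for eng, data in rows.items():
        df = pd.DataFrame(
            data,
            columns=["spectrum_id", "raw_file", "peptide", "score", "matched_entry_id"],
        )
        tables[eng] = df.sort_values(
            ["raw_file", "spectrum_id", "peptide"], kind="stable"
        ).reset_index(drop=True)

    group_map = {raw_of[g]: g for g in config.groups}
    conservation = {
        pp.sequence: pp.profile.conserved
        for pp in truth.peptides
        if pp.profile.conserved
    }
    return SimulatedSearch(tables=tables, group_map=group_map, conservation=conservation)


def generate_dataset(config: SimulationConfig, max_attempts: int = 4) -> Dataset:
    """Run the whole generator: annotation, truth, database, search tables.

    After building the database the planted peptides are verified: each
    must categorize to its own kind (no accidental annotated/splicing
    collision) and span its junction with the identification-time margin.
    A failed verification redraws everything from a derived seed; the
    result is still a pure function of ``config``.
    """
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([config.seed, attempt])
        try:
            annotation = gen_annotation(config, rng)
            truth, pairs = plant_truth(annotation, config, rng)
            entries, manifest = build_database(
                annotation.models,
                pairs,
                annotation.proteome,
                annotation.contaminants,
                min_len=config.min_len,
                max_misc_per_side=config.max_misc_per_side,
            )
            db = PeptideDatabase(entries)
            _verify_truth(db, truth, config)
            search = simulate_search(db, truth, config, rng)
            return Dataset(
                config=config,
                annotation=annotation,
                pairs=pairs,
                truth=truth,
                database=db,
                manifest=manifest,
                search=search,
            )
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"dataset generation failed after {max_attempts} attempts: {last_err}"
    )


def _verify_truth(
    db: PeptideDatabase, truth: GroundTruth, config: SimulationConfig
) -> None:
    from .psm_postprocess import categorize_peptide, junction_span_ok

    pconf = PostprocessConfig(min_side_aa=config.min_side_aa)
    for pp in truth.peptides:
        category = categorize_peptide(pp.sequence, db)
        if category != pp.expected_category:
            raise GenerationError(
                f"planted {pp.kind} peptide {pp.sequence} categorizes as "
                f"{category}; redrawing"
            )
        hits = [
            (e, off)
            for e, off in db.junction_matches(pp.sequence, category)
            if junction_span_ok(pp.sequence, e, pconf)
        ]
        if not hits:
            raise GenerationError(
                f"planted peptide {pp.sequence} lost its junction span; redrawing"
            )
        pp.entry_id = min(e.entry_id for e, _ in hits)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every input file a real run would consume, plus the database.

    TSV artifacts carry a ``# seed=`` header line for provenance; returns
    the path of each artifact by name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = dataset.config.seed
    paths = {
        "exons_tsv": out / "exons.tsv",
        "exons_fasta": out / "exons.fa",
        "proteome": out / "proteome.fa",
        "contaminants": out / "contaminants.fa",
        "pairs": out / "pairs.tsv",
        "database": out / "database.fa",
        "manifest": out / "database.manifest.tsv",
        "psms_xtandem": out / "psms_xtandem.tsv",
        "psms_omssa": out / "psms_omssa.tsv",
        "groups": out / "groups.tsv",
        "conservation": out / "conservation.tsv",
    }

    write_gene_models(
        dataset.annotation.models.values(), paths["exons_tsv"], paths["exons_fasta"]
    )
    _prepend_seed(paths["exons_tsv"], seed)
    with open(paths["proteome"], "w") as fh:
        for pid in sorted(dataset.annotation.proteome):
            fh.write(f">{pid}\n{dataset.annotation.proteome[pid]}\n")
    with open(paths["contaminants"], "w") as fh:
        for pid in sorted(dataset.annotation.contaminants):
            fh.write(f">{pid}\n{dataset.annotation.contaminants[pid]}\n")
    write_gene_pairs(dataset.pairs, paths["pairs"])
    _prepend_seed(paths["pairs"], seed)
    write_database(
        dataset.database.entries, dataset.manifest, paths["database"], paths["manifest"]
    )
    for eng in ("xtandem", "omssa"):
        p = paths[f"psms_{eng}"]
        with open(p, "w") as fh:
            fh.write(f"# seed={seed}\n")
            dataset.search.tables[eng].to_csv(fh, sep="\t", index=False)
    with open(paths["groups"], "w") as fh:
        fh.write(f"# seed={seed}\nraw_file\tgroup\n")
        for rf, g in sorted(dataset.search.group_map.items()):
            fh.write(f"{rf}\t{g}\n")
    with open(paths["conservation"], "w") as fh:
        fh.write(f"# seed={seed}\npeptide\tconserved\n")
        for pep, flag in sorted(dataset.search.conservation.items()):
            fh.write(f"{pep}\t{int(flag)}\n")
    return paths


def _prepend_seed(path: Path, seed: int) -> None:
    text = path.read_text()
    path.write_text(f"# seed={seed}\n{text}")
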