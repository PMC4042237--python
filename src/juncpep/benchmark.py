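"""Published NSCLC benchmark set and the bookkeeping-emulation scenario.

``data/nsclc_characterized_peptides.tsv`` ships the characterized fusion
and splicing peptides reported for a pooled lung study (20 squamous-cell
carcinoma, 20 adenocarcinoma and 39 normal lung samples searched with
X!Tandem and OMSSA): 19 fusion and 4 splicing peptides with their gene
partners, per-engine spectrum counts and digestion class. The sequences
and classes serve as exact oracles for the cleavage and classification
rules.

The same study's identification bookkeeping — 25 fusion and 5 splicing
candidates found by both engines, one further splicing candidate rescued
by cross-species conservation, 6 fusion and 2 splicing candidates ruled
out because the two engines matched entirely different spectra, and a
final distribution with 8 SCC-only, 2 ADC-only and 3 Normal-only
peptides of which 11 fusion events never appear in normal tissue — is
encoded here as a simulation scenario. :func:`benchmark_scenario` plants
synthetic peptides with exactly that evidence structure so the full
pipeline can recompute every aggregate count from raw PSM tables.

The per-peptide group assignment behind the aggregate 8/2/3 counts is
not public; the profile below is one concrete assignment consistent with
every published aggregate (fusion: 7 SCC-only, 2 ADC-only, 2 SCC+ADC,
2 Normal-only, 6 present in all groups; splicing: 1 SCC-only,
1 Normal-only, 2 mixed).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .synth_fixtures import SimulationConfig, TruthProfile

__all__ = [
    "load_characterized_benchmark",
    "STUDY_COUNTS",
    "benchmark_scenario",
]

#: Aggregate identification bookkeeping of the pooled lung study.
STUDY_COUNTS = {
    "fusion_candidates_both_engines": 25,
    "fusion_excluded_disjoint_spectra": 6,
    "fusion_final": 19,
    "splicing_candidates_both_engines": 5,
    "splicing_rescued_by_conservation": 1,
    "splicing_excluded_disjoint_spectra": 2,
    "splicing_final": 4,
    "scc_only": 8,
    "adc_only": 2,
    "normal_only": 3,
    "nsclc_only_fusion_events": 11,
}


def load_characterized_benchmark() -> pd.DataFrame:
    """The shipped table of published fusion/splicing peptides."""
    with resources.files("juncpep.data").joinpath(
        "nsclc_characterized_peptides.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _fusion_profiles() -> list[TruthProfile]:
    profiles: list[TruthProfile] = []
    # 19 retained: both engines, shared spectra
    retained_groups = (
        [{"SCC": 3}] * 7                      # SCC-only
        + [{"ADC": 2}] * 2                    # ADC-only
        + [{"SCC": 2, "ADC": 1}] * 2          # NSCLC-only, both tumour types
        + [{"Normal": 2}] * 2                 # Normal-only
        + [{"SCC": 2, "ADC": 1, "Normal": 1}] * 6  # mixed with Normal
    )
    for groups in retained_groups:
        profiles.append(TruthProfile(groups=groups))
    # 6 ruled out: both engines but disjoint spectra
    for _ in range(6):
        profiles.append(
            TruthProfile(groups={"SCC": 1, "Normal": 1}, shared_fraction=0.0)
        )
    return profiles


def _splicing_profiles() -> list[TruthProfile]:
    return [
        # 3 retained via both engines + shared spectra
        TruthProfile(groups={"SCC": 2}),                          # SCC-only
        TruthProfile(groups={"Normal": 3}),                       # Normal-only
        TruthProfile(groups={"SCC": 1, "ADC": 1, "Normal": 1}),   # mixed
        # 2 ruled out: both engines, disjoint spectra
        TruthProfile(groups={"ADC": 1, "Normal": 1}, shared_fraction=0.0),
        TruthProfile(groups={"SCC": 1}, shared_fraction=0.0),
        # 1 rescued: single engine but conserved in another species (mixed)
        TruthProfile(
            groups={"SCC": 2, "ADC": 1, "Normal": 2},
            engines=("xtandem",),
            conserved=True,
        ),
    ]


def benchmark_scenario(seed: int) -> SimulationConfig:
    """Simulation config whose pipeline output mirrors the study bookkeeping."""
    return SimulationConfig(
        seed=seed,
        n_genes=14,
        exons_per_gene=(3, 5),
        exon_len_range=(45, 90),
        fusion_profiles=_fusion_profiles(),
        splicing_profiles=_splicing_profiles(),
        n_noise_spectra_per_group=60,
        decoy_hit_rate=0.1,
    )
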