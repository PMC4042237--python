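"""Optional adapters normalizing engine-native outputs to the PSM TSV contract.

Search engines themselves are external to this package; these readers
only convert their native result files into the generic table consumed
by :mod:`juncpep.psm_postprocess` (columns ``spectrum_id``, ``raw_file``,
``peptide``, ``score``, ``matched_entry_id``). The shipped X!Tandem
input template (``data/xtandem_input_template.xml``) documents the
recommended parent-mass window (+/- 10 Da monoisotopic) for junction
searches; it is documentation only and is never executed here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from lxml import etree

__all__ = ["read_xtandem_xml", "read_omssa_csv", "to_psm_tsv"]


def read_xtandem_xml(path: str | Path, raw_file: str) -> pd.DataFrame:
    """Parse an X!Tandem BIOML output file into the PSM table contract.

    Each spectrum-level ``<group type="model">`` contributes one row per
    top-ranked ``<domain>``; the hyperscore is the reported score and the
    protein label becomes ``matched_entry_id``. The raw file name is not
    recorded in BIOML output, so it must be supplied.
    """
    tree = etree.parse(str(path))
    rows = []
    for group in tree.iter("group"):
        if group.get("type") != "model":
            continue
        spectrum_id = group.get("id")
        for protein in group.iter("protein"):
            label = protein.get("label", "")
            entry_id = label.split("|")[1] if "|" in label else label
            for domain in protein.iter("domain"):
                rows.append(
                    {
                        "spectrum_id": spectrum_id,
                        "raw_file": raw_file,
                        "peptide": domain.get("seq", "").upper(),
                        "score": float(domain.get("hyperscore")),
                        "matched_entry_id": entry_id,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["spectrum_id", "raw_file", "peptide", "score", "matched_entry_id"],
    )


def read_omssa_csv(path: str | Path, raw_file: str) -> pd.DataFrame:
    """Parse an OMSSA CSV result file into the PSM table contract.

    Uses the standard OMSSA columns ``Spectrum number``, ``Peptide``,
    ``E-value`` and ``Accession``; the e-value is the (lower-is-better)
    score.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    required = ["Spectrum number", "Peptide", "E-value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing OMSSA column(s) {missing}")
    entry = df["Accession"] if "Accession" in df.columns else df.get("Defline", "")
    return pd.DataFrame(
        {
            "spectrum_id": df["Spectrum number"].astype(str),
            "raw_file": raw_file,
            "peptide": df["Peptide"].str.upper(),
            "score": df["E-value"].astype(float),
            "matched_entry_id": entry,
        }
    )


def to_psm_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a normalized PSM table to the TSV contract."""
    df.to_csv(path, sep="\t", index=False)
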