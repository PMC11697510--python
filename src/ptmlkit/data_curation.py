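"""Curation of ChEMBL-style IC50 bioactivity tables.

Raw exports are cleaned (missing values/units/SMILES dropped, non-IC50
endpoints removed), deduplicated per (molecule, target, assay) keeping the
lowest IC50, labeled active when IC50 <= 150 nM, and split 3:1 into
training/test by sorting each protein's cases by potency and tagging them
in a repeating (training, training, training, test) pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "ACTIVITY_CUTOFF_NM",
    "CurationError",
    "read_bioactivity_table",
    "clean",
    "deduplicate",
    "label",
    "split",
    "curate",
]

logger = logging.getLogger(__name__)

#: canonical internal column names
REQUIRED_COLUMNS = ("molecule_id", "smiles", "standard_type", "standard_value",
                    "standard_units", "tp", "ai")

#: IC50 activity cutoff in nM: active (IA = +1) iff IC50 <= this value
ACTIVITY_CUTOFF_NM = 150.0

#: tolerated ChEMBL-export header spellings -> internal names
_HEADER_ALIASES = {
    "molecule chembl id": "molecule_id",
    "molecule_chembl_id": "molecule_id",
    "compound_id": "molecule_id",
    "canonical_smiles": "smiles",
    "canonical smiles": "smiles",
    "target chembl id": "tp",
    "target_chembl_id": "tp",
    "target": "tp",
    "assay_information": "ai",
    "assay information": "ai",
    "a.i.": "ai",
}


class CurationError(ValueError):
    pass


def read_bioactivity_table(path) -> pd.DataFrame:
    """Read a CSV/TSV bioactivity export, normalizing header spellings."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [_HEADER_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurationError(f"bioactivity table lacks required columns: {missing}")
    return df


def clean(records: pd.DataFrame, convert_micromolar: bool = True) -> pd.DataFrame:
    """Drop rows unusable for modelling; log a count per removal reason.

    Removes rows with missing IC50 value, units, or SMILES, non-IC50
    endpoints, and non-positive values.  Micromolar rows are converted to
    nM (x1000) before unit filtering unless ``convert_micromolar=False``;
    only nM survives.
    """
    df = records.copy()
    n0 = len(df)

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            logger.info("clean: dropped %d rows (%s)", n, reason)
        df = df[~mask]

    _drop(df["smiles"].isna() | (df["smiles"].astype(str).str.strip() == ""), "missing SMILES")
    _drop(df["standard_value"].isna(), "missing value")
    _drop(df["standard_units"].isna() | (df["standard_units"].astype(str).str.strip() == ""),
          "missing units")
    _drop(df["standard_type"].astype(str).str.upper() != "IC50", "non-IC50 endpoint")

    if convert_micromolar:
        um = df["standard_units"].astype(str).str.strip().isin(["uM", "µM", "um"])
        if um.any():
            logger.info("clean: converted %d rows from uM to nM", int(um.sum()))
            df.loc[um, "standard_value"] = df.loc[um, "standard_value"].astype(float) * 1000.0
            df.loc[um, "standard_units"] = "nM"
    _drop(df["standard_units"].astype(str).str.strip() != "nM", "non-nM units")
    df["standard_value"] = df["standard_value"].astype(float)
    _drop(df["standard_value"] <= 0, "non-positive value")
    _drop(df["tp"].isna() | (df["tp"].astype(str).str.strip() == ""), "missing target")
    _drop(df["ai"].isna() | (df["ai"].astype(str).str.strip() == ""), "missing assay info")

    if df.empty:
        raise CurationError(f"cleaning removed all {n0} rows; nothing to model")
    return df.reset_index(drop=True)


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (molecule, tp, ai): the one with the lowest IC50.

    Ties on IC50 keep the first-seen row (stable sort).
    """
    df = records.reset_index(drop=True)
    df["_ord"] = range(len(df))
    df = df.sort_values(["molecule_id", "tp", "ai", "standard_value", "_ord"],
                        kind="stable")
    df = df.drop_duplicates(subset=["molecule_id", "tp", "ai"], keep="first")
    df = df.sort_values("_ord").drop(columns="_ord")
    return df.reset_index(drop=True)


def label(records: pd.DataFrame, cutoff: float = ACTIVITY_CUTOFF_NM) -> pd.DataFrame:
    """Attach the activity class IA: +1 iff IC50 <= cutoff (inclusive), else -1."""
    df = records.copy()
    df["IA"] = (df["standard_value"] <= cutoff).map({True: 1, False: -1}).astype(int)
    return df


def split(cases: pd.DataFrame) -> pd.DataFrame:
    """Tag cases training/test with a per-protein 3:1 potency-ordered pattern.

    Within each target protein, cases are sorted by increasing IC50 (ties
    broken by molecule id for determinism) and tagged with the repeating
    pattern training, training, training, test.
    """
    df = cases.copy()
    tags = pd.Series(index=df.index, dtype=object)
    for _, group in df.groupby("tp", sort=False):
        order = group.sort_values(["standard_value", "molecule_id"], kind="stable").index
        for pos, idx in enumerate(order):
            tags.loc[idx] = "test" if pos % 4 == 3 else "training"
    df["split"] = tags
    return df


@dataclass
class CurationSummary:
    n_input: int
    n_curated: int
    n_active: int
    n_training: int


def curate(records: pd.DataFrame, cutoff: float = ACTIVITY_CUTOFF_NM,
           convert_micromolar: bool = True) -> pd.DataFrame:
    """clean -> deduplicate -> label -> split, in one call."""
    df = split(label(deduplicate(clean(records, convert_micromolar)), cutoff))
    logger.info(
        "curate: %d -> %d cases, %d active, %d training",
        len(records), len(df), int((df["IA"] == 1).sum()),
        int((df["split"] == "training").sum()),
    )
    return df
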