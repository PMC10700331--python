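"""Cohort assembly: contamination filtering, SCK classification, descriptives.

Works on pandas DataFrames in the cohort CSV schema produced by
:mod:`ketogene.simulate` (see ``COHORT_COLUMNS`` there). Blood BHB is in
mmol/L; subclinical ketosis (SCK) is diagnosed at BHB >= 1.0 mmol/L by
default, the inclusive diagnostic reference. Alternative literature cutoffs
(1.2, 1.4 mmol/L) can be passed through ``threshold``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import MissingDataError, ParameterError

#: Default diagnostic threshold for subclinical ketosis, mmol/L blood BHB.
DEFAULT_BHB_THRESHOLD = 1.0

#: Milk/phenotype variables summarized by the descriptives table.
DESCRIPTIVE_VARIABLES = [
    "bhb_mmol_l",
    "milk_kg",
    "fat_pct",
    "protein_pct",
    "lactose_pct",
    "dry_matter_pct",
    "urea_mg_l",
    "scc_k_per_ml",
]


def load_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "contaminated" in df.columns:
        df["contaminated"] = df["contaminated"].astype(bool)
    return df


def filter_contaminated(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records whose ketosis test is unusable.

    A record is removed when its contamination flag is set or its BHB value
    is missing (a contaminated sample yields no valid measurement). Input
    order is preserved; returns ``(kept, n_removed)``.
    """
    contaminated = records.get("contaminated")
    bad = pd.Series(False, index=records.index)
    if contaminated is not None:
        bad |= contaminated.fillna(False).astype(bool)
    if "bhb_mmol_l" in records.columns:
        bad |= records["bhb_mmol_l"].isna()
    kept = records.loc[~bad].copy()
    return kept, int(bad.sum())


def classify_sck(bhb: float, threshold: float = DEFAULT_BHB_THRESHOLD) -> int:
    """Classify one BHB value: 1 (SCK) iff bhb >= threshold, else 0 (healthy)."""
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    if bhb is None or (isinstance(bhb, float) and np.isnan(bhb)):
        raise MissingDataError("record has no BHB measurement")
    return int(bhb >= threshold)


def add_sck_status(
    records: pd.DataFrame, threshold: float = DEFAULT_BHB_THRESHOLD
) -> pd.DataFrame:
    """Vectorized :func:`classify_sck`: adds a binary ``sck_status`` column."""
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    if records["bhb_mmol_l"].isna().any():
        missing = records.loc[records["bhb_mmol_l"].isna(), "animal_id"].tolist()
        raise MissingDataError(f"records without BHB cannot be classified: {missing}")
    out = records.copy()
    out["sck_status"] = (out["bhb_mmol_l"] >= threshold).astype(int)
    return out


def descriptives_by_lactation(records: pd.DataFrame) -> pd.DataFrame:
    """Per-lactation-group n, mean and sample SD of BHB and milk variables.

    Sample standard deviation uses the n-1 denominator; a group with a
    single non-missing value reports a missing SD. Missing values are
    excluded pairwise per variable.
    """
    rows = []
    for group, chunk in records.groupby("lactation_group", sort=True):
        for var in DESCRIPTIVE_VARIABLES:
            if var not in chunk.columns:
                continue
            values = chunk[var].dropna()
            rows.append(
                {
                    "lactation_group": group,
                    "variable": var,
                    "n": len(values),
                    "mean": values.mean() if len(values) else np.nan,
                    "sd": values.std(ddof=1) if len(values) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["lactation_group", "variable", "n", "mean", "sd"])


def assemble(
    records: pd.DataFrame, threshold: float = DEFAULT_BHB_THRESHOLD
) -> tuple[pd.DataFrame, int]:
    """Filter contaminated records then classify SCK; the analysis dataset."""
    kept, n_removed = filter_contaminated(records)
    return add_sck_status(kept, threshold), n_removed
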