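"""Genotype-by-ketosis contingency analysis.

Direct-count genotype and allele frequency estimation, the 2x3 Pearson
chi-square test of independence between ketosis status (0 healthy /
1 subclinical ketosis) and osteopontin genotype, Cohen's w effect size, and
sample-size-based power via the noncentral chi-square distribution.

The genotype column order is fixed as CT, CC, TT throughout, matching the
layout of the study's published contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateMarginError,
    EmptyTableError,
    IncompleteRecordError,
    ParameterError,
)

GENOTYPE_ORDER = ("CT", "CC", "TT")
STATUS_ORDER = (0, 1)  # healthy, SCK


@dataclass(frozen=True)
class GenotypeOutcomeTable:
    """2x3 counts of ketosis status (rows 0, 1) by genotype (CT, CC, TT)."""

    counts: np.ndarray  # shape (2, 3), int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 3):
            raise ParameterError(f"counts must be 2x3, got shape {counts.shape}")
        if (counts < 0).any():
            raise ParameterError("counts must be nonnegative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, status: int, genotype: str) -> int:
        return int(self.counts[STATUS_ORDER.index(status), GENOTYPE_ORDER.index(genotype)])

    def to_dataframe(self) -> pd.DataFrame:
        """Table with margins, mirroring the published layout."""
        df = pd.DataFrame(self.counts, index=["0", "1"], columns=list(GENOTYPE_ORDER))
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        df.index.name = "ketosis"
        return df


class ChisqResult(NamedTuple):
    statistic: float
    df: int
    p_value: float
    effect_size_w: float


def count_table(dataset: pd.DataFrame, status_col: str = "sck_status") -> GenotypeOutcomeTable:
    """Cross-tabulate classified, genotyped records into a 2x3 table.

    Raises
    ------
    IncompleteRecordError
        If any record lacks a genotype or a status; the error lists the
        offending animal IDs.
    """
    if len(dataset) == 0:
        return GenotypeOutcomeTable(np.zeros((2, 3), dtype=int))
    genotype = dataset.get("genotype")
    status = dataset.get(status_col)
    bad = pd.Series(True, index=dataset.index)
    if genotype is not None and status is not None:
        bad = genotype.isna() | ~genotype.isin(GENOTYPE_ORDER) | status.isna()
    if bad.any():
        ids = (
            dataset.loc[bad, "animal_id"].tolist()
            if "animal_id" in dataset.columns
            else dataset.index[bad].tolist()
        )
        raise IncompleteRecordError(
            f"{len(ids)} record(s) lack genotype or status", animal_ids=ids
        )
    counts = np.zeros((2, 3), dtype=int)
    for i, s in enumerate(STATUS_ORDER):
        for j, g in enumerate(GENOTYPE_ORDER):
            counts[i, j] = int(((status == s) & (genotype == g)).sum())
    return GenotypeOutcomeTable(counts)


def genotype_frequencies(table: GenotypeOutcomeTable) -> dict[str, float]:
    """Direct-count genotype frequencies: column totals over the grand total."""
    if table.total == 0:
        raise EmptyTableError("cannot estimate frequencies from an empty table")
    cols = table.col_totals / table.total
    return dict(zip(GENOTYPE_ORDER, map(float, cols)))


def allele_frequencies(table: GenotypeOutcomeTable) -> dict[str, float]:
    """Gene-counting allele frequencies: freq(C) = (2 n_CC + n_CT) / 2N."""
    if table.total == 0:
        raise EmptyTableError("cannot estimate frequencies from an empty table")
    n_ct, n_cc, _ = (int(x) for x in table.col_totals)
    freq_c = (2 * n_cc + n_ct) / (2 * table.total)
    return {"C": freq_c, "T": 1.0 - freq_c}


def chisq_independence(table: GenotypeOutcomeTable) -> ChisqResult:
    """Pearson chi-square test of independence, no continuity correction.

    Returns the statistic, df=2, the p-value, and Cohen's w = sqrt(chi2/N).
    """
    if table.total == 0:
        raise EmptyTableError("empty table")
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise DegenerateMarginError("a zero row/column margin makes the test undefined")
    statistic, p_value, df, _ = stats.chi2_contingency(table.counts, correction=False)
    w = float(np.sqrt(statistic / table.total))
    return ChisqResult(float(statistic), int(df), float(p_value), w)


def test_power(
    effect_size_w: float, n: int, alpha: float = 0.05, df: int = 2
) -> float:
    """Power of the chi-square independence test at effect size ``w``.

    Uses the noncentral chi-square distribution with noncentrality n * w**2:
    power = P(X > chi2_crit) for X ~ ncx2(df, n w^2). At w = 0 this reduces
    to alpha.
    """
    if effect_size_w < 0:
        raise ParameterError("effect size w must be >= 0")
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must lie strictly in (0, 1)")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    nc = n * effect_size_w**2
    return float(stats.ncx2.sf(crit, df, nc)) if nc > 0 else float(alpha)
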