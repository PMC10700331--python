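"""Model/Results interface to the candidate-gene association analysis.

`KetosisAssociation` bundles the full analytic chain — contingency table,
direct-count frequencies, chi-square test with power, Weight-of-Evidence
scoring with category merging, and ROC evaluation of the genotype-derived
predictor — behind a statsmodels-style pattern: build the model from data,
call :meth:`KetosisAssociation.fit`, read the
:class:`KetosisAssociationResults`.

>>> from ketogene.datasets import load_study_counts
>>> from ketogene.model import KetosisAssociation
>>> res = KetosisAssociation.from_counts(load_study_counts()).fit()
>>> round(res.woe_table["TT"].woe, 1)
145.3
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import association as assoc
from . import cohort as cohort_mod
from . import roc as roc_mod
from . import woe as woe_mod
from .association import ChisqResult, GenotypeOutcomeTable
from .datasets import expand_counts_to_records
from .roc import PredictorSpec, RocCurve
from .woe import WoETable


class KetosisAssociation:
    """Association model of a diallelic genotype with subclinical ketosis.

    Parameters
    ----------
    data
        Analysis dataset with ``genotype`` (CC/CT/TT) and a binary status
        column; use :meth:`from_cohort` to start from raw records with BHB
        instead.
    status_col
        Name of the binary ketosis column (1 = subclinical ketosis).
    """

    def __init__(self, data: pd.DataFrame, status_col: str = "sck_status"):
        self.data = data
        self.status_col = status_col
        self.n_removed: int | None = None

    @classmethod
    def from_cohort(
        cls,
        records: pd.DataFrame,
        bhb_threshold: float = cohort_mod.DEFAULT_BHB_THRESHOLD,
    ) -> "KetosisAssociation":
        """Build from raw cohort records: filter contamination, classify SCK."""
        dataset, n_removed = cohort_mod.assemble(records, threshold=bhb_threshold)
        model = cls(dataset)
        model.n_removed = n_removed
        return model

    @classmethod
    def from_counts(cls, table: GenotypeOutcomeTable) -> "KetosisAssociation":
        """Build from a 2x3 genotype-by-status counts table."""
        return cls(expand_counts_to_records(table))

    def fit(
        self,
        max_gap: float = 30.0,
        zero_cell_policy: str = "continuity",
        roc_mode: str = "probability",
        positive: str = "resistant",
        alpha: float = 0.05,
    ) -> "KetosisAssociationResults":
        """Run the full analysis and return the results object.

        ``max_gap`` is the WoE-unit threshold for pooling similar genotype
        categories; ``roc_mode``/``positive`` configure the ROC predictor
        (see :class:`ketogene.roc.PredictorSpec`).
        """
        table = assoc.count_table(self.data, status_col=self.status_col)
        genotype_freq = assoc.genotype_frequencies(table)
        allele_freq = assoc.allele_frequencies(table)
        chisq = assoc.chisq_independence(table)
        power = assoc.test_power(chisq.effect_size_w, table.total, alpha=alpha, df=chisq.df)
        woe_table = woe_mod.compute_woe(table, zero_cell_policy=zero_cell_policy)
        woe_merged = woe_mod.merge_similar(woe_table, max_gap=max_gap)
        iv = woe_mod.information_value(woe_table)

        spec = PredictorSpec(mode=roc_mode, positive=positive)
        scores, labels = roc_mod.build_scores(self.data, spec, woe_table, self.status_col)
        curve = roc_mod.roc_curve(scores, labels)

        return KetosisAssociationResults(
            model=self,
            table=table,
            genotype_freq=genotype_freq,
            allele_freq=allele_freq,
            chisq=chisq,
            power=power,
            alpha=alpha,
            woe_table=woe_table,
            woe_merged=woe_merged,
            information_value=iv,
            predictor_spec=spec,
            roc=curve,
            n_removed=self.n_removed,
        )


@dataclass
class KetosisAssociationResults:
    """Estimates, scores and diagnostics from a fitted association model."""

    model: KetosisAssociation
    table: GenotypeOutcomeTable
    genotype_freq: Mapping[str, float]
    allele_freq: Mapping[str, float]
    chisq: ChisqResult
    power: float
    alpha: float
    woe_table: WoETable
    woe_merged: WoETable
    information_value: float
    predictor_spec: PredictorSpec
    roc: RocCurve
    n_removed: int | None = None

    @property
    def n(self) -> int:
        return self.table.total

    def consistency_warnings(
        self, published_allele_freq: Mapping[str, float] | None = None
    ) -> list[str]:
        """Cross-checks between computed and externally reported figures."""
        warnings = []
        if published_allele_freq is not None:
            diff = abs(self.allele_freq["C"] - published_allele_freq["C"])
            if diff > 0.005:
                warnings.append(
                    "direct-count allele frequency C = "
                    f"{self.allele_freq['C']:.4f} differs from the reported "
                    f"{published_allele_freq['C']:.2f} (|diff| = {diff:.4f}); "
                    "gene counting on the published genotype counts does not "
                    "reproduce the published allele frequency"
                )
        return warnings

    def summary(self) -> str:
        """Plain-text summary of the fitted association."""
        lines = [
            "Genotype-ketosis association results",
            "=" * 52,
            f"animals analyzed            {self.n}",
        ]
        if self.n_removed is not None:
            lines.append(f"records removed (filter)    {self.n_removed}")
        lines += [
            "",
            "counts (status x genotype)  CT    CC    TT",
            "  healthy (0)             "
            + "".join(f"{self.table.cell(0, g):>6d}" for g in assoc.GENOTYPE_ORDER),
            "  SCK (1)                 "
            + "".join(f"{self.table.cell(1, g):>6d}" for g in assoc.GENOTYPE_ORDER),
            "",
            "genotype frequencies        "
            + "  ".join(f"{g} {f:.4f}" for g, f in self.genotype_freq.items()),
            "allele frequencies          "
            + "  ".join(f"{a} {f:.4f}" for a, f in self.allele_freq.items()),
            "",
            f"chi-square ({self.chisq.df} df)           "
            f"{self.chisq.statistic:.4f}  (p = {self.chisq.p_value:.4g})",
            f"Cohen's w                   {self.chisq.effect_size_w:.4f}",
            f"power (alpha = {self.alpha:g})        {self.power:.4f}",
            "",
            "Weight of Evidence (x100):",
        ]
        for e in self.woe_table.entries:
            lines.append(
                f"  {e.category:<6s} goods {e.goods:>4d}  bads {e.bads:>3d}  WoE {e.woe:>8.2f}"
            )
        lines.append("after merging (max_gap applied):")
        for e in self.woe_merged.entries:
            lines.append(f"  {e.category:<8s} WoE {e.woe:>8.2f}")
        lines += [
            f"information value           {self.information_value:.4f}",
            "",
            f"ROC ({self.predictor_spec.mode}, positive = {self.predictor_spec.positive}):",
            f"  AUC                       {self.roc.auc:.4f}",
            f"  optimal cutoff            {self.roc.optimal.threshold:.4f}",
            f"  sensitivity/specificity   {self.roc.optimal.sensitivity:.4f} / "
            f"{self.roc.optimal.specificity:.4f}",
        ]
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        """JSON-serializable bundle of every computed quantity."""
        return {
            "n": self.n,
            "n_removed": self.n_removed,
            "contingency_table": self.table.to_dataframe().to_dict(),
            "genotype_frequencies": dict(self.genotype_freq),
            "allele_frequencies": dict(self.allele_freq),
            "chi_square": {
                "statistic": self.chisq.statistic,
                "df": self.chisq.df,
                "p_value": self.chisq.p_value,
                "effect_size_w": self.chisq.effect_size_w,
            },
            "power": self.power,
            "alpha": self.alpha,
            "woe": self.woe_table.to_dataframe().to_dict(orient="records"),
            "woe_merged": self.woe_merged.to_dataframe().to_dict(orient="records"),
            "merge_log": list(self.woe_merged.merge_log),
            "information_value": self.information_value,
            "roc": {
                "mode": self.predictor_spec.mode,
                "positive": self.predictor_spec.positive,
                "auc": self.roc.auc,
                "optimal_threshold": self.roc.optimal.threshold,
                "optimal_sensitivity": self.roc.optimal.sensitivity,
                "optimal_specificity": self.roc.optimal.specificity,
                "optimal_distance": self.roc.optimal_distance,
            },
        }
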