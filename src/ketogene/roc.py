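"""ROC evaluation of genotype-derived predictors of ketosis resistance.

Scores can be the binary TT indicator, the per-animal Weight-of-Evidence
score, or a probability obtained by composing the cohort's baseline
log-odds of the positive class with the genotype's WoE on the natural-log
scale. By default the positive class is "resistant" (healthy, status 0),
matching the framing in which the TT genotype predicts absence of ketosis;
the orientation can be flipped to treat SCK as positive.

The curve sweeps thresholds over the distinct scores (ties pooled), with a
point at each threshold: sensitivity = TP/P and specificity = TN/N for the
rule "score >= threshold => predicted positive". AUC is the trapezoidal
area over (1 - specificity, sensitivity), which equals the Mann-Whitney
concordance probability on tie-pooled data. The optimal cutoff is the point
closest to the (0, 1) corner of the ROC plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateLabelsError, ParameterError
from .woe import WOE_SCALE, WoETable, woe_score

MODES = ("binary_TT", "woe_score", "probability")
ORIENTATIONS = ("resistant", "sck")


@dataclass(frozen=True)
class PredictorSpec:
    """Which per-animal score to build and which class counts as positive."""

    mode: str = "binary_TT"
    positive: str = "resistant"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.positive not in ORIENTATIONS:
            raise ParameterError(
                f"positive must be one of {ORIENTATIONS}, got {self.positive!r}"
            )


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def distance_to_corner(self) -> float:
        """Euclidean distance to (0, 1) in (1 - specificity, sensitivity)."""
        return math.hypot(1.0 - self.specificity, 1.0 - self.sensitivity)


@dataclass(frozen=True)
class RocCurve:
    """Threshold-swept ROC points (thresholds descending) with AUC and cutoff."""

    points: tuple[RocPoint, ...]
    auc: float
    optimal: RocPoint
    optimal_distance: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "threshold": p.threshold,
                    "sensitivity": p.sensitivity,
                    "specificity": p.specificity,
                }
                for p in self.points
            ]
        )


def build_scores(
    dataset: pd.DataFrame,
    spec: PredictorSpec,
    woe_table: WoETable | None = None,
    status_col: str = "sck_status",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal (score, label) pairs for ROC analysis.

    Labels are 1 for the positive class of ``spec`` (default: healthy /
    "resistant"). Scores:

    * ``binary_TT`` — indicator of the TT genotype;
    * ``woe_score`` — the animal's category WoE (requires ``woe_table``);
    * ``probability`` — sigmoid(baseline log-odds of the positive class +
      signed WoE/100), i.e. the WoE treated as a log-likelihood-ratio
      update of the cohort prevalence (requires ``woe_table``).
    """
    if len(dataset) == 0:
        raise ParameterError("dataset must be nonempty")
    if spec.mode in ("woe_score", "probability") and woe_table is None:
        raise ConfigurationError(f"mode {spec.mode!r} requires a WoE table")

    status = dataset[status_col].to_numpy()
    labels = (status == 0).astype(int) if spec.positive == "resistant" else (status == 1).astype(int)
    genotypes = dataset["genotype"].to_numpy()

    if spec.mode == "binary_TT":
        scores = (genotypes == "TT").astype(float)
    else:
        woe = np.array([woe_score(g, woe_table) for g in genotypes])
        # WoE is oriented toward health; flip it when SCK is the positive class
        signed = woe if spec.positive == "resistant" else -woe
        if spec.mode == "woe_score":
            scores = signed
        else:
            base_rate = labels.mean()
            if base_rate in (0.0, 1.0):
                raise DegenerateLabelsError("baseline odds undefined with one class")
            base_logodds = math.log(base_rate / (1.0 - base_rate))
            scores = 1.0 / (1.0 + np.exp(-(base_logodds + signed / WOE_SCALE)))
    return scores, labels


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Build the ROC curve of ``scores`` against binary ``labels``.

    One point per distinct score threshold plus the sweep end-points, so
    the curve runs from (sensitivity 0, specificity 1) at threshold +inf
    down to (sensitivity 1, specificity 0) once every animal is called
    positive. AUC is the trapezoidal area, identical to the Mann-Whitney
    concordance P(score_pos > score_neg) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("ROC needs both classes present")

    thresholds = np.unique(scores)[::-1]  # descending; ties pooled
    points = [RocPoint(threshold=math.inf, sensitivity=0.0, specificity=1.0)]
    for t in thresholds:
        called = scores >= t
        tp = int((called & (labels == 1)).sum())
        tn = int((~called & (labels == 0)).sum())
        points.append(
            RocPoint(threshold=float(t), sensitivity=tp / n_pos, specificity=tn / n_neg)
        )

    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    auc = float(np.trapezoid(tpr, fpr))

    optimal = optimal_cutoff(points)
    return RocCurve(
        points=tuple(points),
        auc=auc,
        optimal=optimal,
        optimal_distance=optimal.distance_to_corner,
    )


def optimal_cutoff(points) -> RocPoint:
    """The ROC point nearest the (0, 1) corner.

    Minimizes sqrt((1 - specificity)^2 + (1 - sensitivity)^2); exact ties go
    to the higher sensitivity, then to the higher threshold.
    """
    pts = list(points.points) if isinstance(points, RocCurve) else list(points)
    if not pts:
        raise ParameterError("curve has no points")
    return min(
        pts,
        key=lambda p: (p.distance_to_corner, -p.sensitivity, -p.threshold),
    )


def plot_roc(curve: RocCurve, path=None):
    """ROC plot with the chance diagonal and the optimal cutoff marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    fpr = [1.0 - p.specificity for p in curve.points]
    tpr = [p.sensitivity for p in curve.points]
    ax.plot(fpr, tpr, marker="o", ms=3, label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.plot(
        1.0 - curve.optimal.specificity,
        curve.optimal.sensitivity,
        marker="*",
        ms=12,
        color="tab:red",
        label="optimal cutoff",
    )
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
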