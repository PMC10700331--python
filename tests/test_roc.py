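"""ROC evaluation: curve construction, AUC concordance, optimal cutoff."""

import math

import numpy as np
import pytest

from ketogene.cohort import assemble
from ketogene.exceptions import (
    ConfigurationError,
    DegenerateLabelsError,
    ParameterError,
)
from ketogene.roc import (
    PredictorSpec,
    RocPoint,
    build_scores,
    optimal_cutoff,
    roc_curve,
)
from ketogene.simulate import SimulationConfig, simulate_cohort
from ketogene.woe import compute_woe
from ketogene.association import count_table
from ketogene.datasets import load_study_counts


def concordance_auc_oracle(scores, labels):
    """O(n^2) Mann-Whitney concordance: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def synthetic_dataset():
    cfg = SimulationConfig(n_animals=200, contamination_rate=0.0, seed=2023)
    dataset, _ = assemble(simulate_cohort(cfg).records)
    return dataset


class TestBuildScores:
    def test_binary_tt_indicator(self, study_records):
        scores, labels = build_scores(study_records, PredictorSpec("binary_TT"))
        assert set(np.unique(scores)) <= {0.0, 1.0}
        assert scores.sum() == 82  # TT animals
        assert labels.sum() == 928  # healthy are the positive class by default

    def test_probability_of_resistance_for_tt(self, study_records):
        """Baseline odds 928/49 composed with the TT WoE give ~0.988."""
        wt = compute_woe(count_table(study_records))
        scores, labels = build_scores(study_records, PredictorSpec("probability"), wt)
        tt_scores = scores[study_records["genotype"].to_numpy() == "TT"]
        expected = 1.0 / (1.0 + math.exp(-(math.log(928 / 49) + wt["TT"].woe / 100)))
        assert np.allclose(tt_scores, expected)
        assert tt_scores[0] == pytest.approx(0.9878, abs=5e-4)
        assert tt_scores[0] > 0.75  # the qualitative resistance claim

    def test_orientation_flip_reverses_ranking(self, study_records):
        wt = compute_woe(count_table(study_records))
        res, _ = build_scores(study_records, PredictorSpec("woe_score", "resistant"), wt)
        sck, _ = build_scores(study_records, PredictorSpec("woe_score", "sck"), wt)
        assert np.all(np.argsort(res) == np.argsort(-sck))

    def test_woe_modes_require_table(self, study_records):
        with pytest.raises(ConfigurationError):
            build_scores(study_records, PredictorSpec("probability"), None)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ParameterError):
            PredictorSpec(mode="nonsense")


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)
        assert curve.optimal.sensitivity == 1.0 and curve.optimal.specificity == 1.0
        assert curve.optimal_distance == 0.0

    def test_uninformative_scores_give_half(self):
        curve = roc_curve([0.5] * 10, [1, 0] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_endpoints_span_the_sweep(self):
        curve = roc_curve([0.2, 0.7, 0.4], [0, 1, 0])
        first, last = curve.points[0], curve.points[-1]
        assert (first.sensitivity, first.specificity) == (0.0, 1.0)
        assert (last.sensitivity, last.specificity) == (1.0, 0.0)

    def test_auc_equals_concordance_oracle_on_synthetic_cohort(self, synthetic_dataset):
        wt = compute_woe(count_table(synthetic_dataset))
        scores, labels = build_scores(synthetic_dataset, PredictorSpec("woe_score"), wt)
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(
            concordance_auc_oracle(scores, labels), abs=1e-12
        )

    def test_monotone_sweep(self, synthetic_dataset):
        wt = compute_woe(count_table(synthetic_dataset))
        scores, labels = build_scores(synthetic_dataset, PredictorSpec("probability"), wt)
        curve = roc_curve(scores, labels)
        sens = [p.sensitivity for p in curve.points]
        spec = [p.specificity for p in curve.points]
        assert sens == sorted(sens)  # thresholds descending => sens non-decreasing
        assert spec == sorted(spec, reverse=True)

    def test_binary_predictor_vertex_identity(self, study_records):
        """For a binary score the single interior vertex satisfies
        AUC = (sensitivity + specificity) / 2 analytically."""
        scores, labels = build_scores(study_records, PredictorSpec("binary_TT"))
        curve = roc_curve(scores, labels)
        interior = [p for p in curve.points if 0 < p.sensitivity < 1 or 0 < 1 - p.specificity < 1]
        vertex = [p for p in curve.points if p.threshold == 1.0][0]
        assert curve.auc == pytest.approx(
            (vertex.sensitivity + vertex.specificity) / 2, abs=1e-12
        )

    def test_auc_invariant_under_monotone_transform(self, synthetic_dataset):
        """woe_score and probability scores are monotone transforms of each
        other, so their ROC curves have identical AUC."""
        wt = compute_woe(count_table(synthetic_dataset))
        auc = {}
        for mode in ("woe_score", "probability"):
            scores, labels = build_scores(synthetic_dataset, PredictorSpec(mode), wt)
            auc[mode] = roc_curve(scores, labels).auc
        assert auc["woe_score"] == pytest.approx(auc["probability"], abs=1e-12)

    def test_sklearn_cross_check(self, synthetic_dataset):
        from sklearn.metrics import roc_auc_score

        wt = compute_woe(count_table(synthetic_dataset))
        scores, labels = build_scores(synthetic_dataset, PredictorSpec("probability"), wt)
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc_curve([0.1, 0.2], [1, 1])


class TestOptimalCutoff:
    def test_perfect_point_wins_with_zero_distance(self):
        points = [
            RocPoint(2.0, 0.0, 1.0),
            RocPoint(1.0, 1.0, 1.0),
            RocPoint(0.0, 1.0, 0.0),
        ]
        best = optimal_cutoff(points)
        assert (best.sensitivity, best.specificity) == (1.0, 1.0)

    def test_symmetric_tie_prefers_higher_sensitivity(self):
        points = [RocPoint(0.7, 0.9, 0.6), RocPoint(0.3, 0.6, 0.9)]
        assert optimal_cutoff(points).sensitivity == 0.9

    def test_full_tie_prefers_higher_threshold(self):
        points = [RocPoint(0.2, 0.8, 0.8), RocPoint(0.9, 0.8, 0.8)]
        assert optimal_cutoff(points).threshold == 0.9

    def test_agrees_with_exhaustive_scan(self, synthetic_dataset):
        wt = compute_woe(count_table(synthetic_dataset))
        scores, labels = build_scores(synthetic_dataset, PredictorSpec("probability"), wt)
        curve = roc_curve(scores, labels)
        brute = min(
            curve.points,
            key=lambda p: (
                math.hypot(1 - p.specificity, 1 - p.sensitivity),
                -p.sensitivity,
                -p.threshold,
            ),
        )
        assert curve.optimal == brute

    def test_empty_curve_rejected(self):
        with pytest.raises(ParameterError):
            optimal_cutoff([])
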