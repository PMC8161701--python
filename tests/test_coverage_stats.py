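"""Metric oracles, replicate aggregation, gain curves, significance protocol."""

import math

import numpy as np
import pandas as pd
import pytest

from octcov.coverage_stats import (
    aggregate,
    aupr,
    auroc,
    build_gain_curve,
    compare_to_baseline,
    diminishing_return,
    percent_gain,
    running_average,
)
from octcov.errors import (
    ConfigurationError,
    FlatCurveError,
    IncompleteReplicatesError,
    UndefinedMetricError,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def pairwise_auroc_oracle(scores, labels):
    """Brute force over all positive x negative pairs, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def threshold_sweep_aupr_oracle(scores, labels):
    """Step-curve area from a descending sweep over distinct thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = labels.sum()
    area = 0.0
    recall_prev = 0.0
    for t in sorted(set(scores), reverse=True):
        kept = scores >= t
        precision = labels[kept].sum() / kept.sum()
        recall = labels[kept].sum() / n_pos
        area += (recall - recall_prev) * precision
        recall_prev = recall
    return area


def _random_instance(rng):
    n = int(rng.integers(5, 201))
    if rng.random() < 0.5:  # tie-rich discrete scores
        scores = rng.integers(0, 6, size=n).astype(float) / 5.0
    else:
        scores = rng.random(n)
    labels = rng.random(n) < rng.uniform(0.15, 0.85)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return scores, labels


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([0.5, 0.5], [1, 0]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            scores, labels = _random_instance(rng)
            assert auroc(scores, labels) == pytest.approx(
                pairwise_auroc_oracle(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])


class TestAupr:
    def test_perfect_ranking_any_prevalence(self):
        assert aupr([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 0, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        assert aupr([0.3] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.3)

    def test_matches_threshold_sweep_oracle_on_random_instances(self):
        rng = np.random.default_rng(777)
        for _ in range(100):
            scores, labels = _random_instance(rng)
            assert aupr(scores, labels) == pytest.approx(
                threshold_sweep_aupr_oracle(scores, labels), abs=1e-12)

    def test_no_positive_undefined(self):
        with pytest.raises(UndefinedMetricError):
            aupr([0.1, 0.2], [0, 0])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _runs_frame(values_by_model, diseases=("AMD",)):
    rows = []
    for disease in diseases:
        for m, values in values_by_model.items():
            for run, v in enumerate(values, start=1):
                rows.append({"model_index": m, "run": run, "disease": disease,
                             "auroc": v, "aupr": v / 2})
    return pd.DataFrame(rows)


class TestAggregate:
    def test_constant_runs_zero_standard_error(self):
        out = aggregate(_runs_frame({1: [0.7, 0.7, 0.7]}), n_runs=3)
        row = out[(out["metric"] == "auroc")].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["se"] == pytest.approx(0.0)

    def test_two_run_example(self):
        out = aggregate(_runs_frame({1: [0.8, 0.9]}), n_runs=2)
        row = out[(out["metric"] == "auroc")].iloc[0]
        assert row["mean"] == pytest.approx(0.85)
        assert row["se"] == pytest.approx(0.05, abs=1e-10)  # sd(0.8,0.9)/sqrt(2)

    def test_matches_direct_formula(self, rng):
        values = rng.random(10)
        out = aggregate(_runs_frame({4: list(values)}), n_runs=10)
        row = out[(out["metric"] == "auroc")].iloc[0]
        assert row["mean"] == pytest.approx(values.mean(), abs=1e-12)
        assert row["se"] == pytest.approx(values.std(ddof=1) / math.sqrt(10),
                                          abs=1e-12)

    def test_missing_runs_listed(self):
        frame = _runs_frame({1: [0.7, 0.8], 2: [0.6]})
        with pytest.raises(IncompleteReplicatesError, match="2"):
            aggregate(frame, n_runs=2)


# ---------------------------------------------------------------------------
# gain curves
# ---------------------------------------------------------------------------


class TestPercentGain:
    def test_endpoints_exact(self):
        g = percent_gain([0.9556, 0.96, 0.97, 0.9718])
        assert g[0] == 0.0 and g[-1] == 100.0

    def test_interior_equal_to_baseline_is_zero(self):
        g = percent_gain([0.5, 0.5, 0.9])
        assert g[1] == 0.0

    def test_linear_ramp_maps_to_linear_percent(self):
        x = 0.6 + 0.01 * np.arange(11)
        assert np.allclose(percent_gain(x), np.linspace(0, 100, 11))

    def test_gain_may_leave_the_unit_range(self):
        g = percent_gain([0.5, 0.95, 0.4, 0.6])
        assert g[1] > 100.0 and g[2] < 0.0

    def test_flat_curve_rejected(self):
        with pytest.raises(FlatCurveError):
            percent_gain([0.7, 0.8, 0.7])


class TestDiminishingReturn:
    def test_trailing_window_arithmetic(self):
        g = np.array([0.0] + [100.0] * 9)
        s = running_average(g, 3)
        assert s[1] == pytest.approx(50.0)
        assert s[2] == pytest.approx(200 / 3)
        assert s[3] == pytest.approx(100.0)
        m, cov = diminishing_return(g)
        assert m == 4
        assert cov == pytest.approx(0.75)

    def test_monotone_curve_reaching_100_late(self):
        # trailing averages: s(8) = (85+88+90)/3 < 90 while s(9) = 92.67
        g = np.array([0, 20, 40, 60, 75, 85, 88, 90, 100], dtype=float)
        m, _ = diminishing_return(g)
        assert m == len(g)  # only the last model clears the smoothed threshold

    def test_jump_at_final_model_leaves_dr_undefined(self):
        g = np.array([0.0] * 9 + [100.0])
        assert diminishing_return(g) == (None, None)

    def test_window_larger_than_curve_rejected(self):
        with pytest.raises(ConfigurationError):
            diminishing_return([0.0, 100.0], window=3)


# ---------------------------------------------------------------------------
# significance protocol
# ---------------------------------------------------------------------------


class TestCompareToBaseline:
    def test_fully_separated_ten_vs_ten(self):
        model = np.linspace(0.8, 0.9, 10)
        base = np.linspace(0.5, 0.6, 10)
        p_raw, p_adj, significant = compare_to_baseline(model, base)
        assert p_raw == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
        assert p_adj == pytest.approx(180 / math.comb(20, 10), rel=1e-9)
        assert significant

    def test_three_vs_three_cannot_survive_bonferroni(self):
        p_raw, p_adj, significant = compare_to_baseline(
            [0.9, 0.91, 0.92], [0.1, 0.11, 0.12])
        assert p_raw == pytest.approx(1 / math.comb(6, 3))  # 0.05 exactly
        assert p_adj == 1.0
        assert not significant

    def test_identical_constant_samples_never_significant(self):
        p_raw, p_adj, significant = compare_to_baseline([0.5] * 5, [0.5] * 5)
        assert p_raw == 0.5
        assert not significant

    def test_model_below_baseline_large_p(self):
        p_raw, _, significant = compare_to_baseline(
            [0.1, 0.2, 0.3, 0.25], [0.7, 0.8, 0.9, 0.85])
        assert p_raw > 0.9
        assert not significant

    def test_small_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_to_baseline([0.5], [0.4, 0.6])


class TestBuildGainCurve:
    def test_curve_assembles_all_fields(self, rng):
        bases = [0.6, 0.7, 0.78, 0.8, 0.8]  # saturating mean curve
        rows = []
        for m, base in enumerate(bases, start=1):
            for run in range(1, 4):
                rows.append({"model_index": m, "run": run, "disease": "AMD",
                             "auroc": base + 0.01 * run,
                             "aupr": base - 0.02 + 0.01 * run})
        curve = build_gain_curve("AMD", "auroc", pd.DataFrame(rows), n_runs=3,
                                 n_comparisons=24)
        assert curve.gain[0] == 0.0 and curve.gain[-1] == 100.0
        assert np.isnan(curve.p_raw[0]) and not np.isnan(curve.p_raw[1:]).any()
        # g = [0, 50, 90, 100, 100] -> trailing s clears 90 at the last model
        assert curve.dr_model_index == 5
        assert curve.dr_coverage_mm == pytest.approx(1.0)
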