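"""Gain-curve statistics for incremental-coverage experiments.

Per disease and metric (AUROC, AUPR) the pipeline produces one value per
(coverage model, run).  This module aggregates the R runs per model into a
mean and standard error (sd/√R), normalizes the mean curve to percent gain
g(m) = 100·(x(m) − x(1)) / (x(M) − x(1)) so that g(1) = 0 and g(M) = 100
exactly, smooths g with a trailing three-model running average s(m), and
reports the point of diminishing return: the smallest m with s(m) ≥ 90% of
the full-coverage gain.  Each non-baseline model is compared with the
baseline (model 1) by a one-tailed two-sample Wilcoxon rank-sum test with a
Bonferroni correction (180 for the default 31-model, 3-disease, 2-metric
design).

AUROC is the Mann–Whitney statistic (ties counted ½); AUPR is the area under
the precision–recall step curve swept over descending score thresholds, both
computed via scikit-learn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort_assembly import CoverageModelSpec
from .errors import (
    ConfigurationError,
    FlatCurveError,
    IncompleteReplicatesError,
    UndefinedMetricError,
)

METRICS = ("auroc", "aupr")

#: Largest per-group size for which the exact rank-sum null is used.
EXACT_WILCOXON_MAX_N = 12


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability that a random positive outranks a random negative.

    Ties count one half (Mann–Whitney identity).  Raises if only one class is
    present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ConfigurationError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(np.clip(roc_auc_score(y, s), 0.0, 1.0))


def aupr(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision–recall step curve (descending thresholds).

    Equals Σ (R_k − R_{k−1})·P_k over distinct score thresholds; a constant
    scorer yields the positive prevalence.  Raises without any positive.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ConfigurationError("scores and labels must have equal length")
    if not y.any():
        raise UndefinedMetricError("AUPR undefined: no positive instances")
    return float(np.clip(average_precision_score(y, s), 0.0, 1.0))


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


def aggregate(run_results: pd.DataFrame, n_runs: int) -> pd.DataFrame:
    """Mean and standard error per (model_index, disease, metric).

    ``run_results`` is a long table with columns model_index, run, disease,
    auroc, aupr.  Every (model, disease) cell must carry exactly ``n_runs``
    runs; gaps raise with the missing cells listed.  SE = sample sd / √R.
    """
    if n_runs < 2:
        raise ConfigurationError("need at least 2 runs to compute a standard error")
    required = {"model_index", "run", "disease", "auroc", "aupr"}
    missing_cols = required - set(run_results.columns)
    if missing_cols:
        raise ConfigurationError(f"run_results missing columns {sorted(missing_cols)}")
    counts = run_results.groupby(["model_index", "disease"])["run"].nunique()
    gaps = counts[counts != n_runs]
    if len(gaps):
        raise IncompleteReplicatesError(
            f"expected {n_runs} runs per cell; incomplete cells: "
            f"{sorted(gaps.index.tolist())}"
        )
    long = run_results.melt(
        id_vars=["model_index", "run", "disease"],
        value_vars=list(METRICS), var_name="metric", value_name="value",
    )
    out = long.groupby(["model_index", "disease", "metric"])["value"].agg(
        mean="mean", sd=lambda v: v.std(ddof=1),
    ).reset_index()
    out["se"] = out["sd"] / math.sqrt(n_runs)
    return out.drop(columns="sd")


# ---------------------------------------------------------------------------
# gain curves and diminishing return
# ---------------------------------------------------------------------------


def percent_gain(means: Sequence[float]) -> np.ndarray:
    """Normalize a mean metric curve to percent gain: g(1)=0, g(M)=100."""
    x = np.asarray(means, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("means must be a 1-D sequence over models 1..M")
    span = x[-1] - x[0]
    if span == 0.0:
        raise FlatCurveError("first and last model means are equal; gain undefined")
    g = 100.0 * (x - x[0]) / span
    g[0], g[-1] = 0.0, 100.0  # exact endpoints by construction
    return g


def running_average(g: Sequence[float], window: int = 3) -> np.ndarray:
    """Trailing running mean over {m−window+1, …, m}, truncated at the left."""
    g = np.asarray(g, dtype=float)
    return np.array([g[max(0, i - window + 1):i + 1].mean() for i in range(len(g))])


def diminishing_return(g: Sequence[float], window: int = 3,
                       threshold: float = 90.0,
                       scan_spacing_mm: float = 0.125,
                       ) -> tuple[int | None, float | None]:
    """Smallest model whose smoothed gain reaches the threshold.

    Smooths ``g`` (indexed by model 1..M) with a trailing ``window``-model
    average and returns ``(model_index, coverage_mm)`` for the first model
    with s(m) ≥ threshold, or ``(None, None)`` if no model qualifies.  The
    threshold is a percentage of the full-coverage (last-model) gain, which
    the normalization fixes at 100.
    """
    g = np.asarray(g, dtype=float)
    if window > len(g):
        raise ConfigurationError("window larger than the number of models")
    s = running_average(g, window)
    hits = np.flatnonzero(s >= threshold)
    if len(hits) == 0:
        return None, None
    m = int(hits[0]) + 1
    spec = CoverageModelSpec(m, n_bscans=2 * len(g) - 1, scan_spacing_mm=scan_spacing_mm)
    return m, spec.coverage_mm


# ---------------------------------------------------------------------------
# significance protocol
# ---------------------------------------------------------------------------


def compare_to_baseline(model_runs: Sequence[float], baseline_runs: Sequence[float],
                        n_comparisons: int = 180) -> tuple[float, float, bool]:
    """One-tailed two-sample Wilcoxon rank-sum: model > baseline.

    Uses the exact null distribution when both groups have ≤ 12 values and no
    ties straddle the samples, else the tie-corrected normal approximation.
    Returns (p_raw, Bonferroni-adjusted p, significant at 0.05).
    """
    x = np.asarray(model_runs, dtype=float)
    y = np.asarray(baseline_runs, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("both samples need at least 2 values")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        p_raw = 0.5  # identical constant samples carry no ordering evidence
    else:
        has_ties = len(np.unique(combined)) < len(combined)
        method = ("exact" if not has_ties
                  and len(x) <= EXACT_WILCOXON_MAX_N
                  and len(y) <= EXACT_WILCOXON_MAX_N else "asymptotic")
        p_raw = float(stats.mannwhitneyu(x, y, alternative="greater",
                                         method=method).pvalue)
    p_adjusted = min(1.0, p_raw * n_comparisons)
    return p_raw, p_adjusted, p_adjusted < 0.05


# ---------------------------------------------------------------------------
# curve bundle
# ---------------------------------------------------------------------------


@dataclass
class GainCurve:
    """Run-aggregated curve for one (disease, metric) with its DR point."""

    disease: str
    metric: str
    model_indices: np.ndarray
    means: np.ndarray
    ses: np.ndarray
    gain: np.ndarray
    smoothed: np.ndarray
    p_raw: np.ndarray        # NaN for the baseline model
    p_adjusted: np.ndarray
    significant: np.ndarray
    dr_model_index: int | None
    dr_coverage_mm: float | None


def build_gain_curve(disease: str, metric: str, runs: pd.DataFrame,
                     n_runs: int, n_comparisons: int = 180,
                     window: int = 3, threshold: float = 90.0,
                     scan_spacing_mm: float = 0.125) -> GainCurve:
    """Assemble one GainCurve from the long (model_index, run, value) table."""
    sub = runs[runs["disease"] == disease]
    agg = aggregate(sub, n_runs)
    agg = agg[agg["metric"] == metric].sort_values("model_index")
    models = agg["model_index"].to_numpy()
    means = agg["mean"].to_numpy()
    ses = agg["se"].to_numpy()
    g = percent_gain(means)
    window = min(window, len(g))  # short smoke curves: truncated smoothing
    s = running_average(g, window)
    dr_m, dr_mm = diminishing_return(g, window, threshold, scan_spacing_mm)

    baseline = sub[sub["model_index"] == models[0]].sort_values("run")[metric].to_numpy()
    p_raw = np.full(len(models), np.nan)
    p_adj = np.full(len(models), np.nan)
    sig = np.zeros(len(models), dtype=bool)
    for i, m in enumerate(models[1:], start=1):
        vals = sub[sub["model_index"] == m].sort_values("run")[metric].to_numpy()
        p_raw[i], p_adj[i], sig[i] = compare_to_baseline(vals, baseline, n_comparisons)
    return GainCurve(disease, metric, models, means, ses, g, s,
                     p_raw, p_adj, sig, dr_m, dr_mm)
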