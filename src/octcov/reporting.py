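"""Figures and text reports for a coverage experiment bundle.

Two figure families mirror the standard presentation of coverage-utility
results: percent-gain curves per metric (three diseases overlaid, standard
error bars, significance asterisks, shaded pre-diminishing-return region) and
ROC/PR curve families coloured on a blue→red scale from least to most
coverage.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from sklearn.metrics import precision_recall_curve, roc_curve  # noqa: E402

from .cohort_assembly import DISEASES, CoverageModelSpec  # noqa: E402
from .coverage_stats import METRICS  # noqa: E402
from .errors import DataError  # noqa: E402
from .experiment import ExperimentResult  # noqa: E402

_DISEASE_COLORS = {"AMD": "#1f77b4", "DME": "#ff7f0e", "POAG": "#2ca02c"}


def _coverages(result: ExperimentResult) -> np.ndarray:
    gen = result.config.generator
    return np.array([
        CoverageModelSpec(m, gen.n_bscans, gen.scan_spacing_mm).coverage_mm
        for m in range(1, result.config.n_models + 1)
    ])


def _check_complete(result: ExperimentResult) -> None:
    missing = [key for key in ((d, m) for d in DISEASES for m in METRICS)
               if key not in result.curves]
    if missing:
        raise DataError(f"results bundle incomplete; missing cells: {missing}")


def gain_figure(result: ExperimentResult, metric: str, path: str | Path) -> Path:
    """Percent-gain curves for one metric, all diseases overlaid."""
    _check_complete(result)
    cov = _coverages(result)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    captions = []
    for disease in DISEASES:
        curve = result.curve(disease, metric)
        color = _DISEASE_COLORS[disease]
        span = curve.means[-1] - curve.means[0]
        se_pct = 100.0 * curve.ses / abs(span)
        ax.errorbar(cov, curve.gain, yerr=se_pct, color=color, marker="o",
                    markersize=3, linewidth=1.2, capsize=2, label=disease)
        for x, g, sig in zip(cov, curve.gain, curve.significant):
            if sig:
                ax.annotate("*", (x, g), textcoords="offset points",
                            xytext=(0, 6), ha="center", color=color, fontsize=8)
        if curve.dr_coverage_mm is not None:
            ax.axvspan(0, curve.dr_coverage_mm, color=color, alpha=0.06)
            ax.axvline(curve.dr_coverage_mm, color=color, linestyle=":",
                       linewidth=1)
        else:
            captions.append(f"{disease}: no diminishing-return point")
    ax.axhline(90, color="gray", linestyle="--", linewidth=0.8)
    ax.set_xlabel("macular coverage (mm)")
    ax.set_ylabel(f"percent gain in {metric.upper()} (%)")
    title = f"{metric.upper()} gain vs coverage"
    if captions:
        title += " — " + "; ".join(captions)
    ax.set_title(title, fontsize=10)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def curve_family_figure(result: ExperimentResult, kind: str, path: str | Path) -> Path:
    """ROC or PR curve families coloured from least (blue) to most (red) coverage."""
    _check_complete(result)
    if not result.test_scores:
        raise DataError("results bundle holds no test scores (cached reload?)")
    cov = _coverages(result)
    cmap = plt.get_cmap("coolwarm")
    fig, axes = plt.subplots(1, len(DISEASES), figsize=(12, 4), sharey=True)
    for ax, disease in zip(np.atleast_1d(axes), DISEASES):
        j = DISEASES.index(disease)
        for i, m in enumerate(sorted(result.test_scores)):
            y, probs = result.test_scores[m]
            color = cmap(i / max(len(result.test_scores) - 1, 1))
            if kind == "roc":
                fpr, tpr, _ = roc_curve(y[:, j], probs[:, j])
                ax.plot(fpr, tpr, color=color, linewidth=0.8)
            else:
                prec, rec, _ = precision_recall_curve(y[:, j], probs[:, j])
                ax.plot(rec, prec, color=color, linewidth=0.8)
        ax.set_title(disease)
        ax.set_xlabel("FPR" if kind == "roc" else "recall")
    np.atleast_1d(axes)[0].set_ylabel("TPR" if kind == "roc" else "precision")
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=plt.Normalize(cov.min(), cov.max()))
    fig.colorbar(sm, ax=list(np.atleast_1d(axes)), label="coverage (mm)",
                 shrink=0.85)
    fig.suptitle(f"{kind.upper()} curves by coverage")
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_figures(result: ExperimentResult, out_dir: str | Path) -> list[Path]:
    """Write the gain and curve-family figures; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [
        gain_figure(result, "auroc", out_dir / "gain_auroc.png"),
        gain_figure(result, "aupr", out_dir / "gain_aupr.png"),
    ]
    if result.test_scores:
        paths.append(curve_family_figure(result, "roc", out_dir / "roc_family.png"))
        paths.append(curve_family_figure(result, "pr", out_dir / "pr_family.png"))
    return paths


def text_report(result: ExperimentResult) -> str:
    """Compact human-readable summary of the bundle."""
    lines = [
        f"coverage models: {result.config.n_models}   runs per model: "
        f"{result.config.n_runs}   total fits: {result.n_fits}",
        f"Bonferroni comparisons: {result.config.n_comparisons}",
        "",
    ]
    for disease in DISEASES:
        for metric in METRICS:
            c = result.curve(disease, metric)
            dr = ("none" if c.dr_coverage_mm is None
                  else f"model {c.dr_model_index} ({c.dr_coverage_mm:.2f} mm)")
            lines.append(
                f"{disease:5s} {metric.upper():5s}  baseline {c.means[0]:.4f}  "
                f"full {c.means[-1]:.4f}  DR {dr}  "
                f"significant models: {int(c.significant.sum())}/{len(c.means) - 1}"
            )
    return "\n".join(lines)
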