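"""Eye-level feature assembly and the random-forest fusion stage.

For coverage model m, the per-B-scan embeddings of the central 2m−1 scans are
concatenated in ascending index order and padded symmetrically with exact 0.0
to a fixed total length K_max × d (61 × 256 = 15,616 by default), so every
model's forest sees vectors of identical dimension and the embedding of scan
index i always lands in the same columns.  One multi-output random forest per
(model, run) then maps the padded vector to three per-disease probabilities in
[0, 1] (not constrained to sum to 1: an eye may carry several diagnoses).

Hyperparameters are chosen by randomized search over a conventional space with
patient-grouped K-fold cross-validation (the grouping prevents visits of one
patient from straddling folds).  The held-out test subset is only ever touched
by :func:`predict`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, ParameterSampler

from .cohort_assembly import CoverageModelSpec
from .errors import ConfigurationError, DataError, EligibilityError, ShapeError

DEFAULT_SEARCH_SPACE: dict = {
    "n_estimators": [100, 200, 400, 800],
    "max_depth": [None, 8, 16, 32],
    "min_samples_leaf": [1, 2, 4, 8],
    "max_features": ["sqrt", 0.1, 0.3],
}


@dataclass(frozen=True)
class ForestConfig:
    """Randomized-search budget and space for the forest stage.

    ``fixed_params`` short-circuits the search with a single explicit
    hyperparameter set (used by light simulation/smoke profiles).
    """

    n_candidates: int = 25
    cv_folds: int = 5
    search_space: Mapping = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    fixed_params: Mapping | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.n_candidates < 1:
            raise ConfigurationError("n_candidates must be >= 1")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def assemble_feature(embeddings: np.ndarray | Sequence[np.ndarray],
                     spec: CoverageModelSpec, d: int, k_max: int) -> np.ndarray:
    """Concatenate a visit's window embeddings and zero-pad to K_max × d.

    ``embeddings`` must hold exactly ``spec.scan_count`` vectors of length
    ``d`` in ascending B-scan index order.  The data block is centred: both
    pads have length (K_max − scan_count) × d / 2 and value exactly 0.0; for
    the full-coverage model no padding occurs.
    """
    arr = np.asarray(embeddings, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != spec.scan_count:
        raise EligibilityError(
            f"model {spec.model_index} needs {spec.scan_count} embeddings, "
            f"got array of shape {arr.shape}"
        )
    if arr.shape[1] != d:
        raise ShapeError(f"embedding length {arr.shape[1]} != d={d}")
    if k_max < spec.scan_count or k_max % 2 == 0:
        raise ConfigurationError(f"k_max={k_max} must be odd and >= scan_count")
    pad = (k_max - spec.scan_count) * d // 2
    out = np.zeros(k_max * d, dtype=np.float64)
    out[pad:pad + spec.scan_count * d] = arr.ravel()
    return out


def assemble_features(visit_embeddings: Sequence[np.ndarray],
                      spec: CoverageModelSpec, d: int, k_max: int) -> np.ndarray:
    """Stack :func:`assemble_feature` over visits into an (n, K_max·d) matrix."""
    return np.stack([assemble_feature(e, spec, d, k_max) for e in visit_embeddings])


# ---------------------------------------------------------------------------
# forest stage
# ---------------------------------------------------------------------------


class ForestModel:
    """A fitted multi-label forest plus degenerate-class fallbacks.

    Diseases whose training labels are single-class cannot be ranked by a
    forest; they are flagged degenerate and predicted as a constant equal to
    the training prevalence (0.0 or 1.0).
    """

    def __init__(self, forest: RandomForestClassifier | None,
                 active: np.ndarray, constants: np.ndarray,
                 n_features: int, params: dict, seed: int):
        self._forest = forest
        self.active = active            # (3,) bool: disease fitted by the forest
        self.constants = constants      # (3,) float: fallback probabilities
        self.n_features = n_features
        self.params = params
        self.seed = seed

    @property
    def degenerate(self) -> np.ndarray:
        return ~self.active

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Per-visit probability triples, each value in [0, 1]."""
        x = np.asarray(features, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_features:
            raise ShapeError(
                f"feature length {x.shape[1]} != training length {self.n_features}"
            )
        out = np.tile(self.constants, (x.shape[0], 1))
        if self._forest is not None:
            proba = self._forest.predict_proba(x)
            if isinstance(proba, list):
                classes_list = self._forest.classes_
            else:
                proba = [proba]
                classes_list = [self._forest.classes_]
            for k, col in enumerate(np.flatnonzero(self.active)):
                pos = list(classes_list[k]).index(1)
                out[:, col] = proba[k][:, pos]
        return out

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "params": {k: (v if not isinstance(v, np.generic) else v.item())
                       for k, v in self.params.items()},
            "n_features": self.n_features,
            "degenerate_diseases": [int(i) for i in np.flatnonzero(self.degenerate)],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2, default=str))

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model (joblib) with a sidecar JSON manifest."""
        import joblib

        path = Path(path)
        joblib.dump(self, path)
        self.save_manifest(path.with_suffix(".json"))

    @staticmethod
    def load(path: str | Path) -> "ForestModel":
        import joblib

        return joblib.load(path)


def _cv_score(params: dict, x: np.ndarray, y: np.ndarray,
              groups: np.ndarray, folds: int, seed: int) -> float:
    """Mean AUROC over diseases and patient-grouped folds (NaN-safe)."""
    splitter = GroupKFold(n_splits=folds)
    scores = []
    for train_idx, val_idx in splitter.split(x, y, groups):
        cols = [j for j in range(y.shape[1])
                if len(np.unique(y[train_idx][:, j])) == 2]
        if not cols:
            continue
        forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        forest.fit(x[train_idx], y[train_idx][:, cols] if len(cols) > 1
                   else y[train_idx][:, cols[0]])
        proba = forest.predict_proba(x[val_idx])
        if isinstance(proba, list):
            classes_list = forest.classes_
        else:
            proba = [proba]
            classes_list = [forest.classes_]
        for k, j in enumerate(cols):
            yv = y[val_idx][:, j]
            if len(np.unique(yv)) < 2:
                continue
            pos = list(classes_list[k]).index(1)
            scores.append(roc_auc_score(yv, proba[k][:, pos]))
    return float(np.mean(scores)) if scores else np.nan


def train_forest(features: np.ndarray, labels: np.ndarray,
                 config: ForestConfig,
                 groups: Sequence | None = None) -> ForestModel:
    """Fit the fused multi-label forest for one (model, run) cell.

    Randomized search draws ``n_candidates`` hyperparameter sets and keeps the
    one with the best patient-grouped cross-validation AUROC, then refits on
    all rows.  Deterministic for a given ``config.seed``.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) == 0:
        raise DataError("features must be a non-empty (n, L) matrix")
    if y.shape != (len(x), 3):
        raise DataError(f"labels must be (n, 3), got {y.shape}")

    active = np.array([len(np.unique(y[:, j])) == 2 for j in range(3)])
    constants = y.mean(axis=0)
    if not active.any():
        return ForestModel(None, active, constants, x.shape[1], {}, config.seed)

    y_active = y[:, active]
    group_arr = (np.asarray(groups) if groups is not None
                 else np.arange(len(x)))

    if config.fixed_params is not None:
        best_params = dict(config.fixed_params)
    else:
        candidates = list(ParameterSampler(
            dict(config.search_space), n_iter=config.n_candidates,
            random_state=config.seed,
        ))
        n_groups = len(np.unique(group_arr))
        folds = min(config.cv_folds, n_groups)
        if len(candidates) == 1 or folds < 2:
            best_params = candidates[0]
        else:
            scored = [
                (_cv_score(params, x, y, group_arr, folds, config.seed), i, params)
                for i, params in enumerate(candidates)
            ]
            scored = [s for s in scored if np.isfinite(s[0])]
            if not scored:
                best_params = candidates[0]
            else:
                best_params = max(scored, key=lambda s: (s[0], -s[1]))[2]

    forest = RandomForestClassifier(random_state=config.seed, n_jobs=1, **best_params)
    forest.fit(x, y_active if active.sum() > 1 else y_active.ravel())
    return ForestModel(forest, active, constants, x.shape[1], best_params, config.seed)


def predict(model: ForestModel, features: np.ndarray) -> np.ndarray:
    """Per-visit (p_AMD, p_DME, p_POAG) probabilities from a fitted forest."""
    return model.predict(features)
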