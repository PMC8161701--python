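"""Labelling, splitting and completeness rules for coverage experiments.

Turns a cohort of patients into the per-coverage-model train/validation/test
datasets used by the ensemble stage: forward-propagates the chronic (AMD)
label over each patient's visit history, splits patients 60:20:20 at the
patient level (all visits of a patient stay in one subset), enumerates the
coverage models (model m uses the central 2m−1 B-scans, spanning
(m−1)·0.25 mm at the default 0.125 mm spacing), and keeps for each model only
the visits whose raster set fully covers its index window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synthetic_data import DISEASES, FORWARD_PROPAGATED, PatientRecord, ScanSet

__all__ = [
    "DISEASES",
    "PatientRecord",
    "ScanSet",
    "CoverageModelSpec",
    "SplitAssignment",
    "coverage_model_specs",
    "propagate_disease_labels",
    "split_patients",
    "eligible_visits",
]

SUBSETS = ("train", "validation", "test")


@dataclass(frozen=True)
class CoverageModelSpec:
    """Coverage model m: the central ``2m−1`` B-scans of a raster set."""

    model_index: int
    n_bscans: int = 61
    scan_spacing_mm: float = 0.125

    def __post_init__(self) -> None:
        max_m = (self.n_bscans + 1) // 2
        if not (1 <= self.model_index <= max_m):
            raise ConfigurationError(
                f"model_index must be in [1, {max_m}], got {self.model_index}"
            )

    @property
    def center_index(self) -> int:
        return (self.n_bscans - 1) // 2

    @property
    def scan_count(self) -> int:
        return 2 * self.model_index - 1

    @property
    def index_window(self) -> range:
        half = self.model_index - 1
        return range(self.center_index - half, self.center_index + half + 1)

    @property
    def coverage_mm(self) -> float:
        return (self.scan_count - 1) * self.scan_spacing_mm


def coverage_model_specs(n_models: int = 31, n_bscans: int = 61,
                         scan_spacing_mm: float = 0.125) -> list[CoverageModelSpec]:
    """Enumerate specs m = 1..n_models (31 models for a 61-scan protocol)."""
    if n_models > (n_bscans + 1) // 2:
        raise ConfigurationError(
            f"n_models={n_models} exceeds (n_bscans+1)/2 for n_bscans={n_bscans}"
        )
    return [CoverageModelSpec(m, n_bscans, scan_spacing_mm) for m in range(1, n_models + 1)]


# ---------------------------------------------------------------------------
# label propagation
# ---------------------------------------------------------------------------


def propagate_disease_labels(patient: PatientRecord) -> PatientRecord:
    """Apply forward propagation of the chronic AMD label across visits.

    Once a patient's visit is labelled AMD, all later visits are labelled AMD
    too; DME and POAG labels are left untouched.  Returns the same record with
    visit labels updated in place (visit order is validated by the record).
    """
    a = DISEASES.index(FORWARD_PROPAGATED)
    seen = False
    for visit in patient.visits:
        seen = seen or bool(visit.labels[a])
        visit.labels[a] = seen
    return patient


def propagate_label_sequence(labels_a: Sequence[bool]) -> list[bool]:
    """Running OR of a time-ordered AMD label sequence (pure helper)."""
    out = []
    seen = False
    for v in labels_a:
        seen = seen or bool(v)
        out.append(seen)
    return out


# ---------------------------------------------------------------------------
# patient-level split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitAssignment:
    """Exhaustive, exclusive patient → subset mapping, fixed for all models."""

    assignment: Mapping[str, str]

    def subset(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def patients(self, subset: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == subset)

    def visits(self, cohort: Sequence[PatientRecord], subset: str) -> list[ScanSet]:
        return [v for p in cohort if self.assignment[p.patient_id] == subset
                for v in p.visits]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dict(self.assignment), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SplitAssignment":
        return cls(assignment=json.loads(Path(path).read_text()))


def _largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_patients(cohort: Sequence[PatientRecord],
                   ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                   seed: int = 0) -> SplitAssignment:
    """Randomly split patients into train/validation/test at the given ratios.

    Deterministic for a given seed; counts follow largest-remainder rounding,
    so 10 patients at 60:20:20 give exactly 6/2/2.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {ratios}")
    patient_ids = sorted(p.patient_id for p in cohort)
    if len(patient_ids) != len(set(patient_ids)):
        raise ConfigurationError("patient_id values must be unique in the cohort")
    if len(patient_ids) < 5:
        raise ConfigurationError("need at least 5 patients to split 60:20:20")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(patient_ids))
    counts = _largest_remainder_counts(len(shuffled), ratios)
    assignment: dict[str, str] = {}
    start = 0
    for subset, count in zip(SUBSETS, counts):
        for pid in shuffled[start:start + count]:
            assignment[pid] = subset
        start += count
    return SplitAssignment(assignment=assignment)


# ---------------------------------------------------------------------------
# completeness rule
# ---------------------------------------------------------------------------


def eligible_visits(visits: Sequence[ScanSet], spec: CoverageModelSpec) -> list[ScanSet]:
    """Visits whose present B-scan indices fully cover the model's window.

    A visit with only three B-scans is retained for models 1 and 2 but is
    dropped from model 3 onward; there is no partial inclusion.
    """
    window = spec.index_window
    return [v for v in visits if v.covers(window)]


def eligibility_manifest(cohort: Sequence[PatientRecord],
                         specs: Sequence[CoverageModelSpec]) -> pd.DataFrame:
    """Long table of (model_index, patient_id, visit_index, eligible)."""
    rows = []
    for spec in specs:
        for patient in cohort:
            for visit in patient.visits:
                rows.append({
                    "model_index": spec.model_index,
                    "patient_id": visit.patient_id,
                    "visit_index": visit.visit_index,
                    "eligible": visit.covers(spec.index_window),
                })
    return pd.DataFrame(rows)
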