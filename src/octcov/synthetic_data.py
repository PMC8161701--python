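"""Synthetic macular OCT cohort generator.

Emulates the statistical structure of a clinical raster-OCT archive: patients
with repeated visits, up to 61 parallel B-scans per eye-visit spaced 0.125 mm
apart, three non-exclusive disease labels (AMD-like, DME-like, POAG-like),
forward-propagated AMD labels, and occasional visits whose raster set was
truncated to a smaller, fovea-centred subset.

Each disease is given a spatial *extent*: a half-width (in mm) around the
foveal B-scan bounding the region its pathology can occupy.  For every
affected eye-visit the pathology occupies an *annular band* of B-scans — all
indices whose eccentricity lies between a per-visit random onset eccentricity
and the disease's extent boundary.  This mirrors the predominantly
extrafoveal onset of early macular disease (parafoveal atrophy and drusen in
AMD, extrafoveal retinal thickening in DME, arcuate nerve-fibre defects in
POAG) that progresses inward toward the fovea at more advanced stages.  Two
consequences matter for the coverage analysis: a centred coverage window
first touches an eye's pathology exactly when it reaches the onset
eccentricity, so with uniform onsets the capture probability rises linearly
with coverage and saturates precisely where the window spans the full
extent; and every B-scan index inside the extent carries signal in a
substantial fraction of affected eyes, so the ensemble stage can learn the
pattern from desk-scale cohorts.  The diminishing-return point recovered
downstream is therefore a known, linear function of the configured extent —
the property the generator exists to provide.

Two output modes are supported:

* ``image`` — grayscale B-scans with a layered-band retina texture plus a
  disease-styled perturbation (bright blob / band thickening / band thinning)
  on the lesion scans;
* ``feature`` — per-B-scan feature vectors (default length 256) in which the
  lesion is a mean shift on a small disease-specific coordinate block,
  bypassing image rendering so the ensemble and statistics layers can be
  exercised in seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Canonical disease order used by every label triple in the package.
DISEASES: tuple[str, str, str] = ("AMD", "DME", "POAG")

#: Disease index that receives forward label propagation (chronic diagnosis).
FORWARD_PROPAGATED = "AMD"

#: Rendering style per disease: drusen-like bright blob, edema-like band
#: thickening, nerve-fibre-layer-like band thinning.
_RENDER_STYLE = {"AMD": "blob", "DME": "thicken", "POAG": "thin"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``disease_extent_mm`` maps each disease to the half-width (mm) of the
    region around the fovea where its lesions may occur.  ``signal_strength``
    is a dimensionless effect size: in feature mode it is the mean shift (in
    noise-SD units) applied to the informative coordinates of lesion scans; in
    image mode it scales the perturbation amplitude in gray levels.
    """

    n_patients_per_disease: int = 50
    visits_per_patient: tuple[int, int] = (1, 8)
    n_bscans: int = 61
    scan_spacing_mm: float = 0.125
    image_height: int = 496
    image_width: int = 768
    disease_extent_mm: Mapping[str, float] = field(
        default_factory=lambda: {"AMD": 1.5, "DME": 2.25, "POAG": 3.0}
    )
    signal_strength: float | Mapping[str, float] = 2.0
    comorbidity_rate: float = 0.15
    missing_scan_rate: float = 0.1
    seed: int = 0
    mode: str = "feature"
    feature_dim: int = 256
    signal_coords_per_disease: int = 4
    onset_bias: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bscans < 1 or self.n_bscans % 2 == 0:
            raise ConfigurationError(
                f"n_bscans must be odd and >= 1, got {self.n_bscans}"
            )
        if self.n_patients_per_disease < 1:
            raise ConfigurationError("n_patients_per_disease must be >= 1")
        lo, hi = self.visits_per_patient
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                f"visits_per_patient range invalid: {self.visits_per_patient}"
            )
        max_extent = (self.n_bscans - 1) * self.scan_spacing_mm / 2
        for disease in DISEASES:
            if disease not in self.disease_extent_mm:
                raise ConfigurationError(f"disease_extent_mm missing {disease!r}")
            extent = self.disease_extent_mm[disease]
            if not (0.0 <= extent <= max_extent + 1e-12):
                raise ConfigurationError(
                    f"disease_extent_mm[{disease!r}]={extent} outside "
                    f"[0, {max_extent}]"
                )
        for name in ("comorbidity_rate", "missing_scan_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} not a probability")
        if self.onset_bias < 1.0:
            raise ConfigurationError("onset_bias must be >= 1 (1 = uniform onsets)")
        if self.mode not in ("image", "feature"):
            raise ConfigurationError(f"mode must be 'image' or 'feature': {self.mode}")
        if self.feature_dim < 3 * self.signal_coords_per_disease:
            raise ConfigurationError(
                "feature_dim must be >= 3 * signal_coords_per_disease"
            )
        if self.image_width < self.image_height:
            raise ConfigurationError("image_width must be >= image_height")

    @property
    def center_index(self) -> int:
        return (self.n_bscans - 1) // 2

    def extent_radius(self, disease: str) -> int:
        """Half-width of the informative window in B-scan index units."""
        return int(round(self.disease_extent_mm[disease] / self.scan_spacing_mm))

    def strength(self, disease: str) -> float:
        if isinstance(self.signal_strength, Mapping):
            return float(self.signal_strength[disease])
        return float(self.signal_strength)

    def signal_block(self, disease: str) -> slice:
        """Feature-mode coordinate block carrying this disease's signal."""
        i = DISEASES.index(disease)
        c = self.signal_coords_per_disease
        return slice(i * c, (i + 1) * c)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["disease_extent_mm"] = dict(self.disease_extent_mm)
        if isinstance(self.signal_strength, Mapping):
            d["signal_strength"] = dict(self.signal_strength)
        return d


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class ScanSet:
    """One eye-visit: a contiguous, fovea-centred set of B-scans plus labels.

    ``present_count`` B-scans are available, centred on the central index
    (truncation removes outermost pairs first), stored in ascending-index
    order either as grayscale images or as precomputed per-scan feature
    vectors.  ``signal_masks`` records, per disease, the B-scan indices where
    signal was actually planted (generator metadata; not persisted).
    """

    patient_id: str
    visit_index: int
    labels: np.ndarray  # (3,) bool, ordered as DISEASES
    n_bscans: int = 61
    present_count: int = 61
    eye: str = "OD"
    images: list[np.ndarray] | None = None
    features: np.ndarray | None = None  # (present_count, d)
    signal_masks: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.present_count % 2 == 0 or not (1 <= self.present_count <= self.n_bscans):
            raise ConfigurationError(
                f"present_count must be odd in [1, {self.n_bscans}]: "
                f"{self.present_count}"
            )
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.shape != (3,):
            raise ConfigurationError("labels must be three booleans")

    @property
    def center_index(self) -> int:
        return (self.n_bscans - 1) // 2

    @property
    def present_indices(self) -> range:
        half = (self.present_count - 1) // 2
        return range(self.center_index - half, self.center_index + half + 1)

    def covers(self, index_window: range) -> bool:
        present = self.present_indices
        return index_window.start >= present.start and index_window.stop <= present.stop

    def rows_for(self, index_window: range) -> slice:
        """Row slice of ``features``/``images`` holding the given index window."""
        present = self.present_indices
        if not self.covers(index_window):
            raise ConfigurationError(
                f"window {index_window} not covered by present {present}"
            )
        off = index_window.start - present.start
        return slice(off, off + len(index_window))


@dataclass
class PatientRecord:
    """All visits of one patient, in strictly increasing visit order."""

    patient_id: str
    visits: list[ScanSet]

    def __post_init__(self) -> None:
        order = [v.visit_index for v in self.visits]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ConfigurationError(
                f"visits of {self.patient_id} not strictly increasing: {order}"
            )


def iter_visits(cohort: Sequence[PatientRecord]):
    for patient in cohort:
        yield from patient.visits


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderContext:
    """Per-visit rendering state shared across that visit's B-scans."""

    height: int
    width: int
    depth_frac: float  # vertical position of the retinal band centre
    #: per active disease: (disease, {scan index: amplitude}, lateral fraction)
    lesions: list[tuple[str, dict[int, float], float]]
    center_index: int = 30
    noise_sd: float = 8.0


def render_bscan(ctx: RenderContext, bscan_index: int, rng: np.random.Generator) -> np.ndarray:
    """Render one grayscale B-scan as a uint8 array of shape (height, width).

    The background is a layered horizontal band texture (retina-like) with
    speckle noise and a mild curvature of the band across the raster.  For
    every lesion whose scan-index patch contains ``bscan_index``, a localized
    perturbation is added in the style of its disease: a bright blob (drusen),
    a band thickening (edema), or a band thinning (nerve-fibre loss).
    """
    h, w = ctx.height, ctx.width
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]
    # band centre bows slightly toward the image top away from the fovea
    ecc = (bscan_index - ctx.center_index) / max(ctx.center_index, 1)
    yc = h * (ctx.depth_frac + 0.05 * ecc**2)
    t = 0.18 * h  # band envelope scale
    envelope = np.exp(-0.5 * ((y - yc) / t) ** 2)
    img = 25.0 + 120.0 * envelope + 35.0 * np.cos(2 * np.pi * (y - yc) / (0.6 * t)) * envelope
    img = np.broadcast_to(img, (h, w)).copy()
    img += rng.normal(0.0, ctx.noise_sd, size=(h, w))

    for style_disease, amplitudes, lateral_frac in ctx.lesions:
        if bscan_index not in amplitudes:
            continue
        amplitude = amplitudes[bscan_index]
        style = _RENDER_STYLE[style_disease]
        x0 = lateral_frac * w
        if style == "blob":  # drusen-like bright deposit at the outer band
            y0, sx, sy, sign = yc + 0.12 * h, 0.04 * w, 0.03 * h, +1.0
        elif style == "thicken":  # edema-like broad thickening
            y0, sx, sy, sign = yc + 0.05 * h, 0.10 * w, 0.08 * h, +1.0
        else:  # "thin": inner-layer thinning
            y0, sx, sy, sign = yc - 0.10 * h, 0.12 * w, 0.05 * h, -1.0
        bump = np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))
        img += sign * amplitude * 14.0 * bump

    return np.clip(img, 0.0, 255.0).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_present_count(config: GeneratorConfig, rng: np.random.Generator) -> int:
    if config.n_bscans < 5 or rng.random() >= config.missing_scan_rate:
        return config.n_bscans
    odd_counts = np.arange(3, config.n_bscans - 1, 2)
    return int(rng.choice(odd_counts))


def _draw_labels(config: GeneratorConfig, primary: str, n_visits: int,
                 rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros((n_visits, 3), dtype=bool)
    labels[:, DISEASES.index(primary)] = True
    for j, disease in enumerate(DISEASES):
        if disease == primary:
            continue
        labels[:, j] |= rng.random(n_visits) < config.comorbidity_rate
    # chronic AMD: once labelled, always labelled at later visits
    a = DISEASES.index(FORWARD_PROPAGATED)
    labels[:, a] = np.maximum.accumulate(labels[:, a])
    return labels


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate a deterministic synthetic cohort for the configured conditions.

    Patients are created in equal numbers per primary disease; comorbid labels
    are added independently per visit at ``comorbidity_rate`` (forward-
    propagated for AMD).  Every visit gets a fovea-centred raster set of
    ``n_bscans`` B-scans, truncated symmetrically with probability
    ``missing_scan_rate``, and one focal lesion per active disease at a
    uniform random index inside that disease's informative window.
    """
    rng = np.random.default_rng(config.seed)
    center = config.center_index
    cohort: list[PatientRecord] = []
    pid_counter = 0
    for primary in DISEASES:
        for _ in range(config.n_patients_per_disease):
            patient_id = f"P{pid_counter:05d}"
            pid_counter += 1
            lo, hi = config.visits_per_patient
            n_visits = int(rng.integers(lo, hi + 1))
            labels = _draw_labels(config, primary, n_visits, rng)
            visits = []
            for visit_index in range(n_visits):
                present_count = _draw_present_count(config, rng)
                scan_set = _make_visit(
                    config, patient_id, visit_index, labels[visit_index],
                    present_count, center, rng,
                )
                visits.append(scan_set)
            cohort.append(PatientRecord(patient_id=patient_id, visits=visits))
    return cohort


def _make_visit(config: GeneratorConfig, patient_id: str, visit_index: int,
                labels: np.ndarray, present_count: int, center: int,
                rng: np.random.Generator) -> ScanSet:
    half_present = (present_count - 1) // 2
    present = range(center - half_present, center + half_present + 1)

    masks: dict[str, frozenset[int]] = {}
    lesion_info: list[tuple[str, dict[int, float], float]] = []
    for j, disease in enumerate(DISEASES):
        if not labels[j]:
            continue
        r = config.extent_radius(disease)
        # annular pathology from a random onset eccentricity out to the extent
        # boundary, on both sides of the fovea; onsets skew peripheral
        # (early disease is predominantly extrafoveal), with
        # P(onset <= x) = 1 - (1 - x/(r+1))^(1/onset_bias)
        u = float(rng.random())
        onset = min(r, int((r + 1) * (1.0 - (1.0 - u) ** config.onset_bias)))
        strength = config.strength(disease)
        amplitudes = {
            center + signed: strength
            for ecc in range(onset, r + 1)
            for signed in ({-ecc, ecc} if ecc else {0})
        }
        masks[disease] = frozenset(idx for idx in amplitudes if idx in present)
        lesion_info.append((disease, amplitudes, float(rng.uniform(0.2, 0.8))))

    images = None
    features = None
    if config.mode == "feature":
        features = rng.standard_normal((present_count, config.feature_dim))
        for disease, amplitudes, _lat in lesion_info:
            block = config.signal_block(disease)
            for idx, amp in amplitudes.items():
                if idx in present:
                    features[idx - present.start, block] += amp
    else:
        ctx = RenderContext(
            height=config.image_height, width=config.image_width,
            depth_frac=float(rng.uniform(0.42, 0.58)),
            lesions=lesion_info, center_index=center,
        )
        images = [render_bscan(ctx, idx, rng) for idx in present]

    return ScanSet(
        patient_id=patient_id, visit_index=visit_index, labels=labels,
        n_bscans=config.n_bscans, present_count=present_count,
        images=images, features=features, signal_masks=masks,
    )


def truncate_scan_set(scan_set: ScanSet, target_count: int) -> ScanSet:
    """Keep the ``target_count`` scans centred on the foveal index.

    ``target_count`` must be odd and no larger than the currently present
    count; labels are unchanged and outermost scans are dropped in pairs.
    """
    if target_count % 2 == 0:
        raise ConfigurationError(f"target_count must be odd, got {target_count}")
    if not (1 <= target_count <= scan_set.present_count):
        raise ConfigurationError(
            f"target_count {target_count} outside [1, {scan_set.present_count}]"
        )
    if target_count == scan_set.present_count:
        return scan_set
    drop = (scan_set.present_count - target_count) // 2
    keep = slice(drop, scan_set.present_count - drop)
    new_present = range(scan_set.center_index - (target_count - 1) // 2,
                        scan_set.center_index + (target_count - 1) // 2 + 1)
    return ScanSet(
        patient_id=scan_set.patient_id,
        visit_index=scan_set.visit_index,
        labels=scan_set.labels.copy(),
        n_bscans=scan_set.n_bscans,
        present_count=target_count,
        eye=scan_set.eye,
        images=None if scan_set.images is None else list(scan_set.images[keep]),
        features=None if scan_set.features is None else scan_set.features[keep].copy(),
        signal_masks={d: frozenset(i for i in m if i in new_present)
                      for d, m in scan_set.signal_masks.items()},
    )


# ---------------------------------------------------------------------------
# persistence and hashing
# ---------------------------------------------------------------------------


def cohort_hash(cohort: Sequence[PatientRecord]) -> str:
    """SHA-256 over all labels, present counts and pixel/feature data."""
    h = hashlib.sha256()
    for visit in iter_visits(cohort):
        h.update(visit.patient_id.encode())
        h.update(bytes([visit.visit_index & 0xFF]))
        h.update(visit.labels.tobytes())
        h.update(visit.present_count.to_bytes(2, "little"))
        if visit.features is not None:
            h.update(np.ascontiguousarray(visit.features).tobytes())
        if visit.images is not None:
            for img in visit.images:
                h.update(np.ascontiguousarray(img).tobytes())
    return h.hexdigest()


def save_cohort(cohort: Sequence[PatientRecord], path: str | Path,
                config: GeneratorConfig | None = None) -> None:
    """Write a cohort as PNG/NPZ data plus labels.csv and manifest.json."""
    from PIL import Image

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    feature_arrays: dict[str, np.ndarray] = {}
    for visit in iter_visits(cohort):
        rows.append({
            "patient_id": visit.patient_id,
            "visit_index": visit.visit_index,
            "eye": visit.eye,
            "label_AMD": int(visit.labels[0]),
            "label_DME": int(visit.labels[1]),
            "label_POAG": int(visit.labels[2]),
            "n_scans": visit.present_count,
            "n_bscans_protocol": visit.n_bscans,
        })
        if visit.features is not None:
            feature_arrays[f"{visit.patient_id}:{visit.visit_index}"] = visit.features
        if visit.images is not None:
            vdir = path / visit.patient_id / f"visit_{visit.visit_index:02d}"
            vdir.mkdir(parents=True, exist_ok=True)
            for idx, img in zip(visit.present_indices, visit.images):
                Image.fromarray(img).save(vdir / f"bscan_{idx:02d}.png")
    pd.DataFrame(rows).to_csv(path / "labels.csv", index=False)
    if feature_arrays:
        np.savez_compressed(path / "features.npz", **feature_arrays)
    manifest = {"n_patients": len(cohort)}
    if config is not None:
        manifest["config"] = config.to_dict()
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(path: str | Path) -> list[PatientRecord]:
    """Reconstruct a cohort from the ``save_cohort`` directory layout."""
    from PIL import Image

    path = Path(path)
    table = pd.read_csv(path / "labels.csv")
    npz_path = path / "features.npz"
    features = np.load(npz_path) if npz_path.exists() else None
    patients: dict[str, list[ScanSet]] = {}
    for row in table.itertuples(index=False):
        labels = np.array([row.label_AMD, row.label_DME, row.label_POAG], dtype=bool)
        images = None
        feats = None
        key = f"{row.patient_id}:{row.visit_index}"
        if features is not None and key in features:
            feats = features[key]
        else:
            vdir = path / str(row.patient_id) / f"visit_{row.visit_index:02d}"
            center = (row.n_bscans_protocol - 1) // 2
            half = (row.n_scans - 1) // 2
            images = [
                np.asarray(Image.open(vdir / f"bscan_{idx:02d}.png"))
                for idx in range(center - half, center + half + 1)
            ]
        patients.setdefault(str(row.patient_id), []).append(ScanSet(
            patient_id=str(row.patient_id), visit_index=int(row.visit_index),
            labels=labels, n_bscans=int(row.n_bscans_protocol),
            present_count=int(row.n_scans), eye=str(row.eye),
            images=images, features=feats,
        ))
    return [
        PatientRecord(patient_id=pid, visits=sorted(v, key=lambda s: s.visit_index))
        for pid, v in sorted(patients.items())
    ]
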