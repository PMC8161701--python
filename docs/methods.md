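# Methods

`octcov` measures how the diagnostic information carried by a macular OCT
raster set grows as coverage expands symmetrically from the central foveal
B-scan, for three non-exclusive disease labels: age-related macular
degeneration (AMD), diabetic macular edema (DME) and primary open-angle
glaucoma (POAG).

## The coverage experiment

A raster set holds up to `n_bscans = 61` parallel B-scans spaced 0.125 mm
apart, so the full set spans (61 − 1) × 0.125 = 7.50 mm and index 30 is the
foveal scan. Coverage model m (m = 1..31) is restricted to the central
2m − 1 scans and therefore spans (m − 1) × 0.25 mm; model 1 is the
foveal-only baseline and model 31 uses all 61 scans.

The inference chain per model m:

1. **Per-scan embedding.** Every B-scan inside model m's index window is
   mapped to a fixed-length feature vector (default length d = 256) by a
   pluggable extractor trained per B-scan against the visit's three labels
   (each scan inherits its visit's labels; scans are embedded independently
   of each other).
2. **Eye-level assembly.** The window's embeddings are concatenated in
   ascending index order and padded symmetrically with exact 0.0 to a fixed
   length K_max × d (61 × 256 = 15,616 by default), so all models present
   identically shaped inputs and scan index i always occupies the same
   columns.
3. **Forest fusion.** A multi-output random forest maps the padded vector to
   three per-disease probabilities in [0, 1] (not summing to 1 — an eye may
   carry several diagnoses). Hyperparameters come from a randomized search
   with patient-grouped five-fold cross-validation; light profiles may pin
   them instead. The held-out test split is touched only at prediction time.
4. **Replication and scoring.** Each model is refit R times (default 10)
   under derived seeds; per run, disease and metric (AUROC, AUPR) the test
   split is scored, giving mean and standard error sd/√R per model.
5. **Gain curves.** Mean curves are normalized to percent gain
   g(m) = 100·(x(m) − x(1)) / (x(M) − x(1)), exactly 0 at the baseline and
   100 at full coverage; interior values may leave [0, 100].
6. **Diminishing return (DR).** g is smoothed with a *trailing* three-model
   running average (left-truncated); the DR point is the smallest m whose
   smoothed gain reaches ≥ 90% of the full-coverage gain. Trailing
   alignment guarantees the DR decision never uses models beyond m; the
   alignment is recorded in the run manifest.
7. **Significance.** Every model m ≥ 2 is compared with the baseline by a
   one-tailed two-sample Wilcoxon rank-sum (alternative: model > baseline),
   Bonferroni-corrected by 180 = 30 models × 3 diseases × 2 metrics in the
   default design. The exact null distribution is used when both groups
   have ≤ 12 values and no cross-group ties; otherwise the tie-corrected
   normal approximation. Identical constant samples short-circuit to
   p = 0.5.

Patients are split 60:20:20 into train/validation/test at the patient level
(largest-remainder rounding, deterministic per seed); all visits of a
patient share one subset, and the split is computed once and reused by every
model and run. A visit whose raster set does not fully cover model m's
window is dropped from that model only (so a 3-scan visit serves models 1–2
and no others); eligibility is monotone in m.

## Synthetic cohorts

The generator emits patients → visits → eye-level raster sets with the
statistical structure the analysis needs, without any clinical data:

* **Labels.** Equal numbers of patients per primary disease; comorbid labels
  arrive independently per visit at `comorbidity_rate` (default 0.15; no
  field anchor exists for overlap rates, so this is a package choice). The
  AMD label is forward-propagated: once true for a patient it stays true for
  all later visits, mirroring how a chronic diagnosis is recorded. DME and
  POAG are not propagated.
* **Raster completeness.** With probability `missing_scan_rate` (default
  0.1) a visit's raster is truncated to a smaller odd count, dropping
  outermost scans in pairs, so eligibility varies across coverage models the
  way incomplete clinical sets do. Interior gaps are never generated.
* **Spatial signal.** Each disease has an extent: the half-width (mm) of the
  fovea-centred region its pathology may occupy (defaults AMD 1.5, DME 2.25,
  POAG 3.0 — ordered and sized so the synthetic DR points fall in the
  clinically reported disease-specific ranges, preserving AMD < DME < POAG).
  Per affected visit the pathology occupies an annular band: all scans whose
  eccentricity lies between a random onset eccentricity and the extent
  boundary. Onsets are skewed peripheral,
  P(onset ≤ x) = 1 − (1 − x/(r+1))^(1/onset_bias) with `onset_bias = 2`,
  reflecting predominantly extrafoveal early disease that involves the fovea
  only at advanced stages.
* **Feature mode.** The per-scan "embedding" is drawn directly: i.i.d.
  standard normal noise of length `feature_dim`, plus a mean shift of
  `signal_strength` (default 2.0 noise-SDs) on a small disease-specific
  coordinate block (default 4 coordinates) for scans inside the annulus.
  This emulates what a trained per-scan discriminator produces and lets the
  ensemble and statistics layers run in seconds. Extraction is an identity
  pass-through in this mode.
* **Image mode.** B-scans are rendered as layered-band textures with speckle
  noise and a mild eccentricity-dependent curvature; annulus scans receive a
  disease-styled local perturbation (AMD: bright drusen-like blob; DME:
  band thickening; POAG: band thinning) scaled by `signal_strength`.

### Why annular bands

The generator's defining requirement is that the DR point recovered by the
pipeline be a known function of the planted extent. Three candidate signal
geometries were evaluated analytically and empirically during design:

* *Window-wide mean shifts* make every affected scan informative, but
  aggregate information then grows like √k in the number of covered scans,
  so the normalized curve is concave and its 90% crossing lands well before
  the planted extent for wide extents.
* *Focal single-scan lesions* at uniform positions give an exactly linear
  capture probability, but concatenated features position-code the lesion:
  with desk-scale cohorts each informative column has only a couple of
  positive training examples, and a random forest cannot learn an OR over
  ~50 such columns (test AUROC stays at chance even for extreme shifts).
* *Annular bands with peripheral-skewed onsets* resolve both problems: a
  centred window first touches an eye's pathology exactly at its onset
  eccentricity (capture linear in coverage, saturating at the extent), and
  outer columns carry signal in a large fraction of positives (dense
  training support). Because no healthy eyes exist — matching the
  clinical design, where every visit carries at least one diagnosis — a
  negative eye's own-disease signal also helps separate pairs once
  captured, inflating the response roughly quadratically; the peripheral
  onset skew (onset_bias = 2) linearizes that two-sided response.

Under this model the expected DR for a planted extent with radius
r = extent/0.125 scans sits at model r (±1 model from smoothing and
sampling), i.e. the half-width of coverage at the DR point —
`dr_coverage_mm / 2`, the package's *recovered extent* — equals the planted
extent to within about one 0.25 mm model step.

### What the generator does not emulate

Anatomically realistic speckle statistics or layer morphology; lesion
substructure (drusen vs. cysts); longitudinal progression (labels propagate
but lesions are re-drawn per visit); inter-eye correlation (one eye per
visit); instrument artefacts. Passing tests therefore demonstrate that the
*inference chain* is correct and calibrated on data with the right spatial
information structure — not that any particular clinical performance level
would be attained on real scans.

## Extractor backbones

The default image-mode extractor is a compact seeded numpy MLP: flattened
input → dense(64, ReLU) → dense(embedding_dim, ReLU) → dropout 0.2 →
3 sigmoid outputs, trained with Adam (lr 1e−4, batch 16) on the sum of the
three binary cross-entropies, up to 50 epochs with patience 10, keeping the
checkpoint with the lowest validation loss; embeddings are the post-ReLU
penultimate activations with dropout disabled, so inference is bitwise
reproducible. Preprocessing center-crops landscape rasters to a square and
resizes to `input_side` (default 299) with intensities in [0, 1] and no
denoising; training-time augmentation draws rotation ≤ 15°, shear ≤ 10% and
width/height shifts ≤ 10%. The backbone sits behind a two-method interface
(`fit`, `embed`), so heavier convolutional extractors can be plugged in
without touching the rest of the pipeline; the desk-scale default is not a
transfer-learned deep network and is not intended to match one.

## Numerical choices and degenerate inputs

* AUROC is the Mann–Whitney statistic with ties counted ½; AUPR is the area
  under the precision–recall step curve over descending thresholds (a
  constant scorer yields the prevalence). Both are clamped to [0, 1] against
  float summation overshoot and raise on single-class inputs.
* Percent-gain normalization fixes the endpoints exactly and raises a
  flat-curve error when x(M) = x(1).
* A disease whose training labels are single-class is flagged degenerate and
  predicted at its training prevalence.
* Per-(model, run) seeds derive from `master_seed` via
  `SeedSequence(master_seed, spawn_key=(model, run))`, all below 2³¹, and
  are written to the run manifest; feature-mode reruns of one config are
  bitwise identical. In feature mode replicate runs re-randomize the forest
  stage (there is no stochastic extractor); in image mode the extractor is
  retrained per run only when `retrain_extractor_per_run` is set.
* Cross-validation folds are grouped by patient; if fewer groups than folds
  exist the fold count shrinks, and with a single candidate the search is
  skipped.

## Study sizes used by the shipped studies

The package's own validation studies are sized for a single desk core:

* *Smoke experiment*: 9-scan rasters, 5 models, 2 runs, ~180 visits,
  16-dim features — seconds; used for determinism and orchestration tests.
* *Extent recovery*: 61-scan rasters, 31 models, 3 runs, ~300 visits
  (34 patients per disease, 2–4 visits each), 12-dim features, 60-tree
  pinned forests, 20 paired seeds probing extents 0.5 vs 3.0 mm with all
  three diseases sharing the probed extent (so counter-evidence from the
  other labels lives on the same spatial scale).
* *Type-I calibration*: signal-free 9-scan cohorts (36 patients), two
  replicate groups of the baseline coverage model with disjoint run seeds,
  ten 50-tree forest replicates per group, 200 pairs; the raw one-tailed
  rejection rate at α = 0.05 is compared with the binomial 95% band around
  0.05. The calibration deliberately compares replicate groups of the
  *same* coverage model: replicate runs re-randomize only the ensemble
  stage, so on one shared dataset two *different* coverage models carry a
  fixed, data-realization-specific offset between their run distributions
  that replicate noise cannot wash out — a rank-sum test between them
  rejects far above α even with zero planted signal. The replicate-level
  Wilcoxon protocol therefore establishes that model m ranks above the
  baseline *on the dataset at hand*, not under re-sampling of patients;
  its size is controlled for the exchangeable replicate null, which is
  what this study verifies.
* *Main synthetic experiment* (acceptance script): 31 models × 10 runs =
  310 forest fits on a ~300-visit cohort with the default disease extents.

## Known limitations

* The recovered extent is calibrated for the annular generator; other signal
  geometries (e.g. purely focal disease) would need larger cohorts than the
  desk-scale forest stage can learn from.
* The coverage ↔ millimetre bookkeeping follows coverage_mm =
  (scan_count − 1) × 0.125 throughout. Published clinical summaries of
  comparable designs sometimes pair B-scan counts with millimetre spans that
  are mutually inconsistent under a fixed 0.125 mm spacing; this package
  reports the arithmetic mapping only.
* Wilcoxon comparisons are per metric; no pooling across AUROC and AUPR is
  attempted, and no DeLong/bootstrap confidence intervals are provided.
* With very small test splits a disease can be single-class in some subset,
  which aborts the experiment with a stage-labelled error rather than
  silently skipping the cell.
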