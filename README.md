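# octcov

**How much macular OCT coverage does a diagnostic classifier actually
need?** Clinics acquire macular OCT volumes as stacks of parallel B-scans
(up to 61 scans, 0.125 mm apart, spanning 7.50 mm) but read and model them
with very different fields of view — often only the central foveal scan.
`octcov` implements a systematic coverage-utility analysis for three common
diagnoses — age-related macular degeneration (AMD), diabetic macular edema
(DME) and primary open-angle glaucoma (POAG) — measuring how eye-level
classification performance grows as coverage expands symmetrically from the
fovea, and where the gains plateau.

It is aimed at readers who want to reproduce, stress-test or extend this
kind of incremental field-of-view ablation: the full inference chain is
driven by a built-in synthetic cohort generator with known spatial ground
truth, so every stage is testable on a laptop without clinical data.

## The method

For coverage models m = 1..31, model m sees the central 2m−1 B-scans
(span (m−1)·0.25 mm). Per model:

1. each B-scan in the window is embedded as a 256-vector by a per-scan
   multi-label classifier (pluggable backbone; identity pass-through for
   precomputed features);
2. the window's embeddings are concatenated and zero-padded symmetrically to
   a fixed 61×256 = 15,616-length vector;
3. a multi-output random forest (randomized hyperparameter search,
   patient-grouped fivefold CV) maps the vector to three per-disease
   probabilities;
4. each model is refit R = 10 times; AUROC and AUPR on the held-out,
   patient-level 20% test split are averaged with standard error sd/√R.

Mean curves x(m) are normalized to percent gain

&nbsp;&nbsp;&nbsp;&nbsp;g(m) = 100 · (x(m) − x(1)) / (x(M) − x(1)),

smoothed with a trailing three-model running average s(m), and the **point
of diminishing return** is the smallest m with s(m) ≥ 90. Every model
m ≥ 2 is compared against the foveal-only baseline with a one-tailed
two-sample Wilcoxon rank-sum test, Bonferroni-corrected by
180 = 30 models × 3 diseases × 2 metrics.

The synthetic generator plants, for each affected eye-visit, an annular band
of pathology between a random onset eccentricity and a disease-specific
spatial extent (defaults: AMD 1.5 mm, DME 2.25 mm, POAG 3.0 mm half-width).
The diminishing-return point recovered by the pipeline is then a known,
linear function of the planted extent — see `docs/methods.md` for the model
and its assumptions.

## Worked example

Run a feature-mode experiment at the full 31-model design on a synthetic
cohort of ~100 patients (~300 eye-visits), with all 310 forest fits:

```bash
cat > config.yaml <<'YAML'
generator:
  n_patients_per_disease: 34
  visits_per_patient: [2, 4]
  n_bscans: 61
  feature_dim: 16
  missing_scan_rate: 0.1
  disease_extent_mm: {AMD: 1.5, DME: 2.25, POAG: 3.0}
n_models: 31
k_max: 61
n_runs: 10
YAML
octcov run --profile smoke --config config.yaml --seed 1 --outdir bundle
```

which prints (numbers from this exact command):

```
coverage models: 31   runs per model: 10   total fits: 310
Bonferroni comparisons: 180

AMD   AUROC  baseline 0.5648  full 0.9985  DR model 14 (3.25 mm)  significant models: 26/30
AMD   AUPR   baseline 0.5943  full 0.9987  DR model 14 (3.25 mm)  significant models: 27/30
DME   AUROC  baseline 0.4614  full 0.9986  DR model 20 (4.75 mm)  significant models: 25/30
DME   AUPR   baseline 0.4428  full 0.9985  DR model 19 (4.50 mm)  significant models: 25/30
POAG  AUROC  baseline 0.5549  full 0.9996  DR model 25 (6.00 mm)  significant models: 24/30
POAG  AUPR   baseline 0.4383  full 0.9994  DR model 25 (6.00 mm)  significant models: 24/30
```

Reading this: the foveal-only baseline is near chance because the planted
pathology is predominantly extrafoveal; performance saturates once coverage
spans the planted extent, and the diminishing-return point lands at about
twice the planted half-width — 3.25 mm of coverage for AMD (1.5 mm extent),
4.5–4.75 mm for DME (2.25 mm), 6.0 mm for POAG (3.0 mm) — preserving the
AMD < DME < POAG ordering of required coverage. Most expanded models beat
the baseline after Bonferroni correction (the smallest windows and the
replicate-noise-limited cells do not). `bundle/` then holds `results.csv`
(per model/disease/metric: mean, SE, percent gain, smoothed gain, p-values),
`dr_points.json`, `split.json` and a manifest with the full per-(model, run)
seed ledger; `octcov figures --outdir bundle ...` renders the percent-gain
curves and coverage-coloured ROC/PR families.

The same chain is available as a library:

```python
from octcov import ExperimentConfig, GeneratorConfig, run_experiment
result = run_experiment(ExperimentConfig(master_seed=1))
result.curve("POAG", "auroc").dr_coverage_mm
```

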