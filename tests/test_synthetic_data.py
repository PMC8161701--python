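"""Generator contracts: determinism, spatial structure, rendering, I/O."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from octcov.errors import ConfigurationError
from octcov.synthetic_data import (
    DISEASES,
    GeneratorConfig,
    RenderContext,
    cohort_hash,
    generate_cohort,
    iter_visits,
    load_cohort,
    render_bscan,
    save_cohort,
    truncate_scan_set,
)


class TestGeneratorConfig:
    @pytest.mark.parametrize("kwargs, field", [
        ({"n_bscans": 60}, "n_bscans"),
        ({"disease_extent_mm": {"AMD": 9.0, "DME": 1.0, "POAG": 1.0}},
         "disease_extent_mm"),
        ({"comorbidity_rate": 1.5}, "comorbidity_rate"),
        ({"missing_scan_rate": -0.1}, "missing_scan_rate"),
        ({"visits_per_patient": (3, 1)}, "visits_per_patient"),
        ({"feature_dim": 4}, "feature_dim"),
        ({"mode": "volumetric"}, "mode"),
        ({"image_width": 100, "image_height": 200}, "image_width"),
    ])
    def test_invalid_fields_raise_naming_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            GeneratorConfig(**kwargs)

    def test_extent_radius_follows_spacing(self):
        config = GeneratorConfig(
            disease_extent_mm={"AMD": 0.5, "DME": 1.0, "POAG": 3.0})
        assert config.extent_radius("AMD") == 4   # 0.5 / 0.125
        assert config.extent_radius("POAG") == 24  # 3.0 / 0.125


class TestGenerateCohort:
    def test_seed_determinism(self, small_feature_config):
        a = generate_cohort(small_feature_config)
        b = generate_cohort(small_feature_config)
        assert cohort_hash(a) == cohort_hash(b)

    def test_different_seed_differs(self, small_feature_config):
        a = generate_cohort(small_feature_config)
        b = generate_cohort(dataclasses.replace(small_feature_config, seed=43))
        assert cohort_hash(a) != cohort_hash(b)

    def test_every_patient_has_a_visit_and_unique_id(self, small_feature_cohort):
        ids = [p.patient_id for p in small_feature_cohort]
        assert len(ids) == len(set(ids))
        assert all(len(p.visits) >= 1 for p in small_feature_cohort)

    def test_label_prevalence_near_configured_counts(self, small_feature_cohort,
                                                     small_feature_config):
        n = small_feature_config.n_patients_per_disease
        for j in range(3):
            carriers = sum(any(v.labels[j] for v in p.visits)
                           for p in small_feature_cohort)
            assert carriers >= n  # each disease has its primary patients

    def test_amd_labels_forward_propagated(self, small_feature_cohort):
        for patient in small_feature_cohort:
            seq = [bool(v.labels[0]) for v in patient.visits]
            assert seq == sorted(seq)  # non-decreasing over visit order

    def test_present_indices_centred_and_contiguous(self, small_feature_cohort):
        for visit in iter_visits(small_feature_cohort):
            idx = visit.present_indices
            assert visit.center_index in idx
            assert len(idx) == visit.present_count
            assert idx.stop - idx.start == visit.present_count

    def test_spatial_fidelity_masks_tile_the_extent_window(self):
        config = GeneratorConfig(
            n_patients_per_disease=60, visits_per_patient=(2, 4),
            disease_extent_mm={"AMD": 0.5, "DME": 1.0, "POAG": 3.0},
            missing_scan_rate=0.0, feature_dim=12, mode="feature", seed=3)
        cohort = generate_cohort(config)
        for disease, extent in (("AMD", 0.5), ("POAG", 3.0)):
            r = int(round(extent / 0.125))
            window = set(range(30 - r, 30 + r + 1))
            union = set()
            for visit in iter_visits(cohort):
                mask = visit.signal_masks.get(disease, frozenset())
                assert mask <= window
                union |= mask
            assert union == window

    def test_masks_are_annular_and_symmetric(self, small_feature_cohort):
        for visit in iter_visits(small_feature_cohort):
            for disease, mask in visit.signal_masks.items():
                eccs = sorted({abs(i - visit.center_index) for i in mask})
                if not eccs:
                    continue
                # eccentricities form a contiguous run up to the boundary
                assert eccs == list(range(eccs[0], eccs[-1] + 1))

    def test_feature_mode_signal_is_a_mean_shift_on_disease_block(self):
        config = GeneratorConfig(
            n_patients_per_disease=4, visits_per_patient=(1, 1),
            disease_extent_mm={"AMD": 0.25, "DME": 0.25, "POAG": 0.25},
            n_bscans=9, feature_dim=8, signal_coords_per_disease=2,
            missing_scan_rate=0.0, comorbidity_rate=0.0, signal_strength=50.0,
            mode="feature", seed=5)
        cohort = generate_cohort(config)
        for visit in iter_visits(cohort):
            j = int(np.flatnonzero(visit.labels)[0])
            block = config.signal_block(DISEASES[j])
            mask = visit.signal_masks[DISEASES[j]]
            rows = [i - visit.present_indices.start for i in sorted(mask)]
            assert np.all(visit.features[rows, block] > 10.0)
            other_rows = [k for k in range(visit.present_count) if k not in rows]
            if other_rows:
                assert np.all(np.abs(visit.features[other_rows, block]) < 10.0)


class TestTruncateScanSet:
    def test_full_count_is_identity(self, small_feature_cohort):
        visit = next(iter_visits(small_feature_cohort))
        assert truncate_scan_set(visit, visit.present_count) is visit

    def test_three_scan_truncation_keeps_central_triplet(self, small_feature_cohort):
        visit = next(v for v in iter_visits(small_feature_cohort)
                     if v.present_count == 9)
        out = truncate_scan_set(visit, 3)
        assert list(out.present_indices) == [3, 4, 5]
        assert np.array_equal(out.labels, visit.labels)
        assert np.array_equal(out.features, visit.features[3:6])

    def test_single_scan_keeps_the_fovea(self, small_feature_cohort):
        visit = next(iter_visits(small_feature_cohort))
        out = truncate_scan_set(visit, 1)
        assert list(out.present_indices) == [visit.center_index]

    def test_even_count_rejected(self, small_feature_cohort):
        visit = next(iter_visits(small_feature_cohort))
        with pytest.raises(ConfigurationError, match="odd"):
            truncate_scan_set(visit, 4)


class TestRenderBscan:
    def _ctx(self, lesions):
        return RenderContext(height=48, width=64, depth_frac=0.5,
                             lesions=lesions, center_index=4)

    def test_background_texture_range_and_shape(self, rng):
        img = render_bscan(self._ctx([]), 4, rng)
        assert img.shape == (48, 64) and img.dtype == np.uint8
        assert 20 < img.mean() < 120  # band plus dark background

    def test_scan_outside_lesion_equals_pure_background(self):
        lesions = [("AMD", {2: 2.0, 3: 2.0}, 0.5)]
        a = render_bscan(self._ctx(lesions), 4, np.random.default_rng(1))
        b = render_bscan(self._ctx([]), 4, np.random.default_rng(1))
        assert np.array_equal(a, b)

    def test_outside_lesion_statistically_indistinguishable(self):
        # two-sample KS on pixel pools over 50 renders each
        lesions = [("AMD", {2: 2.0}, 0.5)]
        rng_a, rng_b = np.random.default_rng(2), np.random.default_rng(3)
        pool_a = np.concatenate([
            render_bscan(self._ctx(lesions), 4, rng_a).ravel() for _ in range(50)])
        pool_b = np.concatenate([
            render_bscan(self._ctx([]), 4, rng_b).ravel() for _ in range(50)])
        sub = slice(None, None, 97)  # thin the pools to keep KS well-behaved
        assert stats.ks_2samp(pool_a[sub], pool_b[sub]).pvalue > 0.01

    def test_lesion_scan_differs_from_paired_background(self):
        lesions = [("AMD", {4: 5.0}, 0.5)]
        diffs = []
        for k in range(20):
            a = render_bscan(self._ctx(lesions), 4, np.random.default_rng(k))
            b = render_bscan(self._ctx([]), 4, np.random.default_rng(k))
            diffs.append(np.abs(a.astype(float) - b.astype(float)).mean())
        t = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        assert t.pvalue < 0.01
        assert min(diffs) > 0.0

    def test_each_disease_has_a_distinct_style(self):
        rng_seed = 11
        base = render_bscan(self._ctx([]), 4, np.random.default_rng(rng_seed))
        signed = {}
        for disease in DISEASES:
            img = render_bscan(self._ctx([(disease, {4: 5.0}, 0.5)]), 4,
                               np.random.default_rng(rng_seed))
            signed[disease] = (img.astype(int) - base.astype(int)).sum()
        assert signed["AMD"] > 0 and signed["DME"] > 0  # additive styles
        assert signed["POAG"] < 0  # thinning removes intensity


class TestCohortIO:
    def test_feature_mode_roundtrip(self, small_feature_cohort,
                                    small_feature_config, tmp_path):
        save_cohort(small_feature_cohort, tmp_path, small_feature_config)
        loaded = load_cohort(tmp_path)
        assert len(loaded) == len(small_feature_cohort)
        for p_in, p_out in zip(small_feature_cohort, loaded):
            assert p_in.patient_id == p_out.patient_id
            for v_in, v_out in zip(p_in.visits, p_out.visits):
                assert np.array_equal(v_in.labels, v_out.labels)
                assert np.allclose(v_in.features, v_out.features)

    def test_image_mode_roundtrip(self, tiny_image_cohort, tmp_path):
        save_cohort(tiny_image_cohort, tmp_path)
        loaded = load_cohort(tmp_path)
        v_in = tiny_image_cohort[0].visits[0]
        v_out = loaded[0].visits[0]
        assert all(np.array_equal(a, b) for a, b in zip(v_in.images, v_out.images))
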