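import numpy as np
import pytest

from octcov.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_feature_config() -> GeneratorConfig:
    """Nine-scan feature-mode cohort: fast, exercises truncation and labels."""
    return GeneratorConfig(
        n_patients_per_disease=6,
        visits_per_patient=(1, 3),
        n_bscans=9,
        disease_extent_mm={"AMD": 0.125, "DME": 0.25, "POAG": 0.375},
        feature_dim=8,
        signal_coords_per_disease=2,
        missing_scan_rate=0.2,
        mode="feature",
        seed=42,
    )


@pytest.fixture(scope="session")
def small_feature_cohort(small_feature_config):
    return generate_cohort(small_feature_config)


@pytest.fixture(scope="session")
def tiny_image_config() -> GeneratorConfig:
    """Five-scan image-mode cohort with miniature rasters."""
    return GeneratorConfig(
        n_patients_per_disease=2,
        visits_per_patient=(1, 2),
        n_bscans=5,
        image_height=32,
        image_width=48,
        disease_extent_mm={"AMD": 0.125, "DME": 0.25, "POAG": 0.25},
        missing_scan_rate=0.0,
        mode="image",
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_image_cohort(tiny_image_config):
    return generate_cohort(tiny_image_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
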