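import numpy as np
import pytest

from ovmorph import synthetic as syn


@pytest.fixture(scope="session")
def small_image():
    """One seeded 256x384 image with 20 comfortably in-range nuclei."""
    return syn.generate_nuclear_image(
        n_nuclei=20, area_range=(80.0, 440.0), image_shape=(256, 384), seed=11
    )


@pytest.fixture(scope="session")
def expression_cohort():
    """Planted 120-sample, 400-gene cohort for selection/fit tests."""
    return syn.generate_expression_dataset(
        n_samples=120, n_genes=400, n_informative=20, log2_fold_change=1.0,
        noise_sd=0.5, resistant_fraction=0.3, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
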