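import numpy as np
import pytest

from dyespy import (
    CANONICAL_GRID,
    Spectrum,
    SpectrumTable,
    StudyConfig,
)
from dyespy.library import SimulationConfig
from dyespy.study import make_demo_library, make_products


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_spectrum(
    centers, grid=None, widths=20.0, amplitudes=1.0, baseline=0.0,
    spectrum_id="g", sample_id="g",
):
    """Gaussian peaks on a flat offset, for hand-built fixtures."""
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, float)
    centers = np.atleast_1d(centers)
    widths = np.broadcast_to(np.atleast_1d(widths), centers.shape)
    amplitudes = np.broadcast_to(np.atleast_1d(amplitudes), centers.shape)
    y = np.full(grid.shape, float(baseline))
    for c, w, a in zip(centers, widths, amplitudes):
        y = y + a * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return Spectrum(grid, y, spectrum_id, sample_id)


@pytest.fixture
def make_gaussian():
    return gaussian_spectrum


def tiny_study_config() -> StudyConfig:
    """Scaled-down study for fast unit tests (not the acceptance study)."""
    return StudyConfig(
        n_primaries=3,
        n_couplers=3,
        n_direct=3,
        n_products=8,
        samples_per_ox_product=3,
        samples_per_nonox_product=1,
        spectra_per_sample=3,
        spectra_per_nonox_sample=5,
        n_controls=1,
        spectra_per_control=5,
        calibration_samples_per_product=2,
        phase1_replicates=2,
        phase2_replicates=2,
        max_nonox_mixture_size=2,
        ox_train_fraction=0.34,
        simulation=SimulationConfig(noise_sigma=0.05, jitter=0.2),
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_study_config()


@pytest.fixture(scope="session")
def tiny_library(tiny_cfg):
    library, speclib = make_demo_library(7, tiny_cfg)
    return library, speclib, tiny_cfg


@pytest.fixture(scope="session")
def tiny_products(tiny_library):
    library, speclib, cfg = tiny_library
    return make_products(library, 7, cfg)
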