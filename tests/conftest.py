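import logging

import numpy as np
import pytest

from rbcspec.preprocess import PreprocessConfig, default_config_for
from rbcspec.spectra_io import Modality, Spectrum, Stage
from rbcspec.synthetic import default_cohort_config, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # expected-warning paths (despiking aborts on noiseless spectra etc.)
    # should not spam test output
    logging.getLogger("rbcspec").setLevel(logging.ERROR)
    yield


@pytest.fixture
def ftir_config() -> PreprocessConfig:
    return default_config_for(Modality.FTIR)


@pytest.fixture
def raman_config() -> PreprocessConfig:
    return default_config_for(Modality.RAMAN)


def make_spectrum(x, y, modality=Modality.FTIR, stage=Stage.RAW, sample_id="s1", group="control"):
    return Spectrum(
        wavenumbers=np.asarray(x, dtype=float),
        intensities=np.asarray(y, dtype=float),
        modality=modality,
        sample_id=sample_id,
        group=group,
        stage=stage,
    )


@pytest.fixture
def gaussian_spectrum():
    """Unit-amplitude Gaussian (center 2000, sigma 5) on a 1 cm^-1 grid."""
    x = np.arange(1900.0, 2101.0)
    y = np.exp(-0.5 * ((x - 2000.0) / 5.0) ** 2)
    return make_spectrum(x, y)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic noiseless cohort shared by truth-recovery tests."""
    cfg = default_cohort_config(seed=11, n_control=3, n_treated=3, amplitude_cv=0.0)
    cfg.noise_sd_ftir = 0.0
    cfg.noise_sd_raman = 0.0
    cfg.cosmic_rate = 0.0
    raw, raw2d, truth = generate_cohort(cfg)
    return cfg, raw, raw2d, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default noisy cohort (CV 5%, spikes on) shared by pipeline tests."""
    cfg = default_cohort_config(seed=23, n_control=5, n_treated=5)
    raw, raw2d, truth = generate_cohort(cfg)
    return cfg, raw, raw2d, truth
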