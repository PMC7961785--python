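"""Synthetic two-group cohorts with retained ground truth.

Spectra are sums of analytic band profiles (Gaussian / Lorentzian /
pseudo-Voigt) on a smooth polynomial baseline with white noise; Raman
spectra additionally receive cosmic-ray spikes.  Band amplitudes vary
log-normally across samples, and treated-group mean amplitudes are scaled
by per-band effect multipliers.  Every generated spectrum keeps a
noise-free twin and its analytic band areas in the truth store, so each
downstream stage can be checked against a known answer.

All randomness flows through a single ``numpy.random.Generator`` seeded
from the config; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from rbcspec.errors import ConfigError, InputError
from rbcspec.hemorheology import DeformabilityRecord, derive_cbc, CBCRecord
from rbcspec.spectra_io import Modality, Spectrum, SpectrumSet, Stage

__all__ = [
    "BandModel",
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "default_cohort_config",
    "generate_spectrum",
    "generate_cohort",
    "generate_deformability",
    "generate_cbc",
    "band_profile",
    "analytic_band_area",
    "analytic_band_area_windowed",
]

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class BandModel:
    """Analytic profile of one synthetic band.

    ``width`` is the full width at half maximum; ``eta`` is the Lorentzian
    fraction for pseudo-Voigt profiles.
    """

    shape: str  # {"gaussian", "lorentzian", "pseudo_voigt"}
    center: float
    width: float
    amplitude: float
    amplitude_cv: float = 0.0
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in {"gaussian", "lorentzian", "pseudo_voigt"}:
            raise ConfigError(f"unknown band shape {self.shape!r}")
        if self.width <= 0 or self.amplitude < 0 or self.amplitude_cv < 0:
            raise ConfigError("width must be > 0; amplitude and CV must be >= 0")
        if not 0 <= self.eta <= 1:
            raise ConfigError("pseudo-Voigt eta must be in [0, 1]")


def band_profile(model: BandModel, x: np.ndarray, amplitude: float | None = None) -> np.ndarray:
    """Evaluate the unit-amplitude-scaled profile on the grid ``x``."""
    a = model.amplitude if amplitude is None else amplitude
    if model.shape == "gaussian":
        sigma = model.width * GAUSS_FWHM_TO_SIGMA
        return a * np.exp(-0.5 * ((x - model.center) / sigma) ** 2)
    if model.shape == "lorentzian":
        gamma = model.width / 2.0  # HWHM
        return a * gamma**2 / ((x - model.center) ** 2 + gamma**2)
    # pseudo-Voigt: eta * Lorentzian + (1 - eta) * Gaussian, same FWHM
    sigma = model.width * GAUSS_FWHM_TO_SIGMA
    gamma = model.width / 2.0
    g = np.exp(-0.5 * ((x - model.center) / sigma) ** 2)
    lo = gamma**2 / ((x - model.center) ** 2 + gamma**2)
    return a * (model.eta * lo + (1.0 - model.eta) * g)


def analytic_band_area_windowed(
    model: BandModel, low: float, high: float, amplitude: float | None = None
) -> float:
    """Closed-form area of the profile over [low, high]."""
    a = model.amplitude if amplitude is None else amplitude
    sigma = model.width * GAUSS_FWHM_TO_SIGMA
    gamma = model.width / 2.0
    c = model.center
    gauss = (
        a * sigma * math.sqrt(math.pi / 2.0)
        * (math.erf((high - c) / (sigma * math.sqrt(2))) - math.erf((low - c) / (sigma * math.sqrt(2))))
    )
    lorentz = a * gamma * (math.atan((high - c) / gamma) - math.atan((low - c) / gamma))
    if model.shape == "gaussian":
        return gauss
    if model.shape == "lorentzian":
        return lorentz
    return model.eta * lorentz + (1.0 - model.eta) * gauss


def analytic_band_area(model: BandModel, amplitude: float | None = None) -> float:
    """Closed-form area of the full profile over (-inf, inf)."""
    a = model.amplitude if amplitude is None else amplitude
    sigma = model.width * GAUSS_FWHM_TO_SIGMA
    gamma = model.width / 2.0
    gauss_area = a * sigma * math.sqrt(2.0 * math.pi)
    lorentz_area = a * math.pi * gamma
    if model.shape == "gaussian":
        return gauss_area
    if model.shape == "lorentzian":
        return lorentz_area
    return model.eta * lorentz_area + (1.0 - model.eta) * gauss_area


# --- default band models ---------------------------------------------------
# Amplitudes are chosen so the amide bands dominate the FTIR vector norm
# (as in measured membrane spectra) and lipid marker bands are small; this
# keeps normalization cross-talk between bands well below the sample CV.

DEFAULT_FTIR_BANDS: dict[str, BandModel] = {
    # lipid marker bands are kept small relative to the amide bands so the
    # vector norm is amide-dominated and group effects on lipid bands do not
    # leak into the protein indices through normalization
    "amide_I": BandModel("gaussian", 1651, 30, 1.00),
    "amide_II": BandModel("gaussian", 1544, 16, 0.60),
    "ch_window_A": BandModel("gaussian", 2855, 9, 0.11),
    "ch_window_B": BandModel("gaussian", 2950, 12, 0.13),
    "po2_asym": BandModel("gaussian", 1236, 18, 0.14),
    "co_o_c": BandModel("gaussian", 1167, 18, 0.09),
    "ester_co_1738": BandModel("gaussian", 1738, 20, 0.06),
}

DEFAULT_RAMAN_BANDS: dict[str, BandModel] = {
    "raman_ester_co": BandModel("gaussian", 1743, 20, 60.0),
    "raman_cc": BandModel("gaussian", 1661, 20, 90.0),
    "raman_ch_def": BandModel("gaussian", 1447, 24, 150.0),
    "raman_phe": BandModel("gaussian", 1007, 14, 80.0),
}

# amide I fine structure for the second-derivative (intact-cell) branch:
# alpha-helix 1650, turns 1660, unordered 1640; widths 12 cm^-1
DEFAULT_AMIDE_SUBBANDS: dict[str, BandModel] = {
    "helix_1650": BandModel("gaussian", 1650, 12, 0.80),
    "turns_1660": BandModel("gaussian", 1660, 12, 0.40),
    "unordered_1640": BandModel("gaussian", 1640, 12, 0.35),
}

# default aging scenario: phospholipids down, unsaturation down, acyl chain
# shortening up; amide bands unchanged
DEFAULT_EFFECT_MULTIPLIERS: dict[str, float] = {
    "po2_asym": 0.75,
    "raman_cc": 0.8,
    "ch_window_B": 1.25,
    "amide_I": 1.0,
    "amide_II": 1.0,
}


@dataclass
class SyntheticCohortConfig:
    """Generative description of a two-group cohort."""

    n_control: int = 3
    n_treated: int = 3
    modalities: tuple[str, ...] = ("FTIR", "RAMAN")
    grid_ftir: tuple[float, float, float] = (900.0, 3800.0, 1.0)  # start, stop, step
    grid_raman: tuple[float, float, float] = (400.0, 1800.0, 1.0)
    band_models: dict[str, BandModel] = field(default_factory=dict)  # per modality defaults if empty
    amide_subbands: dict[str, BandModel] = field(
        default_factory=lambda: dict(DEFAULT_AMIDE_SUBBANDS)
    )
    effect_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MULTIPLIERS)
    )
    amplitude_cv: float = 0.05
    # FTIR default baseline is zero: the FTIR chain applies no baseline
    # correction (normalized ATR absorbance is analyzed directly), so the
    # emulated FTIR spectra are baseline-free; Raman gets a linear baseline
    # that the rubberband correction removes exactly.
    baseline_coeffs_ftir: tuple[float, ...] = (0.0,)
    baseline_coeffs_raman: tuple[float, ...] = (40.0, 10.0)
    noise_sd_ftir: float = 0.0015
    noise_sd_raman: float = 1.0
    cosmic_rate: float = 1.0  # expected spikes per Raman spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_treated < 0:
            raise ConfigError("group sizes must be non-negative")
        for g in (self.grid_ftir, self.grid_raman):
            if g[2] <= 0 or g[1] <= g[0]:
                raise ConfigError(f"bad grid {g}")
        if self.amplitude_cv < 0 or self.noise_sd_ftir < 0 or self.noise_sd_raman < 0:
            raise ConfigError("CV and noise SDs must be >= 0")
        if self.cosmic_rate < 0:
            raise ConfigError("cosmic_rate must be >= 0")
        for name, m in self.effect_multipliers.items():
            if m <= 0:
                raise ConfigError(f"effect multiplier for {name!r} must be > 0")

    def grid(self, modality: Modality) -> np.ndarray:
        start, stop, step = (
            self.grid_ftir if Modality(modality) == Modality.FTIR else self.grid_raman
        )
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)

    def bands_for(self, modality: Modality) -> dict[str, BandModel]:
        """Band models for a modality: user-supplied (filtered to bands whose
        center falls on this modality's grid) or the built-in defaults."""
        if not self.band_models:
            defaults = (
                DEFAULT_FTIR_BANDS
                if Modality(modality) == Modality.FTIR
                else DEFAULT_RAMAN_BANDS
            )
            return dict(defaults)
        grid = self.grid(modality)
        return {
            name: bm
            for name, bm in self.band_models.items()
            if grid[0] <= bm.center <= grid[-1]
        }

    def baseline_coeffs(self, modality: Modality) -> tuple[float, ...]:
        return (
            self.baseline_coeffs_ftir
            if Modality(modality) == Modality.FTIR
            else self.baseline_coeffs_raman
        )

    def noise_sd(self, modality: Modality) -> float:
        return self.noise_sd_ftir if Modality(modality) == Modality.FTIR else self.noise_sd_raman

    def to_dict(self) -> dict:
        return asdict(self)


def default_cohort_config(
    seed: int = 0,
    n_control: int = 3,
    n_treated: int = 3,
    amplitude_cv: float = 0.05,
    effect_multipliers: Mapping[str, float] | None = None,
    **kwargs,
) -> SyntheticCohortConfig:
    """Config for the default D-gal-style aging scenario."""
    return SyntheticCohortConfig(
        n_control=n_control,
        n_treated=n_treated,
        amplitude_cv=amplitude_cv,
        effect_multipliers=(
            dict(effect_multipliers)
            if effect_multipliers is not None
            else dict(DEFAULT_EFFECT_MULTIPLIERS)
        ),
        seed=seed,
        **kwargs,
    )


@dataclass
class SyntheticTruth:
    """Ground truth retained for every generated spectrum.

    ``entries`` maps (sample_id, modality) to a dict with keys:
    ``clean``  noise-free intensities (bands + baseline, no noise/spikes),
    ``amplitudes``  per-band sampled amplitude,
    ``areas``  per-band analytic area at the sampled amplitude,
    ``spike_positions``  indices of injected cosmic rays (Raman).
    """

    entries: dict[tuple[str, str], dict] = field(default_factory=dict)
    effect_multipliers: dict[str, float] = field(default_factory=dict)

    def clean_spectrum(self, s: Spectrum) -> Spectrum:
        """The noise-free twin of a generated spectrum."""
        key = (s.sample_id, s.modality.value)
        if key not in self.entries:
            raise InputError(f"no truth entry for {key}")
        return s.with_intensities(self.entries[key]["clean"])

    def programmed_direction(self, band: str) -> str:
        m = self.effect_multipliers.get(band, 1.0)
        return "UP" if m > 1 else ("DOWN" if m < 1 else "NONE")


def _lognormal_amplitude(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with the requested mean and coefficient of variation."""
    if mean == 0 or cv == 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def generate_spectrum(
    cfg: SyntheticCohortConfig,
    modality: Modality | str,
    group: str,
    sample_id: str,
    rng: np.random.Generator,
    band_models: Mapping[str, BandModel] | None = None,
) -> tuple[Spectrum, dict]:
    """Generate one spectrum and its truth entry.

    intensity(nu) = sum_i A_i * shape_i(nu) + baseline(nu) + eps(nu) with
    A_i log-normal around the band mean (times the effect multiplier for
    treated samples) and eps white Gaussian noise; Raman spectra receive
    Poisson(cosmic_rate) positive spikes of 20-100x the local amplitude.
    """
    modality = Modality(modality)
    x = cfg.grid(modality)
    models = dict(band_models) if band_models is not None else cfg.bands_for(modality)
    for name, bm in models.items():
        if not (x[0] <= bm.center <= x[-1]):
            raise ConfigError(f"band {name!r} center {bm.center} outside grid")
    treated = group == "treated"
    amplitudes: dict[str, float] = {}
    areas: dict[str, float] = {}
    clean = np.polynomial.polynomial.polyval(
        (x - x[0]) / (x[-1] - x[0]), np.asarray(cfg.baseline_coeffs(modality))
    )
    for name, bm in models.items():
        mean_amp = bm.amplitude * (cfg.effect_multipliers.get(name, 1.0) if treated else 1.0)
        cv = bm.amplitude_cv if bm.amplitude_cv > 0 else cfg.amplitude_cv
        a = _lognormal_amplitude(rng, mean_amp, cv)
        amplitudes[name] = a
        areas[name] = analytic_band_area(bm, a)
        clean = clean + band_profile(bm, x, a)
    noise_sd = cfg.noise_sd(modality)
    y = clean + (rng.normal(0.0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0)
    spike_positions: list[int] = []
    if modality == Modality.RAMAN and cfg.cosmic_rate > 0:
        n_spikes = int(rng.poisson(cfg.cosmic_rate))
        if n_spikes:
            idx = rng.choice(len(x), size=n_spikes, replace=False)
            local = np.maximum(np.abs(y[idx]), 1.0)
            y = y.copy()
            y[idx] = y[idx] + local * rng.uniform(20.0, 100.0, size=n_spikes)
            spike_positions = sorted(int(i) for i in idx)
    spectrum = Spectrum(
        wavenumbers=x,
        intensities=y,
        modality=modality,
        sample_id=sample_id,
        group=group,
        stage=Stage.RAW,
    )
    truth = {
        "clean": clean,
        "amplitudes": amplitudes,
        "areas": areas,
        "spike_positions": spike_positions,
    }
    return spectrum, truth


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[SpectrumSet, SpectrumSet, SyntheticTruth]:
    """Generate the full cohort.

    Returns ``(raw, raw_2d, truth)``: the raw marker-band spectra for every
    configured modality, a parallel FTIR set whose amide I region carries
    the three-sub-band fine structure (input of the second-derivative
    secondary-structure analysis), and the truth store covering both.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth(effect_multipliers=dict(cfg.effect_multipliers))
    spectra: list[Spectrum] = []
    spectra_2d: list[Spectrum] = []
    sample_ids = [(f"ctrl{i:02d}", "control") for i in range(1, cfg.n_control + 1)] + [
        (f"trt{i:02d}", "treated") for i in range(1, cfg.n_treated + 1)
    ]
    for sample_id, group in sample_ids:
        for mod_name in cfg.modalities:
            modality = Modality(mod_name)
            s, t = generate_spectrum(cfg, modality, group, sample_id, rng)
            spectra.append(s)
            truth.entries[(sample_id, modality.value)] = t
        if Modality.FTIR in [Modality(m) for m in cfg.modalities]:
            models = dict(cfg.bands_for(Modality.FTIR))
            models.pop("amide_I", None)  # replaced by the fine structure
            models.update(cfg.amide_subbands)
            s2, t2 = generate_spectrum(
                cfg, Modality.FTIR, group, f"{sample_id}_2d", rng, band_models=models
            )
            spectra_2d.append(s2)
            truth.entries[(f"{sample_id}_2d", Modality.FTIR.value)] = t2
    return SpectrumSet(spectra=spectra), SpectrumSet(spectra=spectra_2d), truth


def generate_deformability(
    n_per_group: Mapping[str, int],
    ei_max_mean: Mapping[str, float],
    sigma_half: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 14,
) -> list[DeformabilityRecord]:
    """Generate saturating EI(sigma) = EImax * sigma / (sigma + sigma_half)
    sweeps over 0.5-20 Pa.

    L and W are synthesized on a unit scale consistent with each noisy EI.
    """
    if sigma_half <= 0:
        raise InputError("sigma_half must be positive")
    rng = np.random.default_rng(seed)
    shear = np.linspace(0.5, 20.0, n_points)
    records = []
    for group in n_per_group:
        emm = ei_max_mean[group]
        for i in range(1, n_per_group[group] + 1):
            ei_inf = emm * (1.0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            curve = []
            for sigma in shear:
                ei = ei_inf * sigma / (sigma + sigma_half)
                if noise_sd > 0:
                    ei += rng.normal(0.0, noise_sd)
                ei = float(np.clip(ei, -0.99, 0.99))
                curve.append((float(sigma), 1.0 + ei, 1.0 - ei, ei))
            records.append(
                DeformabilityRecord(
                    sample_id=f"{group}{i:02d}", curve=curve, group=group
                )
            )
    return records


def generate_cbc(
    n_per_group: Mapping[str, int],
    means: Mapping[str, tuple[float, float, float]],
    sds: Mapping[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> list[CBCRecord]:
    """Generate CBC records from per-group (HGB, HCT, RBC) means and SDs."""
    rng = np.random.default_rng(seed)
    records = []
    for group in n_per_group:
        mu = np.asarray(means[group], dtype=float)
        sd = np.asarray(sds[group], dtype=float) if sds is not None else np.zeros(3)
        for i in range(1, n_per_group[group] + 1):
            vals = mu + (rng.normal(0.0, 1.0, size=3) * sd if sd.any() else 0.0)
            vals = np.maximum(vals, 1e-6)
            records.append(
                derive_cbc(
                    HGB=float(vals[0]), HCT=float(vals[1]), RBC=float(vals[2]),
                    sample_id=f"{group}{i:02d}", group=group,
                )
            )
    return records
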