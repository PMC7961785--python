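"""Spectral preprocessing chains.

FTIR chain (defaults): smooth -> (optional ATR correction) -> vector
normalization over 900-3600 cm^-1.  Raman chain (defaults): cosmic-ray
removal -> smooth -> rubberband baseline -> vector normalization.  Second
derivatives branch from the smoothed (and by default normalized) spectrum
using a Savitzky-Golay derivative filter with the same 13-point window.

All operations preserve the wavenumber axis bit-exactly and append a
provenance record to ``Spectrum.meta["ops"]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from rbcspec.errors import ConfigError, InputError
from rbcspec.spectra_io import Modality, Spectrum, Stage

__all__ = [
    "PreprocessConfig",
    "savitzky_golay_smooth",
    "second_derivative",
    "remove_cosmic_rays",
    "remove_baseline",
    "normalize",
    "atr_correct",
    "preprocess_spectrum",
    "second_derivative_spectrum",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults follow the published workflow: 13-point Savitzky-Golay window,
    normalization over 900-3600 cm^-1.  The polynomial order (3) and the
    baseline method are implementation choices recorded in provenance.
    """

    sg_window: int = 13
    sg_polyorder: int = 3
    norm_range: tuple[float, float] = (900.0, 3600.0)
    baseline_method: str = "rubberband"  # {"rubberband", "poly", "none"}
    poly_degree: int = 3
    cosmic_z_threshold: float = 8.0
    atr_correction: bool = False
    atr_reference_wavenumber: float = 1650.0
    # order of the derivative branch: if True the spectrum is normalized
    # before the second derivative is taken
    derivative_after_normalization: bool = True
    # min-max (range) scaling of the second-derivative amide I region; pure
    # scale factor, cancels in every ratio
    second_derivative_scale_range: tuple[float, float] = (1600.0, 1700.0)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ConfigError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window < self.sg_polyorder + 2:
            raise ConfigError(
                f"sg_window ({self.sg_window}) must be >= sg_polyorder+2 "
                f"({self.sg_polyorder + 2})"
            )
        low, high = self.norm_range
        if not low < high:
            raise ConfigError(f"norm_range low must be < high, got {self.norm_range}")
        if self.cosmic_z_threshold <= 0:
            raise ConfigError("cosmic_z_threshold must be positive")
        if self.baseline_method not in {"rubberband", "poly", "none"}:
            raise ConfigError(f"unknown baseline method {self.baseline_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_uniform_grid(s: Spectrum) -> float:
    """Return the mean step; error if spacing is not near-uniform."""
    dx = np.diff(s.wavenumbers)
    if dx.max() / dx.min() > 1.01:
        raise InputError(
            "wavenumber grid is not near-uniform "
            f"(max/min step ratio {dx.max() / dx.min():.4f} > 1.01)"
        )
    return float(dx.mean())


def savitzky_golay_smooth(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Savitzky-Golay smoothing.

    Polynomials of degree <= ``sg_polyorder`` pass through unchanged away
    from the edges; edges are handled by polynomial refit over the last full
    window (scipy ``mode='interp'``).
    """
    _check_uniform_grid(s)
    if len(s) < cfg.sg_window:
        raise InputError(
            f"spectrum length {len(s)} shorter than SG window {cfg.sg_window}"
        )
    y = savgol_filter(s.intensities, cfg.sg_window, cfg.sg_polyorder, mode="interp")
    return s.with_intensities(
        y, op={"op": "savitzky_golay_smooth", "window": cfg.sg_window, "polyorder": cfg.sg_polyorder}
    )


def second_derivative(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Savitzky-Golay second derivative, units intensity/(cm^-1)^2.

    The interior of f(nu) = a*nu^2 maps exactly to the constant 2a.
    """
    delta = _check_uniform_grid(s)
    if len(s) < cfg.sg_window:
        raise InputError(
            f"spectrum length {len(s)} shorter than SG window {cfg.sg_window}"
        )
    y = savgol_filter(
        s.intensities, cfg.sg_window, cfg.sg_polyorder, deriv=2, delta=delta, mode="interp"
    )
    return s.with_intensities(
        y,
        stage=Stage.SECOND_DERIVATIVE,
        op={
            "op": "second_derivative",
            "window": cfg.sg_window,
            "polyorder": cfg.sg_polyorder,
            "delta": delta,
        },
    )


def _modified_zscores(v: np.ndarray) -> np.ndarray:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        # fall back to mean absolute deviation to avoid division by zero
        mad = np.mean(np.abs(v - med))
        if mad == 0:
            return np.zeros_like(v)
    return 0.6745 * (v - med) / mad


def _second_difference(y: np.ndarray) -> np.ndarray:
    d2 = np.zeros_like(y)
    d2[1:-1] = y[2:] - 2 * y[1:-1] + y[:-2]
    return d2


def remove_cosmic_rays(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Iterative despiking by modified z-score of the second difference.

    The single worst offender above ``cosmic_z_threshold`` is replaced by
    linear interpolation of its nearest unflagged neighbors, then z-scores
    are recomputed; iteration stops when no point exceeds the threshold.
    Replacing one point at a time keeps the neighbors of a spike (whose
    second difference is also inflated) bit-identical.  If more than 10% of
    points would be flagged, a warning is logged and the spectrum is
    returned unmodified with the flags in ``meta["cosmic_flags"]``.
    """
    if s.modality != Modality.RAMAN:
        raise InputError("cosmic-ray removal applies to Raman spectra only")
    y = s.intensities.copy()
    n = len(y)
    max_replacements = max(1, int(0.10 * n))
    flagged: list[int] = []
    for _ in range(n):
        z = np.abs(_modified_zscores(_second_difference(y)))
        z[flagged] = 0.0
        worst = int(np.argmax(z))
        if z[worst] <= cfg.cosmic_z_threshold:
            break
        flagged.append(worst)
        if len(flagged) > max_replacements:
            logger.warning(
                "cosmic-ray removal flagged >10%% of points in %s; threshold %.1f "
                "looks misconfigured — returning spectrum unchanged",
                s.sample_id,
                cfg.cosmic_z_threshold,
            )
            out = s.with_intensities(
                s.intensities, op={"op": "remove_cosmic_rays", "aborted": True}
            )
            out.meta["cosmic_flags"] = sorted(flagged)
            return out
        good = np.setdiff1d(np.arange(n), np.asarray(flagged))
        y[flagged] = np.interp(s.wavenumbers[flagged], s.wavenumbers[good], y[good])
    out = s.with_intensities(
        y, op={"op": "remove_cosmic_rays", "n_replaced": len(flagged)}
    )
    out.meta["cosmic_flags"] = sorted(flagged)
    return out


def _rubberband_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull baseline (monotone-chain on the lower hull)."""
    n = len(x)
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # cross product; keep turns that stay convex from below
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hx, hy = x[hull], y[hull]
    return np.interp(x, hx, hy)


def _poly_baseline(x: np.ndarray, y: np.ndarray, degree: int, n_iter: int = 100) -> np.ndarray:
    """Iteratively reweighted polynomial baseline (ModPoly-style clipping)."""
    # center/scale x for conditioning
    xs = (x - x.mean()) / (x.std() or 1.0)
    work = y.copy()
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coef = np.polynomial.polynomial.polyfit(xs, work, degree)
        fit = np.polynomial.polynomial.polyval(xs, coef)
        clipped = np.minimum(work, fit)
        if np.allclose(clipped, work, rtol=0, atol=1e-12 * max(1.0, np.abs(y).max())):
            break
        work = clipped
    return fit


def remove_baseline(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Subtract a baseline estimate.

    ``rubberband``: lower convex hull of (nu, intensity); output is zero at
    every hull anchor.  ``poly``: least-squares polynomial of
    ``poly_degree`` through iteratively clipped non-peak points.
    """
    if len(s) < 10:
        raise InputError("baseline removal needs at least 10 points")
    if cfg.baseline_method == "none":
        return s.with_intensities(s.intensities, op={"op": "remove_baseline", "method": "none"})
    if cfg.baseline_method == "rubberband":
        base = _rubberband_baseline(s.wavenumbers, s.intensities)
    elif cfg.baseline_method == "poly":
        base = _poly_baseline(s.wavenumbers, s.intensities, cfg.poly_degree)
    else:  # pragma: no cover - caught by config validation
        raise ConfigError(f"unknown baseline method {cfg.baseline_method!r}")
    return s.with_intensities(
        s.intensities - base,
        op={"op": "remove_baseline", "method": cfg.baseline_method},
    )


def normalize(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Vector normalization over ``norm_range``.

    Intensities are divided by the Euclidean norm of the points inside the
    range, so the in-range norm of the output is exactly 1.
    """
    low, high = cfg.norm_range
    mask = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    if not mask.any():
        raise InputError(
            f"spectrum [{s.wavenumbers[0]:.0f}, {s.wavenumbers[-1]:.0f}] does not "
            f"cover the normalization range [{low}, {high}]"
        )
    norm = float(np.linalg.norm(s.intensities[mask]))
    if norm == 0.0:
        raise InputError("all-zero intensities in the normalization range")
    return s.with_intensities(
        s.intensities / norm,
        op={"op": "normalize", "range": [low, high], "norm": norm},
    )


def atr_correct(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """First-order ATR penetration-depth correction.

    The evanescent-wave penetration depth scales as 1/nu, so absorbances are
    multiplied by nu / atr_reference_wavenumber; the value at the reference
    wavenumber is unchanged.  This is a documented simple stand-in for the
    vendor's proprietary extended correction and is OFF by default.
    """
    if s.modality != Modality.FTIR:
        raise InputError("ATR correction applies to FTIR spectra only")
    if np.any(s.wavenumbers <= 0):
        raise InputError("ATR correction requires positive wavenumbers")
    scale = s.wavenumbers / cfg.atr_reference_wavenumber
    return s.with_intensities(
        s.intensities * scale,
        op={"op": "atr_correct", "reference": cfg.atr_reference_wavenumber},
    )


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full chain: (cosmic-ray) -> smooth -> baseline -> (ATR) -> normalize.

    Cosmic-ray removal runs for Raman only; ATR correction for FTIR only and
    only when enabled.  Default baseline: rubberband for Raman, none for
    FTIR (normalized ATR absorbance is analyzed directly).
    """
    if cfg is None:
        cfg = default_config_for(s.modality)
    out = s
    if s.modality == Modality.RAMAN:
        out = remove_cosmic_rays(out, cfg)
    out = savitzky_golay_smooth(out, cfg)
    out = remove_baseline(out, cfg)
    if s.modality == Modality.FTIR and cfg.atr_correction:
        out = atr_correct(out, cfg)
    out = normalize(out, cfg)
    out.stage = Stage.PREPROCESSED
    return out


def second_derivative_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Derivative branch: smooth, (normalize), second derivative, range-scale.

    With ``derivative_after_normalization`` (default) the spectrum is vector
    normalized before differentiation.  The result is divided by the
    peak-to-peak range of the second derivative inside
    ``second_derivative_scale_range`` — a pure scale factor (no offset) so
    every downstream ratio is unaffected; the choice is recorded in
    provenance.
    """
    if cfg is None:
        cfg = default_config_for(s.modality)
    out = savitzky_golay_smooth(s, cfg)
    if cfg.derivative_after_normalization:
        out = normalize(out, cfg)
    out = second_derivative(out, cfg)
    lo, hi = cfg.second_derivative_scale_range
    mask = (out.wavenumbers >= lo) & (out.wavenumbers <= hi)
    if mask.any():
        rng = float(np.ptp(out.intensities[mask]))
        if rng > 0:
            out = out.with_intensities(
                out.intensities / rng,
                stage=Stage.SECOND_DERIVATIVE,
                op={"op": "range_scale", "range": [lo, hi], "factor": rng},
            )
    return out


def default_config_for(modality: Modality | str) -> PreprocessConfig:
    """Modality defaults: rubberband baseline for Raman, none for FTIR."""
    modality = Modality(modality)
    if modality == Modality.RAMAN:
        return PreprocessConfig(baseline_method="rubberband", norm_range=(400.0, 1800.0))
    return PreprocessConfig(baseline_method="none", norm_range=(900.0, 3600.0))
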