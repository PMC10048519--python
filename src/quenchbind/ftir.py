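"""Amide-band analysis of protein FTIR spectra.

The amide I band (1700-1600 cm^-1) is a superposition of component bands
whose positions report secondary structure.  The band is deconvolved into
Gaussians seeded at negative second-derivative minima (Savitzky-Golay) and
refined by bounded least squares; component areas are pooled by standard
assignment windows into beta-sheet, random-coil, alpha-helix and beta-turn
percentages.

The assignment windows (cm^-1) are the usual amide-I convention and are
configurable:

    beta-sheet   1610-1640 and 1682-1700
    random coil  1640-1650
    alpha-helix  1650-1660
    beta-turn    1660-1682
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import argrelmin, savgol_filter

__all__ = [
    "IRSpectrum",
    "GaussianBand",
    "SecondaryStructure",
    "ASSIGNMENT_WINDOWS",
    "AMIDE_I_WINDOW",
    "AMIDE_II_WINDOW",
    "amide_peaks",
    "deconvolve_amide_I",
]

AMIDE_I_WINDOW = (1600.0, 1700.0)
AMIDE_II_WINDOW = (1500.0, 1600.0)

ASSIGNMENT_WINDOWS: dict[str, tuple[tuple[float, float], ...]] = {
    "beta_sheet": ((1610.0, 1640.0), (1682.0, 1700.0)),
    "random_coil": ((1640.0, 1650.0),),
    "alpha_helix": ((1650.0, 1660.0),),
    "beta_turn": ((1660.0, 1682.0),),
}

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = _FWHM * sigma


@dataclass(frozen=True)
class IRSpectrum:
    """Absorbance spectrum; wavenumbers normalised to ascending order."""

    wavenumbers: np.ndarray  # cm^-1
    absorbance: np.ndarray  # AU

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or wn.shape != ab.shape:
            raise ValueError("wavenumbers and absorbance must be 1-D and equal length")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum values must be finite")
        order = np.argsort(wn)
        wn, ab = wn[order], ab[order]
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be distinct")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class GaussianBand:
    center: float  # cm^-1
    fwhm: float  # cm^-1
    area: float
    amplitude: float
    assignment: str  # assignment-window label or "unassigned"


@dataclass(frozen=True)
class SecondaryStructure:
    beta_sheet: float
    random_coil: float
    alpha_helix: float
    beta_turn: float

    def __post_init__(self):
        vals = self.as_dict().values()
        if any(v < -1e-9 or v > 100 + 1e-9 for v in vals):
            raise ValueError("percentages must lie in [0, 100]")
        if abs(sum(vals) - 100.0) > 0.5:
            raise ValueError("percentages must sum to 100 +/- 0.5")

    def as_dict(self) -> dict[str, float]:
        return {
            "beta_sheet": self.beta_sheet,
            "random_coil": self.random_coil,
            "alpha_helix": self.alpha_helix,
            "beta_turn": self.beta_turn,
        }


def _window_peak(s: IRSpectrum, window: tuple[float, float]) -> tuple[float, float]:
    lo, hi = window
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"spectrum does not cover the {lo:g}-{hi:g} cm^-1 window")
    wn = s.wavenumbers[mask]
    ab = s.absorbance[mask]
    if np.ptp(ab) <= 1e-12 * max(1.0, abs(float(ab.max()))):
        raise ValueError("no peak above baseline in window")
    i = int(np.argmax(ab))  # first maximum -> lowest wavenumber on ties
    return float(wn[i]), float(ab[i])


def amide_peaks(s: IRSpectrum) -> dict:
    """Positions and intensities of the amide I and II absorbance maxima.

    Invariant to input wavenumber ordering (normalised on construction) and
    to uniform absorbance scaling; ties resolve to the lower wavenumber.
    """
    pos_i, int_i = _window_peak(s, AMIDE_I_WINDOW)
    pos_ii, int_ii = _window_peak(s, AMIDE_II_WINDOW)
    return {
        "amide_I_position": pos_i,
        "amide_I_intensity": int_i,
        "amide_II_position": pos_ii,
        "amide_II_intensity": int_ii,
    }


def _assign(center: float, windows: dict) -> str:
    for name, spans in windows.items():
        if any(lo <= center < hi for lo, hi in spans):
            return name
    return "unassigned"


def _detect_seeds(
    x: np.ndarray,
    y: np.ndarray,
    sg_window: int,
    sg_poly: int,
    min_depth_frac: float,
    min_separation: float,
) -> np.ndarray:
    """Candidate band centers: negative minima of the smoothed 2nd derivative."""
    step = float(np.median(np.diff(x)))
    win = min(sg_window, (len(x) // 2) * 2 - 1)
    smooth = savgol_filter(y, win, sg_poly)
    d2 = savgol_filter(smooth, win, sg_poly, deriv=2, delta=step)
    order = max(2, int(round(min_separation / step)))
    idx = argrelmin(d2, order=order)[0]
    if idx.size == 0 or d2.min() >= 0:
        return np.array([])
    idx = idx[d2[idx] < min_depth_frac * d2.min()]
    return x[idx[np.argsort(d2[idx])]]  # deepest first


def deconvolve_amide_I(
    s: IRSpectrum,
    n_bands: int | None = None,
    windows: dict | None = None,
    sg_window: int = 9,
    sg_poly: int = 3,
    center_slack: float = 4.0,
    fwhm_bounds: tuple[float, float] = (5.0, 30.0),
    min_depth_frac: float = 0.1,
    min_separation: float = 4.0,
    seed_missing_windows: bool = True,
) -> tuple[list[GaussianBand], SecondaryStructure]:
    """Deconvolve the amide I region into Gaussian bands and pool areas.

    A linear baseline between the window endpoints is removed; candidate
    centers come from negative second-derivative minima (Savitzky-Golay,
    ``sg_window`` points, order ``sg_poly``), deepest first, capped at
    ``n_bands`` when given.  Any assignment window left without a candidate
    is seeded at its midpoint (one component per window is the amide-I
    convention) unless ``seed_missing_windows`` is off.  Bands are refined
    by bounded least squares: centers within +/-``center_slack`` cm^-1 of
    their seeds, FWHM in ``fwhm_bounds``, non-negative amplitudes.
    Percentages are renormalised to sum to 100.
    """
    windows = ASSIGNMENT_WINDOWS if windows is None else windows
    lo, hi = AMIDE_I_WINDOW
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if mask.sum() < 7:
        raise ValueError("spectrum does not cover the amide I window")
    x = s.wavenumbers[mask]
    y = s.absorbance[mask]
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    y = y - baseline
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise ValueError("no peak above baseline in the amide I window")

    seeds = list(_detect_seeds(x, y, sg_window, sg_poly, min_depth_frac, min_separation))
    if n_bands is not None and len(seeds) > n_bands:
        seeds = seeds[:n_bands]
    if seed_missing_windows:
        for name, spans in windows.items():
            covered = any(
                any(wlo <= c < whi for wlo, whi in spans) for c in seeds
            )
            if not covered:
                wlo, whi = spans[0] if len(spans) == 1 else max(spans, key=lambda w: w[1] - w[0])
                seeds.append(min(max((wlo + whi) / 2.0, lo), hi))
    seeds = np.sort(np.asarray(seeds, dtype=float))
    k = len(seeds)
    if k < 2:
        raise ValueError(
            f"fewer than 2 bands to fit (seeds at {list(seeds)}); "
            "spectrum too featureless for deconvolution"
        )

    sig_lo, sig_hi = fwhm_bounds[0] / _FWHM, fwhm_bounds[1] / _FWHM
    amp0 = np.clip(np.interp(seeds, x, y), 1e-12, None)
    p0 = np.r_[amp0, seeds, np.full(k, np.clip(12.0 / _FWHM, sig_lo, sig_hi))]
    lower = np.r_[np.zeros(k), seeds - center_slack, np.full(k, sig_lo)]
    upper = np.r_[np.full(k, 2.0 * float(y.max())), seeds + center_slack, np.full(k, sig_hi)]

    def residual(p):
        a, c, sg = p[:k], p[k : 2 * k], p[2 * k :]
        model = np.zeros_like(x)
        for i in range(k):
            model += a[i] * np.exp(-((x - c[i]) ** 2) / (2.0 * sg[i] ** 2))
        return model - y

    fit = least_squares(residual, p0, bounds=(lower, upper))
    if not fit.success:
        raise RuntimeError(
            f"amide I deconvolution did not converge (seeds: {list(seeds)})"
        )
    a, c, sg = fit.x[:k], fit.x[k : 2 * k], fit.x[2 * k :]
    areas = a * sg * np.sqrt(2.0 * np.pi)

    bands = [
        GaussianBand(
            center=float(c[i]),
            fwhm=float(sg[i] * _FWHM),
            area=float(areas[i]),
            amplitude=float(a[i]),
            assignment=_assign(float(c[i]), windows),
        )
        for i in range(k)
    ]
    pooled = {name: 0.0 for name in windows}
    for b in bands:
        if b.assignment in pooled:
            pooled[b.assignment] += b.area
    total = sum(pooled.values())
    if total <= 0:
        raise RuntimeError("all fitted band areas are zero inside assignment windows")
    pct = {name: 100.0 * v / total for name, v in pooled.items()}
    return bands, SecondaryStructure(**pct)
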