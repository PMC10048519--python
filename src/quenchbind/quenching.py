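"""Fluorescence-quenching titration analysis.

Intrinsic protein fluorescence (280 nm excitation, 300-500 nm emission) is
quenched by a small-molecule ligand.  The titration is analysed with two
classical linear models:

* Stern-Volmer:  F0/F = 1 + Ksv[Q],  with Kq = Ksv / tau0 deciding the
  quenching mechanism (static above the diffusion-limited 2e10 L/mol/s).
* Double-logarithmic:  log10((F0-F)/F) = log10(KA) + n log10([Q]),  giving
  the apparent binding constant KA and the number of binding sites n.

Both fits are ordinary least squares on the linearised coordinates; the
Stern-Volmer intercept is left free as a background-subtraction diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "TitrationCurve",
    "PeakInfo",
    "QuenchAnalysis",
    "Mechanism",
    "DEFAULT_TAU0",
    "STATIC_KQ_THRESHOLD",
    "subtract_blank",
    "extract_titration",
    "fit_stern_volmer",
    "classify_mechanism",
    "fit_double_log",
    "analyze_titration",
]

#: Default fluorophore lifetime in seconds (biopolymer convention, ~1e-8 s).
DEFAULT_TAU0 = 1e-8

#: Kq above this (L mol^-1 s^-1) indicates static quenching.
STATIC_KQ_THRESHOLD = 2.0e10

EMISSION_WINDOW = (300.0, 500.0)


class Mechanism(str, Enum):
    STATIC = "static"
    NOT_STATIC = "not_static"


@dataclass(frozen=True)
class EmissionSpectrum:
    """One background-subtracted emission scan at a single quencher level."""

    temperature: float  # K
    quencher_conc: float  # mol/L
    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # AU, non-negative

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative after background subtraction")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)


@dataclass(frozen=True)
class PeakInfo:
    quencher_conc: float
    peak_intensity: float
    lambda_max: float
    shift: str  # "blue" | "red" | "none"


@dataclass(frozen=True)
class TitrationCurve:
    """Peak intensities F vs quencher concentration [Q] at one temperature."""

    temperature: float  # K
    q: np.ndarray  # mol/L, non-negative, strictly increasing
    f: np.ndarray  # AU
    f0: float  # intensity at [Q] = 0

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if q.shape != f.shape or q.ndim != 1:
            raise ValueError("q and f must be 1-D and equal length")
        if np.any(q < 0):
            raise ValueError("quencher concentrations must be non-negative")
        if np.any(np.diff(q) <= 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "f", f)

    @classmethod
    def from_points(cls, temperature, q, f, f0=None):
        """Build a curve; f0 is taken from the [Q]=0 point when not given."""
        q = np.asarray(q, dtype=float)
        f = np.asarray(f, dtype=float)
        if f0 is None:
            zero = np.flatnonzero(q == 0)
            if zero.size == 0:
                raise ValueError("no [Q]=0 point and no explicit f0 supplied")
            f0 = float(f[zero[0]])
        return cls(temperature=float(temperature), q=q, f=f, f0=float(f0))


@dataclass(frozen=True)
class QuenchAnalysis:
    """Joint result of the Stern-Volmer and double-log fits."""

    ksv: float  # L/mol
    kq: float  # L mol^-1 s^-1
    tau0: float  # s
    r2_sv: float
    ka: float  # L/mol
    n: float
    r2_dl: float
    mechanism: Mechanism
    sv_intercept: float = field(default=1.0)


def subtract_blank(sample: EmissionSpectrum, blank: EmissionSpectrum) -> EmissionSpectrum:
    """Subtract a blank (buffer/background) scan; negatives clipped to zero."""
    if not np.array_equal(sample.wavelengths, blank.wavelengths):
        raise ValueError("sample and blank must share the wavelength grid")
    corrected = np.clip(sample.intensities - blank.intensities, 0.0, None)
    return EmissionSpectrum(
        temperature=sample.temperature,
        quencher_conc=sample.quencher_conc,
        wavelengths=sample.wavelengths,
        intensities=corrected,
    )


def _peak(spectrum: EmissionSpectrum) -> tuple[float, float]:
    """(F, lambda_max) inside the emission window; argmax ties -> lowest nm."""
    lo, hi = EMISSION_WINDOW
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise ValueError("spectrum has no support in the 300-500 nm emission window")
    wl = spectrum.wavelengths[mask]
    it = spectrum.intensities[mask]
    i = int(np.argmax(it))  # first maximum = lowest wavelength on ties
    return float(it[i]), float(wl[i])


def extract_titration(
    spectra: list[EmissionSpectrum],
) -> tuple[TitrationCurve, list[PeakInfo]]:
    """Reduce an emission series to a titration curve plus peak metadata.

    F per spectrum is the maximum intensity in the 300-500 nm window (the
    peak is tracked, not a fixed wavelength, because the emission maximum
    shifts on binding).  The shift label compares lambda_max to the zero-
    quencher spectrum with a one-grid-step tolerance.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    ref = spectra[0]
    for s in spectra:
        if s.temperature != ref.temperature:
            raise ValueError("all spectra in a titration must share one temperature")
        if not np.array_equal(s.wavelengths, ref.wavelengths):
            raise ValueError("all spectra must share the wavelength grid")
    zero = [s for s in spectra if s.quencher_conc == 0]
    if len(zero) != 1:
        raise ValueError("exactly one zero-quencher spectrum is required")
    f0, lmax0 = _peak(zero[0])
    step = float(np.min(np.diff(ref.wavelengths))) if ref.wavelengths.size > 1 else 0.0

    ordered = sorted(spectra, key=lambda s: s.quencher_conc)
    peaks: list[PeakInfo] = []
    q, f = [], []
    for s in ordered:
        fi, lmax = _peak(s)
        if abs(lmax - lmax0) <= step:
            shift = "none"
        elif lmax < lmax0:
            shift = "blue"
        else:
            shift = "red"
        peaks.append(PeakInfo(s.quencher_conc, fi, lmax, shift))
        q.append(s.quencher_conc)
        f.append(fi)
    curve = TitrationCurve(temperature=ref.temperature, q=np.array(q), f=np.array(f), f0=f0)
    return curve, peaks


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_stern_volmer(
    curve: TitrationCurve, tau0: float = DEFAULT_TAU0
) -> tuple[float, float, float, float]:
    """OLS fit of F0/F on [Q]; returns (ksv, kq, r2, intercept).

    The intercept is fitted freely rather than pinned at 1: a free fit with
    |intercept - 1| > 0.05 flags bad background subtraction (warning).
    A non-positive slope is flagged as degenerate (warning), not raised,
    since an unquenched series legitimately gives Ksv = 0.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if curve.f0 <= 0 or np.any(curve.f <= 0):
        raise ValueError("all intensities must be positive for the Stern-Volmer fit")
    if np.unique(curve.q).size < 3:
        raise ValueError("need at least 3 distinct quencher concentrations")
    y = curve.f0 / curve.f
    slope, intercept = np.polyfit(curve.q, y, 1)
    r2 = _r2(y, slope * curve.q + intercept)
    if slope <= 0:
        warnings.warn(
            f"degenerate Stern-Volmer fit: non-positive slope Ksv={slope:.3g} "
            "(no quenching, or intensities rising with [Q])",
            stacklevel=2,
        )
    if abs(intercept - 1.0) > 0.05:
        warnings.warn(
            f"Stern-Volmer intercept {intercept:.4f} deviates from 1 by more than "
            "0.05; check background subtraction",
            stacklevel=2,
        )
    ksv = float(slope)
    return ksv, ksv / tau0, float(r2), float(intercept)


def classify_mechanism(kq: float) -> Mechanism:
    """Static quenching iff Kq strictly exceeds 2.0e10 L mol^-1 s^-1."""
    if not np.isfinite(kq) or kq < 0:
        raise ValueError("kq must be finite and non-negative")
    return Mechanism.STATIC if kq > STATIC_KQ_THRESHOLD else Mechanism.NOT_STATIC


def fit_double_log(
    curve: TitrationCurve, log_base: float = 10.0
) -> tuple[float, float, float]:
    """Fit log((F0-F)/F) = log(KA) + n log([Q]); returns (ka, n, r2).

    Base-10 logarithms by convention; any base gives the same n, and KA is
    recovered as base**intercept so the result is base-independent as long
    as both axes use the same base.  Points with F >= F0 at [Q] > 0 are
    rejected with a warning ([Q] = 0 is excluded by construction).
    """
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    if curve.f0 <= 0:
        raise ValueError("f0 must be positive")
    usable = (curve.q > 0) & (curve.f > 0) & (curve.f < curve.f0)
    n_bad = int(np.sum((curve.q > 0) & ~usable))
    if n_bad:
        warnings.warn(
            f"{n_bad} titration point(s) with F >= F0 (or F <= 0) at [Q] > 0 "
            "rejected from the double-log fit",
            stacklevel=2,
        )
    q = curve.q[usable]
    f = curve.f[usable]
    if q.size < 3:
        raise ValueError("fewer than 3 usable points for the double-log fit")
    lb = np.log(log_base)
    x = np.log(q) / lb
    y = np.log((curve.f0 - f) / f) / lb
    slope, intercept = np.polyfit(x, y, 1)
    r2 = _r2(y, slope * x + intercept)
    return float(log_base**intercept), float(slope), float(r2)


def analyze_titration(
    curve: TitrationCurve, tau0: float = DEFAULT_TAU0, log_base: float = 10.0
) -> QuenchAnalysis:
    """Run both fits and the mechanism rule on one titration curve."""
    ksv, kq, r2_sv, intercept = fit_stern_volmer(curve, tau0=tau0)
    ka, n, r2_dl = fit_double_log(curve, log_base=log_base)
    mechanism = classify_mechanism(max(kq, 0.0)) if kq >= 0 else Mechanism.NOT_STATIC
    return QuenchAnalysis(
        ksv=ksv,
        kq=kq,
        tau0=tau0,
        r2_sv=r2_sv,
        ka=ka,
        n=n,
        r2_dl=r2_dl,
        mechanism=mechanism,
        sv_intercept=intercept,
    )
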