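"""Synthetic instrument data with known ground truth.

Raw instrument data for this kind of study are rarely deposited, so every
pipeline stage is exercised on generated inputs whose truth is recorded:

* quenching titrations — F = F0 / (1 + KA(T) [Q]^n), the exact inverse of
  the double-log binding model, with KA(T) linked across temperatures by an
  exact van't Hoff enthalpy;
* emission spectra — Gaussian tryptophan-like peak whose amplitude follows
  the titration and whose center can shift with [Q];
* amide I/II spectra — Gaussian band mixtures with prescribed area fractions;
* release tables — replicate release rates by treatment group and phase.

Noise is additive Gaussian on intensities (fraction of F0 or of the signal
maximum), truncated at zero; every generator is reproducible from its seed
and returns a truth record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ftir import IRSpectrum
from .quenching import EmissionSpectrum, TitrationCurve
from .thermo import R_GAS

__all__ = [
    "QuenchScenario",
    "ReleaseScenario",
    "ka_at",
    "gen_titration",
    "gen_spectra",
    "gen_ftir",
    "gen_release",
    "DEFAULT_Q_GRID",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_FTIR_TRUTH",
]

#: Quencher grid, mol/L: 0-200 umol/L in the 9 steps of the study design.
DEFAULT_Q_GRID = tuple(c * 1e-6 for c in (0, 20, 40, 60, 80, 100, 120, 160, 200))

DEFAULT_TEMPERATURES = (297.0, 304.0, 311.0)

#: Default amide-I truth: (percent, center cm^-1, FWHM cm^-1) per class.
DEFAULT_FTIR_TRUTH = {
    "beta_sheet": (40.17, 1627.0, 24.0),
    "random_coil": (16.78, 1645.0, 10.0),
    "alpha_helix": (17.29, 1655.0, 10.0),
    "beta_turn": (25.77, 1669.0, 20.0),
}

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class QuenchScenario:
    """Ground truth for a temperature-resolved quenching experiment."""

    ka_ref: float = 4.13e4  # L/mol at t_ref
    t_ref: float = 297.0  # K
    dh: float = -50.17  # kJ/mol, exact van't Hoff link between temperatures
    n: float = 1.16  # binding sites
    f0: float = 1000.0  # unquenched peak intensity, AU
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    noise_sigma: float = 0.0  # fraction of f0
    seed: int = 0

    def ka(self, t: float) -> float:
        return ka_at(self.ka_ref, self.t_ref, self.dh, t)


def ka_at(ka_ref: float, t_ref: float, dh_kj_mol: float, t: float) -> float:
    """KA(T) from an exact two-parameter van't Hoff relation."""
    return float(ka_ref * np.exp(-dh_kj_mol * 1000.0 / R_GAS * (1.0 / t - 1.0 / t_ref)))


def gen_titration(
    sc: QuenchScenario, t: float, rng: np.random.Generator | None = None
) -> tuple[TitrationCurve, dict]:
    """Titration curve at temperature t, plus the truth record.

    F = F0 / (1 + KA(T) [Q]^n) so a noiseless curve inverts exactly under
    the double-log fit.  Gaussian noise (sigma x F0) is truncated at zero;
    each temperature gets an independent noise stream (seeded by the
    scenario seed and the temperature) since each scan is a separate
    measurement, while staying fully reproducible.
    """
    ka = sc.ka(t)
    q = np.asarray(sc.q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("quencher concentrations must be non-negative")
    denom = 1.0 + ka * np.where(q > 0, q, 1.0) ** sc.n
    f = np.where(q > 0, sc.f0 / denom, sc.f0)
    if not np.all(f > 0):
        raise ValueError("infeasible scenario: non-positive intensities")
    if sc.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng([sc.seed, int(round(t * 1000))])
        f = np.clip(f + rng.normal(0.0, sc.noise_sigma * sc.f0, f.shape), 0.0, None)
    curve = TitrationCurve(temperature=t, q=q, f=f, f0=sc.f0)
    truth = {"ka": ka, "n": sc.n, "f0": sc.f0, "dh": sc.dh, "temperature": t}
    return curve, truth


def gen_spectra(
    sc: QuenchScenario,
    t: float,
    peak_center: float = 340.0,
    peak_fwhm: float = 60.0,
    shift_at_max_q: float = 0.0,
    wavelengths: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[EmissionSpectrum], dict]:
    """Emission series whose peak amplitudes follow gen_titration.

    The peak center moves linearly with [Q], reaching ``shift_at_max_q`` nm
    (negative = blue shift) at the highest concentration.
    """
    wl = np.arange(300.0, 500.0 + 1.0, 1.0) if wavelengths is None else np.asarray(wavelengths)
    curve, truth = gen_titration(sc, t, rng=rng)
    qmax = max(sc.q_grid)
    sigma = peak_fwhm / _FWHM
    spectra = []
    for qi, fi in zip(curve.q, curve.f):
        center = peak_center + shift_at_max_q * (qi / qmax if qmax > 0 else 0.0)
        spectra.append(
            EmissionSpectrum(
                temperature=t,
                quencher_conc=float(qi),
                wavelengths=wl,
                intensities=fi * np.exp(-((wl - center) ** 2) / (2.0 * sigma**2)),
            )
        )
    truth = dict(truth, peak_center=peak_center, shift_at_max_q=shift_at_max_q)
    return spectra, truth


def gen_ftir(
    truth: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    step: float = 0.5,
    span: tuple[float, float] = (1450.0, 1750.0),
    amide_ii: tuple[float, float, float] | None = (1542.0, 0.35, 40.0),
) -> tuple[IRSpectrum, dict]:
    """Amide-region spectrum from a Gaussian band mixture.

    ``truth`` maps class -> (percent, center, FWHM); class areas are the
    percentages (total area 1 AU.cm^-1).  ``amide_ii`` optionally adds a
    single band (center, relative area, FWHM) outside the amide I window so
    the amide II peak exists too.  Noise is sigma x max(signal), Gaussian.
    """
    truth = DEFAULT_FTIR_TRUTH if truth is None else truth
    total = sum(v[0] for v in truth.values())
    if abs(total - 100.0) > 0.5:
        raise ValueError("truth percentages must sum to 100")
    wn = np.arange(span[0], span[1] + step, step)
    y = np.zeros_like(wn)
    for pct, center, fwhm in truth.values():
        sigma = fwhm / _FWHM
        amp = (pct / 100.0) / (sigma * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-((wn - center) ** 2) / (2.0 * sigma**2))
    if amide_ii is not None:
        center, rel_area, fwhm = amide_ii
        sigma = fwhm / _FWHM
        y += rel_area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(
            -((wn - center) ** 2) / (2.0 * sigma**2)
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma * float(y.max()), y.shape)
    record = {name: vals for name, vals in truth.items()}
    return IRSpectrum(wavenumbers=wn, absorbance=y), record


@dataclass(frozen=True)
class ReleaseScenario:
    """Group structure of a release experiment: mean rate per (treatment, phase)."""

    means: dict = field(
        default_factory=lambda: {
            ("thermal", "gastric"): 55.0,
            ("thermal", "intestinal"): 45.0,
            ("nontreated", "gastric"): 65.0,
            ("nontreated", "intestinal"): 55.0,
            ("hph", "gastric"): 75.0,
            ("hph", "intestinal"): 65.0,
        }
    )
    sd: float = 2.0
    n_reps: int = 3
    a_total: float = 100.0
    seed: int = 0


def gen_release(sc: ReleaseScenario) -> tuple[pd.DataFrame, dict]:
    """Replicate release table (long format) plus the truth record.

    Columns: treatment, phase, replicate, a_total, a1_free.  Rates are drawn
    N(mean, sd) per replicate, clipped to [0, 100].
    """
    rng = np.random.default_rng(sc.seed)
    rows = []
    for (treatment, phase), mean in sc.means.items():
        rates = np.clip(rng.normal(mean, sc.sd, sc.n_reps), 0.0, 100.0)
        for rep, r in enumerate(rates):
            rows.append(
                {
                    "treatment": treatment,
                    "phase": phase,
                    "replicate": rep,
                    "a_total": sc.a_total,
                    "a1_free": r / 100.0 * sc.a_total,
                }
            )
    truth = {"means": dict(sc.means), "sd": sc.sd, "n_reps": sc.n_reps}
    return pd.DataFrame(rows), truth
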