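"""Van't Hoff thermodynamics of protein-ligand binding.

From temperature-resolved binding constants KA(T):

    dG = -R T ln KA           (kJ/mol, per temperature)
    dH = -R * slope           slope of ln KA vs 1/T  (kJ/mol, one per series)
    dS = (dH - dG) / T        (J mol^-1 K^-1, per temperature)

The (dH, dS) sign pattern classifies the dominant interaction forces by the
Ross-Subramanian rules: both negative -> hydrogen bonds + van der Waals;
both positive -> hydrophobic; dH negative or near zero with dS positive ->
electrostatic.  dG < 0 marks a spontaneous association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "R_GAS",
    "Force",
    "ThermoResult",
    "gibbs",
    "vant_hoff",
    "entropy",
    "classify_forces",
    "analyze_series",
]

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314


class Force(str, Enum):
    HBOND_VDW = "hbond_vdw"
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC = "electrostatic"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ThermoResult:
    temperatures: tuple[float, ...]  # K
    ka: tuple[float, ...]  # L/mol
    dh: float  # kJ/mol, one per series
    dg: tuple[float, ...]  # kJ/mol, per temperature
    ds: tuple[float, ...]  # J mol^-1 K^-1, per temperature
    forces: Force
    spontaneous: tuple[bool, ...]  # dG < 0 per temperature
    r2_vant_hoff: float


def gibbs(ka: float, t: float) -> float:
    """Standard free energy of binding, dG = -R T ln KA, in kJ/mol."""
    if ka <= 0:
        raise ValueError("binding constant must be positive")
    if t <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -R_GAS * t * math.log(ka) / 1000.0


def vant_hoff(pairs: list[tuple[float, float]]) -> tuple[float, dict]:
    """Enthalpy from the van't Hoff plot; returns (dH kJ/mol, diagnostics).

    Least squares of ln KA on 1/T; dH = -R * slope.  Diagnostics carry the
    slope, intercept, R^2 and the per-adjacent-pair two-point enthalpies
    (useful for spotting curvature, never used as the reported dH).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 (temperature, KA) pairs")
    t = np.array([p[0] for p in pairs], dtype=float)
    ka = np.array([p[1] for p in pairs], dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    if np.any(ka <= 0):
        raise ValueError("binding constants must be positive")
    if np.unique(t).size != t.size:
        raise ValueError("temperatures must be distinct")
    x = 1.0 / t
    y = np.log(ka)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    order = np.argsort(t)
    pairwise = [
        -R_GAS * (y[j] - y[i]) / (x[j] - x[i]) / 1000.0
        for i, j in zip(order[:-1], order[1:])
    ]
    dh = -R_GAS * float(slope) / 1000.0
    return dh, {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": r2,
        "pairwise_dh_kj_mol": pairwise,
    }


def entropy(dh: float, dg: float, t: float) -> float:
    """dS = (dH - dG) / T, J mol^-1 K^-1, with dH and dG in kJ/mol."""
    if t <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return (dh - dg) * 1000.0 / t


def classify_forces(dh: float, ds: float, dh_zero_band: float = 5.0) -> Force:
    """Ross-Subramanian sign rules for the dominant interaction forces.

    Mapping: dH<0, dS<0 -> hydrogen bonding + van der Waals; dH>0, dS>0 ->
    hydrophobic; dH<0 (or |dH| below dh_zero_band kJ/mol) with dS>0 ->
    electrostatic.  dH>0 with dS<0 has no assignment and returns
    ``unclassified`` rather than failing silently.
    """
    if not (np.isfinite(dh) and np.isfinite(ds)):
        raise ValueError("dH and dS must be finite")
    if ds > 0:
        if dh < 0 or abs(dh) < dh_zero_band:
            return Force.ELECTROSTATIC
        return Force.HYDROPHOBIC
    if ds < 0 and dh < 0:
        return Force.HBOND_VDW
    return Force.UNCLASSIFIED


def analyze_series(pairs: list[tuple[float, float]]) -> ThermoResult:
    """Full thermodynamic work-up of a (T, KA) series.

    One van't Hoff dH for the whole series; dG and dS per temperature; force
    classification from dH and the mean dS; spontaneity per temperature.
    """
    dh, diag = vant_hoff(pairs)
    ordered = sorted(pairs)
    t = tuple(p[0] for p in ordered)
    ka = tuple(p[1] for p in ordered)
    dg = tuple(gibbs(k, ti) for ti, k in zip(t, ka))
    ds = tuple(entropy(dh, g, ti) for ti, g in zip(t, dg))
    forces = classify_forces(dh, float(np.mean(ds)))
    return ThermoResult(
        temperatures=t,
        ka=ka,
        dh=dh,
        dg=dg,
        ds=ds,
        forces=forces,
        spontaneous=tuple(g < 0 for g in dg),
        r2_vant_hoff=diag["r2"],
    )
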