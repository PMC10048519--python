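"""Wet-chemistry quantitation: binding rate, free sulfhydryl content, release rate.

All three are simple ratios over HPLC or absorbance readings:

* binding rate   B(%)  = 100 (A - A0) / A      (A total, A0 free in supernatant)
* sulfhydryl     -SH   = 73.53 A412 D / C      (umol/g; D dilution, C in g/L)
* release rate   R(%)  = 100 A1 / A            (A1 free in digestive fluid)

Replicates are aggregated as mean +/- SD of per-replicate rates (rates of
replicates, not rates of replicate means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BindingMeasurement",
    "SulfhydrylMeasurement",
    "ReleaseMeasurement",
    "ELLMAN_FACTOR",
    "binding_rate",
    "sulfhydryl_content",
    "release_rate",
    "aggregate_replicates",
]

#: Ellman sulfhydryl factor: 1e6 / (extinction 13600 M^-1 cm^-1) with C in g/L.
ELLMAN_FACTOR = 73.53

_PHASES = ("gastric", "intestinal")


@dataclass(frozen=True)
class BindingMeasurement:
    a_total: float
    a_free: float
    group: dict = field(default_factory=dict)  # e.g. {"spi_pct": 1, "aa_mmol_l": 2.5}

    def __post_init__(self):
        if self.a_total < 0 or self.a_free < 0:
            raise ValueError("analyte amounts must be non-negative")


@dataclass(frozen=True)
class SulfhydrylMeasurement:
    a412: float  # absorbance at 412 nm
    dilution: float  # D, >= 1
    conc_g_per_l: float  # C, sample concentration in g/L

    def __post_init__(self):
        if self.a412 < 0:
            raise ValueError("absorbance must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.conc_g_per_l <= 0:
            raise ValueError("sample concentration must be positive")


@dataclass(frozen=True)
class ReleaseMeasurement:
    a1_free: float
    a_total: float
    phase: str  # "gastric" | "intestinal"
    group: dict = field(default_factory=dict)
    replicate: int = 0

    def __post_init__(self):
        if self.a1_free < 0 or self.a_total < 0:
            raise ValueError("analyte amounts must be non-negative")
        if self.phase not in _PHASES:
            raise ValueError(f"phase must be one of {_PHASES}")


def binding_rate(m: BindingMeasurement) -> float:
    """Bound fraction in percent; small negatives clamp to 0 with a warning.

    Triplicate HPLC noise routinely pushes the free amount a hair above the
    total; clamping keeps batch processing alive while still flagging it.
    """
    if m.a_total == 0:
        raise ValueError("total analyte amount must be positive")
    if m.a_free > m.a_total:
        warnings.warn(
            f"free amount {m.a_free} exceeds total {m.a_total}; binding rate "
            "clamped to 0 (measurement noise)",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * (m.a_total - m.a_free) / m.a_total


def sulfhydryl_content(m: SulfhydrylMeasurement) -> float:
    """Free -SH content in umol per g protein (Ellman assay, 412 nm)."""
    return ELLMAN_FACTOR * m.a412 * m.dilution / m.conc_g_per_l


def release_rate(m: ReleaseMeasurement) -> float:
    """Released fraction in percent; values above 100 are flagged, not clipped."""
    if m.a_total == 0:
        raise ValueError("total analyte amount must be positive")
    r = 100.0 * m.a1_free / m.a_total
    if r > 100.0:
        warnings.warn(
            f"release rate {r:.2f}% exceeds 100%; free amount larger than total",
            stacklevel=2,
        )
    return r


def aggregate_replicates(
    df: pd.DataFrame, value: str, by: list[str]
) -> pd.DataFrame:
    """Mean +/- SD (ddof=1) of per-replicate values within each group."""
    g = df.groupby(by, sort=False)[value]
    out = g.agg(mean="mean", sd=lambda x: np.std(x, ddof=1) if len(x) > 1 else 0.0,
                n="count").reset_index()
    return out
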