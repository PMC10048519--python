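"""CSV readers and writers for the package's tabular dialects.

* Emission spectrum: columns ``wavelength_nm, intensity`` with metadata in
  ``#``-prefixed header comments (``# temperature_K=297``, ``# quencher_M=2e-5``).
* Titration curve: columns ``q_mol_per_L, intensity`` (same header comments
  for temperature; the [Q]=0 row supplies F0).
* IR spectrum: columns ``wavenumber_cm1, absorbance``.
* Measurements: long tables with group/treatment/phase/replicate columns.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .ftir import IRSpectrum
from .quenching import EmissionSpectrum, TitrationCurve

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_ir_csv",
    "write_ir_csv",
]


def _read_with_comments(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    lines = Path(path).read_text().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            text = line.lstrip("#").strip()
            if "=" in text:
                key, val = text.split("=", 1)
                meta[key.strip()] = val.strip()
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)))
    return df, meta


def read_spectrum_csv(path) -> EmissionSpectrum:
    df, meta = _read_with_comments(path)
    return EmissionSpectrum(
        temperature=float(meta.get("temperature_K", "nan")),
        quencher_conc=float(meta.get("quencher_M", "nan")),
        wavelengths=df["wavelength_nm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
    )


def write_spectrum_csv(path, s: EmissionSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={s.temperature:g}\n")
        fh.write(f"# quencher_M={s.quencher_conc:g}\n")
        pd.DataFrame(
            {"wavelength_nm": s.wavelengths, "intensity": s.intensities}
        ).to_csv(fh, index=False)


def read_titration_csv(path) -> TitrationCurve:
    df, meta = _read_with_comments(path)
    q = df["q_mol_per_L"].to_numpy(float)
    f = df["intensity"].to_numpy(float)
    order = np.argsort(q)
    return TitrationCurve.from_points(
        temperature=float(meta.get("temperature_K", "nan")), q=q[order], f=f[order]
    )


def write_titration_csv(path, curve: TitrationCurve) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={curve.temperature:g}\n")
        pd.DataFrame({"q_mol_per_L": curve.q, "intensity": curve.f}).to_csv(
            fh, index=False
        )


def read_ir_csv(path) -> IRSpectrum:
    df, _ = _read_with_comments(path)
    return IRSpectrum(
        wavenumbers=df["wavenumber_cm1"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
    )


def write_ir_csv(path, s: IRSpectrum) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": s.wavenumbers, "absorbance": s.absorbance}
    ).to_csv(path, index=False)
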