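"""Two-wavelength hemoglobin inversion and chromophore-contamination errors.

With hemoglobin assumed to be the only absorber, the Beer law links the
absorption coefficients at the two wavelengths to the oxy- and deoxy-
hemoglobin concentrations through the 2x2 linear system

    mua(lambda) = ln(10) * [ eps_HbO2(lambda) * [HbO2] + eps_HHb(lambda) * [HHb] ]

with molar extinction coefficients eps in 1/(cm M) and concentrations in
micromolar.  Total hemoglobin and saturation follow as tHb = HbO2 + HHb and
SO2 = 100 * HbO2 / tHb.

The default extinction table is compiled from the standard hemoglobin
compilation (Prahl/OMLC scale) interpolated to 686 and 830 nm, together with
pure-water and lipid absorption spectra used only by the contamination-error
analysis; all entries are swappable via a CSV file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

LN10 = math.log(10.0)

HEMOGLOBIN_CHROMOPHORES = ("HbO2", "HHb")
BACKGROUND_CHROMOPHORES = ("water", "lipid")


class ExtinctionError(ValueError):
    """The extinction table cannot support the requested inversion."""


@dataclass(frozen=True)
class HemodynamicState:
    """Hemoglobin concentrations (uM) and derived oxygenation.

    ``so2_pct`` is None when tHb is zero (saturation undefined); negative
    concentrations are preserved and flagged via ``physical`` rather than
    clipped, because they signal model misfit.
    """

    hbo2: float  # uM
    hhb: float  # uM
    thb: float  # uM
    so2_pct: float | None  # %

    @property
    def physical(self) -> bool:
        return self.hbo2 >= 0 and self.hhb >= 0


def derive_oxygenation(hbo2: float, hhb: float) -> HemodynamicState:
    """tHb = HbO2 + HHb; SO2 = 100 * HbO2/tHb (undefined sentinel at tHb = 0)."""
    if not (np.isfinite(hbo2) and np.isfinite(hhb)):
        raise ValueError("concentrations must be finite")
    thb = hbo2 + hhb
    so2 = None if thb == 0 else 100.0 * hbo2 / thb
    return HemodynamicState(hbo2=hbo2, hhb=hhb, thb=thb, so2_pct=so2)


@dataclass(frozen=True)
class ExtinctionTable:
    """Chromophore absorption data at the instrument wavelengths.

    ``hemoglobin`` maps (chromophore, wavelength) to the molar extinction
    coefficient in 1/(cm M); ``background`` maps (chromophore, wavelength) to
    the absorption coefficient of the pure substance in 1/cm.
    """

    hemoglobin: dict[tuple[str, float], float]
    background: dict[tuple[str, float], float]
    source: str

    def __post_init__(self) -> None:
        for table in (self.hemoglobin, self.background):
            if any(v <= 0 for v in table.values()):
                raise ExtinctionError("all extinction entries must be positive")

    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted({w for _, w in self.hemoglobin}))

    def specific_absorption(self, chromophore: str, wavelength: float) -> float:
        """Hemoglobin absorption per unit concentration, 1/(cm uM)."""
        try:
            eps = self.hemoglobin[(chromophore, wavelength)]
        except KeyError as exc:
            raise ExtinctionError(
                f"no extinction entry for {chromophore} at {wavelength} nm"
            ) from exc
        return LN10 * eps * 1e-6

    def background_mua(self, chromophore: str, wavelength: float) -> float:
        """Absorption coefficient of the pure background substance, 1/cm."""
        try:
            return self.background[(chromophore, wavelength)]
        except KeyError as exc:
            raise ExtinctionError(
                f"no background absorption for {chromophore} at {wavelength} nm"
            ) from exc

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 specific-absorption matrix, rows = wavelengths, cols = (HbO2, HHb)."""
        return np.array(
            [
                [self.specific_absorption(c, w) for c in HEMOGLOBIN_CHROMOPHORES]
                for w in wavelengths
            ]
        )


#: Default extinction table.  Hemoglobin: molar extinction (1/(cm M)) from the
#: standard compiled spectra, interpolated to the laser wavelengths; water:
#: pure-water absorption (1/cm); lipid: soybean-oil scale absorption (1/cm).
DEFAULT_EXTINCTION = ExtinctionTable(
    hemoglobin={
        ("HbO2", 686.0): 290.0,
        ("HHb", 686.0): 2150.0,
        ("HbO2", 830.0): 974.0,
        ("HHb", 830.0): 693.0,
    },
    background={
        ("water", 686.0): 0.00465,
        ("water", 830.0): 0.0298,
        ("lipid", 686.0): 0.0006,
        ("lipid", 830.0): 0.005,
    },
    source=(
        "hemoglobin: compiled molar extinction spectra (Prahl/OMLC scale), "
        "interpolated to 686/830 nm; water: Hale & Querry pure-water "
        "absorption; lipid: van Veen soybean-oil absorption"
    ),
)

_EXTINCTION_COLUMNS = ["chromophore", "wavelength_nm", "value", "units", "source"]


def write_extinction_table(ext: ExtinctionTable, path: str | Path) -> None:
    rows = []
    for (chrom, w), eps in sorted(ext.hemoglobin.items()):
        rows.append((chrom, w, eps, "1/(cm M)", ext.source))
    for (chrom, w), mua in sorted(ext.background.items()):
        rows.append((chrom, w, mua, "1/cm", ext.source))
    pd.DataFrame(rows, columns=_EXTINCTION_COLUMNS).to_csv(path, index=False)


def load_extinction_table(path: str | Path) -> ExtinctionTable:
    df = pd.read_csv(path)
    missing = [c for c in _EXTINCTION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ExtinctionError(f"{path}: missing columns {missing}")
    hemoglobin: dict[tuple[str, float], float] = {}
    background: dict[tuple[str, float], float] = {}
    for _, row in df.iterrows():
        key = (str(row["chromophore"]), float(row["wavelength_nm"]))
        if key[0] in HEMOGLOBIN_CHROMOPHORES:
            hemoglobin[key] = float(row["value"])
        elif key[0] in BACKGROUND_CHROMOPHORES:
            background[key] = float(row["value"])
        else:
            raise ExtinctionError(f"{path}: unknown chromophore {key[0]!r}")
    source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else ""
    return ExtinctionTable(hemoglobin=hemoglobin, background=background, source=source)


def forward_beer(
    hbo2: float,
    hhb: float,
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
    wavelengths: tuple[float, float] = (686.0, 830.0),
) -> tuple[float, float]:
    """Absorption coefficients (1/cm) at the two wavelengths for given
    concentrations (uM); the forward counterpart of :func:`invert_beer`."""
    E = ext.matrix(wavelengths)
    mua = E @ np.array([hbo2, hhb])
    return float(mua[0]), float(mua[1])


def invert_beer(
    mua_686: float,
    mua_830: float,
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
    wavelengths: tuple[float, float] = (686.0, 830.0),
) -> HemodynamicState:
    """Solve the 2x2 Beer-law system for (HbO2, HHb) in uM.

    Negative solutions are returned (flagged via ``HemodynamicState.physical``),
    never clipped.
    """
    if mua_686 < 0 or mua_830 < 0:
        raise ValueError("absorption coefficients must be nonnegative")
    E = ext.matrix(wavelengths)
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > 1e12:
        raise ExtinctionError(
            f"extinction matrix is singular or ill-conditioned (cond = {cond:.3g})"
        )
    hbo2, hhb = np.linalg.solve(E, np.array([mua_686, mua_830]))
    return derive_oxygenation(float(hbo2), float(hhb))


def contamination_error(
    mua_686: float,
    mua_830: float,
    chromophore: str,
    volume_fraction: float,
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
    wavelengths: tuple[float, float] = (686.0, 830.0),
) -> dict[str, float]:
    """Relative error (%) of the hemoglobin-only inversion when a background
    chromophore contributes to the measured absorption.

    The corrected inversion subtracts ``volume_fraction`` times the pure
    chromophore's absorption from each mua before inverting.  Reported value
    is 100 * (uncorrected - corrected) / corrected for each of HHb, HbO2,
    tHb, SO2: a positive number means the hemoglobin-only assumption
    overestimates that quantity.
    """
    if not 0 <= volume_fraction <= 1:
        raise ValueError("volume_fraction must lie in [0, 1]")
    if chromophore not in BACKGROUND_CHROMOPHORES:
        raise ValueError(f"chromophore must be one of {BACKGROUND_CHROMOPHORES}")
    corrected_mua = []
    for mua, w in zip((mua_686, mua_830), wavelengths):
        mua_c = mua - volume_fraction * ext.background_mua(chromophore, w)
        if mua_c < 0:
            raise ValueError(
                f"contamination exceeds measured absorption at {w} nm "
                f"(corrected mua = {mua_c:.4g} 1/cm)"
            )
        corrected_mua.append(mua_c)
    uncorrected = invert_beer(mua_686, mua_830, ext, wavelengths)
    corrected = invert_beer(*corrected_mua, ext, wavelengths)

    def rel(u: float | None, c: float | None) -> float:
        if u is None or c is None or c == 0:
            return float("nan")
        return 100.0 * (u - c) / c

    return {
        "HHb": rel(uncorrected.hhb, corrected.hhb),
        "HbO2": rel(uncorrected.hbo2, corrected.hbo2),
        "tHb": rel(uncorrected.thb, corrected.thb),
        "SO2": rel(uncorrected.so2_pct, corrected.so2_pct),
    }
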