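"""Domain types and file formats shared by all pipeline stages.

The raw measurement unit is the DTOF (distribution of time-of-flight): a
histogram of photon arrival delays on a fixed-width time grid (one TDC channel
per bin).  A time axis is defined by ``t_offset + k * channel_width`` for
channel ``k``, both in picoseconds.  DTOF and IRF files use a transparent
two-part text format: a ``key: value`` header followed by one count per line.
Cohorts are plain CSV, one subject per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: CODATA speed of light in vacuum, cm/s.
SPEED_OF_LIGHT_CM_S = 2.99792458e10

#: Age range (years) covered by the reference pediatric cohort.  Ages outside
#: this range are warned about but never rejected: the range is a property of
#: the cohort, not of the physical model.
COHORT_AGE_RANGE = (2.0, 18.0)


class FormatError(ValueError):
    """A file violates the documented on-disk format."""


class SchemaError(ValueError):
    """A tabular file is missing or mistypes a mandatory column."""


class CohortRangeWarning(UserWarning):
    """A subject variable lies outside the reference-cohort range."""


# ---------------------------------------------------------------------------
# instrument
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentConfig:
    """Static description of the TD-NIRS instrument.

    Defaults mirror a two-wavelength (686/830 nm) tissue oximeter with a
    2.5 cm source-detector separation and a 9.7 ps/channel time-to-digital
    converter; the tissue refractive index is taken constant at 1.4.
    """

    wavelengths: tuple[float, ...] = (686.0, 830.0)
    rho: float = 2.5  # cm
    channel_width: float = 9.7  # ps
    n_channels: int = 4096
    refractive_index: float = 1.4
    speed_of_light_vacuum: float = SPEED_OF_LIGHT_CM_S  # cm/s

    def __post_init__(self) -> None:
        if not self.wavelengths or any(w <= 0 for w in self.wavelengths):
            raise ValueError("wavelengths must be nonempty and positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")

    @property
    def v_tissue_cm_ps(self) -> float:
        """Speed of light in tissue, cm/ps (v = c/n)."""
        return self.speed_of_light_vacuum / self.refractive_index * 1e-12

    @property
    def time_span_ps(self) -> float:
        return self.n_channels * self.channel_width


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------


@dataclass
class DTOFHistogram:
    """Photon counts per fixed-width time channel.

    ``counts[k]`` is the number of photons detected in the channel whose
    nominal time is ``t_offset + k * channel_width`` (ps).
    """

    counts: np.ndarray
    channel_width: float  # ps
    t_offset: float = 0.0  # ps
    wavelength: float | None = None  # nm
    acquisition_time: float = 1.0  # s

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Channel time axis in ps."""
        return self.t_offset + np.arange(self.n_channels) * self.channel_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def mean_time(self) -> float:
        """Count-weighted mean arrival time (ps). Requires positive total."""
        total = self.total_counts
        if total <= 0:
            raise ValueError("mean time undefined for an empty histogram")
        return float(np.dot(self.counts, self.times) / total)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DTOFHistogram):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.channel_width == other.channel_width
            and self.t_offset == other.t_offset
            and self.wavelength == other.wavelength
            and self.acquisition_time == other.acquisition_time
        )


@dataclass(eq=False)
class InstrumentResponse(DTOFHistogram):
    """The instrument response function: the DTOF recorded with source
    coupled (almost) directly to the detector.  Must be nonempty."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.counts.sum() <= 0:
            raise ValueError("IRF must have positive total counts")

    @property
    def barycenter(self) -> float:
        """First moment of the IRF (ps); the temporal origin it imprints on
        every convolved measurement."""
        return self.mean_time()


# ---------------------------------------------------------------------------
# results of the physical analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering coefficients at one wavelength."""

    mua: float  # 1/cm
    musp: float  # 1/cm

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError("mua must be nonnegative")
        if self.musp <= 0:
            raise ValueError("musp must be positive")


@dataclass(frozen=True)
class DPFResult:
    """Differential pathlength factor and the mean time it came from."""

    dpf: float
    mean_time: float  # ps

    def __post_init__(self) -> None:
        if self.mean_time > 0 and self.dpf <= 0:
            raise ValueError("dpf must be positive when mean_time > 0")


@dataclass(frozen=True)
class FitReport:
    """Diagnostics of a single-DTOF model fit."""

    estimate: OpticalProperties
    fit_window: tuple[int, int]  # inclusive channel range
    reduced_residual: float
    converged: bool
    iterations: int
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.fit_window
        if lo < 0 or hi < lo:
            raise ValueError("fit_window must be a nonempty channel range")
        if self.reduced_residual < 0:
            raise ValueError("reduced_residual must be nonnegative")


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

GENDER_CODES = ("F", "M")

#: CSV column -> (attribute, required).  Optical/hemodynamic ground-truth
#: columns are optional: they are present for synthetic cohorts and absent for
#: purely demographic tables.
_COHORT_COLUMNS: dict[str, tuple[str, bool]] = {
    "subject_id": ("subject_id", True),
    "gender": ("gender", True),
    "age_years": ("age_years", True),
    "bmi": ("bmi", True),
    "bmi_z": ("bmi_z", True),
    "head_circ_cm": ("head_circ_cm", True),
    "htc_pct": ("htc_pct", True),
    "hb_gdl": ("hb_gdl", True),
    "hr_bpm": ("hr_bpm", True),
    "br_bpm": ("br_bpm", True),
    "spo2_pct": ("spo2_pct", True),
    "hbo2_um": ("hbo2_um", False),
    "hhb_um": ("hhb_um", False),
    "thb_um": ("thb_um", False),
    "so2_pct": ("so2_pct", False),
    "mua_686": ("mua_686", False),
    "mua_830": ("mua_830", False),
    "musp_686": ("musp_686", False),
    "musp_830": ("musp_830", False),
    "dpf_686": ("dpf_686", False),
    "dpf_830": ("dpf_830", False),
    "compliant": ("compliant", False),
}


@dataclass
class SubjectRecord:
    """Demographics, auxology, physiology and (optionally) the subject's
    ground-truth optical/hemodynamic state used to synthesize DTOFs."""

    subject_id: str
    gender: str
    age_years: float
    bmi: float
    bmi_z: float
    head_circ_cm: float
    htc_pct: float
    hb_gdl: float
    hr_bpm: float
    br_bpm: float
    spo2_pct: float
    hbo2_um: float | None = None
    hhb_um: float | None = None
    thb_um: float | None = None
    so2_pct: float | None = None
    mua_686: float | None = None
    mua_830: float | None = None
    musp_686: float | None = None
    musp_830: float | None = None
    dpf_686: float | None = None
    dpf_830: float | None = None
    compliant: bool = True

    def __post_init__(self) -> None:
        if self.gender not in GENDER_CODES:
            raise SchemaError(f"gender must be one of {GENDER_CODES}, got {self.gender!r}")
        lo, hi = COHORT_AGE_RANGE
        if not np.isfinite(self.age_years):
            raise SchemaError("age_years must be a finite number")
        if not lo <= self.age_years <= hi:
            warnings.warn(
                f"subject {self.subject_id}: age {self.age_years} outside the "
                f"reference range {lo}-{hi} y; record retained",
                CohortRangeWarning,
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# DTOF file format
# ---------------------------------------------------------------------------

_HEADER_FIELDS = {
    "channel_width_ps": ("channel_width", float),
    "t_offset_ps": ("t_offset", float),
    "wavelength_nm": ("wavelength", float),
    "acquisition_time_s": ("acquisition_time", float),
}


def write_dtof(h: DTOFHistogram, path: str | Path) -> None:
    """Write a histogram in the two-part text format (header + counts)."""
    path = Path(path)
    lines = [
        "# pedinirs dtof v1",
        f"channel_width_ps: {h.channel_width!r}",
        f"t_offset_ps: {h.t_offset!r}",
        f"wavelength_nm: {'' if h.wavelength is None else repr(h.wavelength)}",
        f"acquisition_time_s: {h.acquisition_time!r}",
        "counts:",
    ]
    lines.extend(str(int(c)) for c in h.counts)
    path.write_text("\n".join(lines) + "\n")


def read_dtof(path: str | Path) -> DTOFHistogram:
    """Read a histogram written by :func:`write_dtof`.  Lossless."""
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("# pedinirs dtof"):
        raise FormatError(f"{path}: missing dtof header line")
    meta: dict[str, object] = {}
    counts: list[int] = []
    in_counts = False
    for lineno, line in enumerate(text[1:], start=2):
        line = line.strip()
        if not line:
            continue
        if in_counts:
            try:
                value = int(line)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count {line!r}") from exc
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative count {value}")
            counts.append(value)
            continue
        if line == "counts:":
            in_counts = True
            continue
        key, _, raw = line.partition(":")
        key = key.strip()
        raw = raw.strip()
        if key not in _HEADER_FIELDS:
            raise FormatError(f"{path}:{lineno}: unknown header field {key!r}")
        attr, conv = _HEADER_FIELDS[key]
        if raw == "":
            meta[attr] = None
        else:
            try:
                meta[attr] = conv(raw)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad value for {key}: {raw!r}") from exc
    missing = {a for a, _ in _HEADER_FIELDS.values()} - set(meta)
    if missing:
        raise FormatError(f"{path}: missing header fields {sorted(missing)}")
    cw = meta.pop("channel_width")
    if cw is None or cw <= 0:
        raise FormatError(f"{path}: channel_width_ps must be positive")
    return DTOFHistogram(counts=np.asarray(counts, dtype=np.int64), channel_width=cw, **meta)  # type: ignore[arg-type]


def read_irf(path: str | Path) -> InstrumentResponse:
    h = read_dtof(path)
    return InstrumentResponse(
        counts=h.counts,
        channel_width=h.channel_width,
        t_offset=h.t_offset,
        wavelength=h.wavelength,
        acquisition_time=h.acquisition_time,
    )


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {col: getattr(r, attr) for col, (attr, _) in _COHORT_COLUMNS.items()}
        rows.append(row)
    pd.DataFrame(rows, columns=list(_COHORT_COLUMNS)).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV; one validated :class:`SubjectRecord` per row."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file (no header)") from exc
    required = [c for c, (_, req) in _COHORT_COLUMNS.items() if req]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    numeric = [c for c in required if c not in ("subject_id", "gender")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            raise SchemaError(f"{path}: non-numeric value in column {col!r}")
        df[col] = coerced
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, (attr, req) in _COHORT_COLUMNS.items():
            if col not in df.columns:
                continue
            value = row[col]
            if attr == "compliant":
                value = bool(value) if pd.notna(value) else True
            elif not req and pd.isna(value):
                value = None
            kwargs[attr] = value
        kwargs["subject_id"] = str(kwargs["subject_id"])
        records.append(SubjectRecord(**kwargs))
    return records


def cohort_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (one row per subject)."""
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in fields(SubjectRecord)} for r in records]
    )
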