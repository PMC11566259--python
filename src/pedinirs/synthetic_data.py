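"""Synthetic stand-in for the clinical cohort and its measurement protocol.

Generates subject cohorts whose per-(age-cluster, gender) cell counts, means
and SDs reproduce the reference pediatric tables (auxology, physiology,
optical and hemodynamic variables), plus instrument response functions and
per-protocol DTOF sets (5 probe repositionings x 5 acquisitions at 1 Hz per
subject and wavelength) with configurable repositioning variability.

Internal consistency: the generator draws (tHb, SO2) per subject, derives
HbO2/HHb from them, and computes the absorption coefficients through the
forward Beer law, so the optical and
hemodynamic variables of one subject can never contradict each other.  The
reduced scattering coefficients are drawn from their reference cells.  The
DPF columns are drawn directly as reported descriptors: the reference tables'
DPF values are systematically lower (by roughly a factor 1/n) than the
semi-infinite diffusion model predicts at the tabulated (mua, musp), so they
cannot be derived from the drawn optical properties without breaking either
the tables or the physics (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_io import (
    DTOFHistogram,
    InstrumentConfig,
    InstrumentResponse,
    OpticalProperties,
    SubjectRecord,
)
from .forward_model import (
    MediumGeometry,
    ModelCurve,
    convolve_irf,
    simulate_dtof,
    tr_reflectance,
)
from .hemodynamics import DEFAULT_EXTINCTION, ExtinctionTable, forward_beer

CLUSTER_LABELS = (
    "2 to 4", "4 to 6", "6 to 8", "8 to 10",
    "10 to 12", "12 to 14", "14 to 16", "16 to 18",
)
GENDERS = ("F", "M")

#: Subjects per (cluster, gender) in the reference cohort (totals 157 F, 148 M).
REFERENCE_COUNTS: dict[tuple[str, str], int] = {}
for _label, _f, _m in zip(
    CLUSTER_LABELS,
    (20, 21, 25, 17, 17, 22, 22, 13),
    (23, 16, 18, 19, 21, 27, 14, 10),
):
    REFERENCE_COUNTS[(_label, "F")] = _f
    REFERENCE_COUNTS[(_label, "M")] = _m

# Per-cell (mean, sd) of every tabulated variable; rows follow CLUSTER_LABELS,
# each entry is (F_mean, F_sd, M_mean, M_sd).
_CELL_ROWS: dict[str, list[tuple[float, float, float, float]]] = {
    "bmi": [
        (15.0, 1.5, 15.4, 1.5), (14.8, 1.7, 15.2, 1.8), (16.7, 3.5, 17.4, 6.0),
        (19.6, 5.3, 17.8, 3.5), (19.6, 5.4, 18.7, 3.3), (22.6, 7.4, 23.9, 7.1),
        (22.4, 6.7, 23.3, 4.8), (23.1, 4.8, 24.0, 6.4),
    ],
    "bmi_z": [
        (-0.3, 1.0, -0.1, 1.2), (-0.3, 1.0, -0.1, 1.3), (0.7, 1.9, 1.1, 3.6),
        (1.5, 2.3, 0.9, 1.9), (0.9, 2.0, 0.8, 1.5), (1.4, 2.5, 2.3, 2.8),
        (0.6, 2.0, 1.2, 1.5), (0.6, 1.4, 0.9, 2.0),
    ],
    "head_circ_cm": [
        (48.9, 1.6, 50.4, 1.5), (50.8, 1.6, 52.1, 1.3), (52.2, 2.1, 52.2, 1.8),
        (52.8, 2.3, 53.1, 1.4), (53.5, 2.0, 54.2, 1.8), (54.7, 2.0, 55.3, 1.8),
        (54.9, 2.2, 55.7, 2.9), (55.9, 1.4, 56.9, 2.8),
    ],
    "htc_pct": [
        (34.3, 2.7, 35.4, 3.5), (34.3, 2.0, 36.5, 3.7), (36.4, 3.9, 37.8, 4.3),
        (36.1, 3.3, 36.4, 2.3), (38.5, 2.8, 37.5, 3.4), (38.5, 3.6, 39.3, 3.1),
        (37.3, 4.1, 39.8, 2.6), (36.4, 3.7, 41.9, 3.2),
    ],
    "hb_gdl": [
        (11.6, 0.8, 12.1, 1.2), (11.8, 0.8, 12.9, 1.3), (12.3, 1.4, 12.9, 1.7),
        (12.5, 1.1, 12.8, 1.0), (13.3, 1.0, 13.0, 1.3), (13.2, 1.3, 13.4, 1.2),
        (12.6, 1.5, 13.9, 0.7), (12.5, 1.4, 14.1, 0.9),
    ],
    "hr_bpm": [
        (112.0, 12.3, 104.7, 15.7), (103.4, 10.3, 98.8, 14.0),
        (88.4, 12.3, 95.2, 16.9), (93.6, 17.7, 87.9, 10.6),
        (85.9, 13.8, 88.4, 8.7), (83.4, 7.4, 87.4, 15.0),
        (78.6, 12.3, 84.1, 15.6), (83.5, 13.6, 78.1, 9.5),
    ],
    "br_bpm": [
        (25.8, 3.6, 24.8, 3.2), (23.0, 2.3, 23.7, 3.4), (23.0, 3.2, 23.3, 4.2),
        (24.2, 5.0, 21.5, 2.7), (21.8, 3.5, 22.2, 2.9), (20.0, 2.0, 21.7, 3.7),
        (20.2, 2.1, 19.9, 2.3), (20.8, 6.0, 19.8, 2.4),
    ],
    "spo2_pct": [
        (98.8, 1.3, 98.5, 1.3), (98.7, 1.2, 98.6, 0.8), (98.5, 1.3, 98.1, 1.0),
        (98.8, 1.0, 98.3, 1.3), (98.4, 0.9, 98.2, 0.9), (99.0, 1.1, 98.6, 1.0),
        (99.2, 0.8, 98.4, 1.3), (98.5, 1.2, 97.9, 0.7),
    ],
    "mua_686": [
        (0.22, 0.03, 0.24, 0.03), (0.24, 0.03, 0.25, 0.03), (0.23, 0.04, 0.24, 0.04),
        (0.23, 0.03, 0.22, 0.03), (0.22, 0.06, 0.22, 0.04), (0.20, 0.04, 0.23, 0.05),
        (0.18, 0.03, 0.23, 0.06), (0.16, 0.04, 0.20, 0.06),
    ],
    "mua_830": [
        (0.21, 0.02, 0.23, 0.02), (0.22, 0.03, 0.24, 0.03), (0.21, 0.03, 0.23, 0.04),
        (0.22, 0.03, 0.21, 0.02), (0.22, 0.05, 0.22, 0.03), (0.21, 0.04, 0.24, 0.05),
        (0.18, 0.03, 0.25, 0.07), (0.17, 0.03, 0.21, 0.05),
    ],
    "musp_686": [
        (13.2, 1.4, 14.0, 1.4), (13.7, 1.0, 14.0, 1.0), (13.5, 1.3, 13.7, 1.1),
        (13.7, 0.9, 13.5, 1.3), (13.6, 1.1, 14.0, 1.0), (13.7, 1.2, 14.2, 1.4),
        (14.0, 1.4, 14.4, 1.6), (13.5, 1.0, 13.9, 2.5),
    ],
    "musp_830": [
        (11.3, 1.2, 11.9, 1.0), (11.7, 0.7, 12.1, 0.8), (11.6, 1.0, 11.9, 0.9),
        (11.8, 0.8, 11.7, 1.0), (11.9, 0.8, 12.0, 0.9), (11.9, 0.9, 12.3, 1.2),
        (12.0, 1.2, 12.2, 1.3), (11.9, 0.8, 11.8, 1.6),
    ],
    "dpf_686": [
        (4.3, 1.3, 4.2, 0.4), (4.2, 0.4, 4.2, 0.4), (4.3, 0.3, 4.2, 0.5),
        (4.3, 0.4, 4.3, 0.5), (4.4, 0.6, 4.6, 0.8), (4.7, 0.6, 4.5, 0.6),
        (5.1, 0.7, 4.6, 0.8), (5.2, 0.6, 4.9, 1.1),
    ],
    "dpf_830": [
        (4.0, 0.4, 3.9, 0.3), (4.0, 0.3, 3.9, 0.4), (4.0, 0.4, 4.0, 0.5),
        (3.9, 0.3, 4.0, 0.4), (4.1, 0.7, 4.0, 0.4), (4.2, 0.4, 4.0, 0.5),
        (4.6, 0.6, 3.8, 0.6), (4.8, 0.4, 4.1, 0.7),
    ],
    "hbo2_um": [
        (65.9, 8.2, 72.6, 8.0), (69.4, 8.7, 77.3, 9.7), (69.5, 11.8, 74.4, 12.2),
        (72.3, 8.5, 70.4, 8.7), (74.0, 14.3, 73.9, 12.1), (70.1, 12.0, 80.1, 15.4),
        (61.7, 11.6, 86.0, 24.1), (55.9, 9.4, 73.5, 15.6),
    ],
    "hhb_um": [
        (36.3, 5.5, 39.3, 5.0), (38.5, 6.0, 39.2, 5.4), (36.4, 6.3, 37.5, 7.9),
        (36.5, 5.7, 35.1, 5.5), (34.7, 10.4, 33.8, 7.0), (30.2, 6.2, 35.7, 9.3),
        (27.5, 5.8, 34.0, 10.8), (25.4, 6.5, 30.2, 11.2),
    ],
    "thb_um": [
        (102.2, 10.9, 111.8, 10.9), (107.9, 13.3, 116.6, 13.5),
        (105.9, 16.8, 112.0, 17.9), (108.8, 12.9, 105.4, 11.0),
        (108.8, 23.9, 107.7, 16.3), (100.3, 17.2, 115.8, 22.7),
        (89.2, 16.0, 120.0, 31.7), (81.3, 15.0, 103.7, 24.1),
    ],
    "so2_pct": [
        (64.5, 3.9, 64.9, 3.1), (64.3, 2.8, 66.3, 2.8), (65.5, 3.1, 66.6, 3.6),
        (66.5, 3.0, 66.7, 4.3), (68.5, 3.4, 68.7, 4.5), (70.0, 3.1, 69.3, 3.9),
        (69.2, 3.9, 71.8, 6.0), (69.0, 3.6, 71.5, 5.9),
    ],
}

REFERENCE_CELLS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    var: {
        (label, g): (row[0], row[1]) if g == "F" else (row[2], row[3])
        for label, row in zip(CLUSTER_LABELS, rows)
        for g in GENDERS
    }
    for var, rows in _CELL_ROWS.items()
}

#: Total rows of the reference tables (mean, sd) per gender.
REFERENCE_TOTALS: dict[str, dict[str, tuple[float, float]]] = {
    "bmi": {"F": (19.0, 5.9), "M": (19.3, 5.8)},
    "bmi_z": {"F": (0.6, 1.9), "M": (0.9, 2.3)},
    "head_circ_cm": {"F": (52.8, 2.9), "M": (53.5, 2.7)},
    "htc_pct": {"F": (36.5, 3.7), "M": (37.8, 3.8)},
    "hb_gdl": {"F": (12.5, 1.3), "M": (13.0, 1.3)},
    "hr_bpm": {"F": (91.2, 16.5), "M": (91.6, 15.8)},
    "br_bpm": {"F": (22.4, 4.0), "M": (22.3, 3.6)},
    "spo2_pct": {"F": (98.7, 1.1), "M": (98.4, 1.1)},
    "mua_686": {"F": (0.21, 0.05), "M": (0.23, 0.05)},
    "mua_830": {"F": (0.21, 0.04), "M": (0.23, 0.04)},
    "musp_686": {"F": (13.6, 1.2), "M": (14.0, 1.4)},
    "musp_830": {"F": (11.7, 1.0), "M": (12.0, 1.1)},
    "dpf_686": {"F": (4.6, 0.8), "M": (4.4, 0.7)},
    "dpf_830": {"F": (4.2, 0.5), "M": (4.0, 0.5)},
    "hbo2_um": {"F": (67.7, 11.9), "M": (75.9, 14.2)},
    "hhb_um": {"F": (33.5, 7.9), "M": (36.0, 8.2)},
    "thb_um": {"F": (101.2, 18.3), "M": (111.9, 19.5)},
    "so2_pct": {"F": (67.1, 4.0), "M": (67.9, 4.8)},
}

#: Variables the generator draws from their cells (the rest are derived).
#: Hemodynamics are parametrized by (tHb, SO2): propagating their reference
#: SDs through HbO2 = SO2*tHb and HHb = (1-SO2)*tHb reproduces the tabulated
#: HbO2/HHb dispersions almost exactly, whereas independent HbO2/HHb draws
#: would inflate the derived SO2 spread well beyond its reference cells.
DRAWN_VARIABLES = (
    "bmi", "bmi_z", "head_circ_cm", "htc_pct", "hb_gdl", "hr_bpm", "br_bpm",
    "spo2_pct", "thb_um", "so2_pct", "musp_686", "musp_830",
    "dpf_686", "dpf_830",
)
DERIVED_VARIABLES = ("mua_686", "mua_830", "hbo2_um", "hhb_um")

#: Truncation bounds per variable (None = unbounded).  Lower bounds keep
#: physically positive quantities positive; SpO2 cannot exceed 100%.
VARIABLE_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "bmi": (5.0, None), "bmi_z": (None, None), "head_circ_cm": (30.0, None),
    "htc_pct": (10.0, 70.0), "hb_gdl": (4.0, None), "hr_bpm": (30.0, None),
    "br_bpm": (5.0, None), "spo2_pct": (None, 100.0), "thb_um": (20.0, None),
    "so2_pct": (5.0, 100.0), "musp_686": (1.0, None), "musp_830": (1.0, None),
    "dpf_686": (1.0, None), "dpf_830": (1.0, None),
}


@dataclass(frozen=True)
class CohortSpec:
    """Cell counts and per-cell (mean, sd) targets for the drawn variables.

    ``age_trends`` optionally adds a within-cluster linear age trend (units
    per year, centered on the cluster midpoint, so cell means are preserved)
    to emulate the qualitative age correlations of the reference cohort.
    """

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(REFERENCE_COUNTS)
    )
    cells: dict[str, dict[tuple[str, str], tuple[float, float]]] = field(
        default_factory=lambda: {v: dict(REFERENCE_CELLS[v]) for v in DRAWN_VARIABLES}
    )
    age_trends: dict[str, float] = field(default_factory=dict)
    extinction: ExtinctionTable = DEFAULT_EXTINCTION

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("cell counts must be nonnegative")
        for var, cells in self.cells.items():
            if any(sd < 0 for _, sd in cells.values()):
                raise ValueError(f"negative SD in spec for {var!r}")


DEFAULT_COHORT_SPEC = CohortSpec()


def _cluster_bounds(label: str) -> tuple[float, float]:
    lo, _, hi = label.partition(" to ")
    return float(lo), float(hi)


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    bounds: tuple[float | None, float | None],
    size: int,
) -> np.ndarray:
    """Draw from a normal law truncated to ``bounds``.

    When a bound is active (within 6 SD of the target mean) the location
    parameter is adjusted so the truncated law's mean equals the target:
    the tabulated cell means are sample means of the truncated quantity, so
    matching the raw normal location would bias the generated cell.
    """
    if sd == 0:
        return np.full(size, mean)
    lo, hi = bounds
    a = -np.inf if lo is None else lo
    b = np.inf if hi is None else hi
    if a <= mean - 6 * sd and b >= mean + 6 * sd:
        return rng.normal(mean, sd, size)

    def trunc_mean(loc: float) -> float:
        return stats.truncnorm.mean((a - loc) / sd, (b - loc) / sd, loc=loc, scale=sd)

    loc = optimize.brentq(
        lambda m: trunc_mean(m) - mean, mean - 6 * sd, mean + 6 * sd, xtol=1e-10
    )
    aa, bb = (a - loc) / sd, (b - loc) / sd
    return stats.truncnorm.rvs(aa, bb, loc=loc, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec = DEFAULT_COHORT_SPEC, seed: int = 0
) -> list[SubjectRecord]:
    """Draw a cohort with exactly the specified cell counts.

    Ages are uniform within each two-year cluster; drawn variables follow
    truncated-normal laws at their cell targets; absorption coefficients are
    computed from the drawn hemoglobin concentrations through the Beer law,
    and tHb/SO2 are derived exactly.  Reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    sid = 0
    for label in CLUSTER_LABELS:
        lo, hi = _cluster_bounds(label)
        for gender in GENDERS:
            n = spec.counts.get((label, gender), 0)
            if n == 0:
                continue
            ages = rng.uniform(lo, hi, n)
            draws: dict[str, np.ndarray] = {}
            for var in DRAWN_VARIABLES:
                mean, sd = spec.cells[var][(label, gender)]
                values = _truncated_normal(
                    rng, mean, sd, VARIABLE_BOUNDS.get(var, (None, None)), n
                )
                trend = spec.age_trends.get(var, 0.0)
                if trend:
                    values = values + trend * (ages - (lo + hi) / 2.0)
                draws[var] = values
            for i in range(n):
                sid += 1
                thb = float(draws["thb_um"][i])
                so2 = float(draws["so2_pct"][i])
                hbo2 = so2 / 100.0 * thb
                hhb = thb - hbo2
                mua686, mua830 = forward_beer(hbo2, hhb, spec.extinction)
                records.append(
                    SubjectRecord(
                        subject_id=f"S{sid:04d}",
                        gender=gender,
                        age_years=float(ages[i]),
                        bmi=float(draws["bmi"][i]),
                        bmi_z=float(draws["bmi_z"][i]),
                        head_circ_cm=float(draws["head_circ_cm"][i]),
                        htc_pct=float(draws["htc_pct"][i]),
                        hb_gdl=float(draws["hb_gdl"][i]),
                        hr_bpm=float(draws["hr_bpm"][i]),
                        br_bpm=float(draws["br_bpm"][i]),
                        spo2_pct=float(draws["spo2_pct"][i]),
                        hbo2_um=hbo2,
                        hhb_um=hhb,
                        thb_um=thb,
                        so2_pct=so2,
                        mua_686=mua686,
                        mua_830=mua830,
                        musp_686=float(draws["musp_686"][i]),
                        musp_830=float(draws["musp_830"][i]),
                        dpf_686=float(draws["dpf_686"][i]),
                        dpf_830=float(draws["dpf_830"][i]),
                    )
                )
    return records


def generate_enrollment_fixture(
    n_enrolled: int, n_noncompliant: int, seed: int = 0
) -> list[SubjectRecord]:
    """An enrollment set with exactly ``n_noncompliant`` subjects flagged
    non-compliant; the compliant subset has size n_enrolled - n_noncompliant."""
    if n_noncompliant > n_enrolled:
        raise ValueError("cannot flag more subjects than enrolled")
    rng = np.random.default_rng(seed)
    spec = DEFAULT_COHORT_SPEC
    # draw a plain cohort, then trim/extend to the enrollment size
    records = generate_cohort(spec, seed=seed)
    while len(records) < n_enrolled:
        extra = generate_cohort(spec, seed=int(rng.integers(2**31)))
        records.extend(extra)
    records = records[:n_enrolled]
    flagged = rng.choice(n_enrolled, size=n_noncompliant, replace=False)
    for idx in flagged:
        records[idx].compliant = False
    return records


def filter_compliant(records: list[SubjectRecord]) -> list[SubjectRecord]:
    return [r for r in records if r.compliant]


def generate_irf(
    fwhm: float,
    instrument: InstrumentConfig,
    shape: str = "gaussian",
    total_counts: float = 1e7,
    t0: float | None = None,
    tail_tau: float = 150.0,
    seed: int = 0,
    wavelength: float | None = None,
) -> InstrumentResponse:
    """Synthesize a unimodal IRF histogram with the requested FWHM (ps).

    ``gaussian`` gives a symmetric pulse; ``exp-modified`` convolves it with
    an exponential tail of time constant ``tail_tau`` (detector diffusion
    tail).  Counts are Poisson draws around the shape; reproducible for a
    given seed.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if total_counts <= 0:
        raise ValueError("IRF must be nonempty (total_counts > 0)")
    if fwhm < instrument.channel_width:
        import warnings

        warnings.warn(
            f"requested FWHM {fwhm} ps is below the {instrument.channel_width} "
            "ps channel width; the histogram FWHM is quantization-limited",
            UserWarning,
            stacklevel=2,
        )
    dt = instrument.channel_width
    t = np.arange(instrument.n_channels) * dt
    if t0 is None:
        t0 = 50 * dt
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    shape_vals = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    if shape == "exp-modified":
        tail = np.exp(-t / tail_tau)
        shape_vals = np.convolve(shape_vals, tail / tail.sum())[: len(t)]
    elif shape != "gaussian":
        raise ValueError("shape must be 'gaussian' or 'exp-modified'")
    lam = shape_vals * (total_counts / shape_vals.sum())
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.int64)
    if counts.sum() == 0:  # pathological tiny total_counts
        counts[int(np.argmax(lam))] = 1
    return InstrumentResponse(
        counts=counts, channel_width=dt, t_offset=0.0, wavelength=wavelength
    )


@dataclass(frozen=True)
class RepositioningModel:
    """Between-repositioning variability of the synthetic protocol.

    One relative perturbation of mua and one of musp are drawn per probe
    replacement and applied at both wavelengths (the replaced probe samples a
    slightly different tissue volume, which shifts blood content and
    scattering coherently across wavelengths); the optical coupling
    (amplitude) is drawn per replacement and wavelength.  Within a
    replacement, acquisitions differ only by photon (Poisson) noise.
    """

    mua_rel_sd: float = 0.025
    musp_rel_sd: float = 0.02
    amplitude_rel_sd: float = 0.05
    counts_per_dtof: float = 1e6
    n_repositionings: int = 5
    n_acquisitions: int = 5

    def __post_init__(self) -> None:
        if min(self.mua_rel_sd, self.musp_rel_sd, self.amplitude_rel_sd) < 0:
            raise ValueError("relative SDs must be nonnegative")


DEFAULT_REPOSITIONING = RepositioningModel()

#: Default synthetic instrument: a 1024-channel (~10 ns) window comfortably
#: contains the DTOF at pediatric-head optical properties and keeps the
#: per-DTOF fit cheap.
DEFAULT_SYNTH_INSTRUMENT = InstrumentConfig(n_channels=1024)


@dataclass(frozen=True)
class ProtocolDTOF:
    """One acquired DTOF with its protocol coordinates."""

    wavelength: float
    repositioning_index: int
    acquisition_index: int
    dtof: DTOFHistogram


def _positive_factor(rng: np.random.Generator, rel_sd: float) -> float:
    if rel_sd == 0:
        return 1.0
    return float(max(rng.normal(1.0, rel_sd), 1e-3))


def simulate_protocol(
    subject: SubjectRecord,
    instrument: InstrumentConfig = DEFAULT_SYNTH_INSTRUMENT,
    rep_model: RepositioningModel = DEFAULT_REPOSITIONING,
    irf: InstrumentResponse | None = None,
    seed: int = 0,
) -> list[ProtocolDTOF]:
    """Simulate the full measurement protocol of one subject.

    Returns n_repositionings x n_acquisitions DTOFs per wavelength (25 + 25
    by default).  The subject record must carry its true optical properties.
    """
    if irf is None:
        irf = generate_irf(60.0, instrument, seed=seed)
    rng = np.random.default_rng(seed)
    geom = MediumGeometry(
        rho=instrument.rho, refractive_index_tissue=instrument.refractive_index
    )
    t_grid = np.arange(instrument.n_channels) * instrument.channel_width
    truth = {
        686.0: (subject.mua_686, subject.musp_686),
        830.0: (subject.mua_830, subject.musp_830),
    }
    out: list[ProtocolDTOF] = []
    for rep in range(1, rep_model.n_repositionings + 1):
        f_mua = _positive_factor(rng, rep_model.mua_rel_sd)
        f_musp = _positive_factor(rng, rep_model.musp_rel_sd)
        for wl in instrument.wavelengths:
            mua0, musp0 = truth[wl]
            if mua0 is None or musp0 is None:
                raise ValueError(
                    f"subject {subject.subject_id} lacks true optical properties at {wl} nm"
                )
            op = OpticalProperties(mua=mua0 * f_mua, musp=musp0 * f_musp)
            conv = convolve_irf(tr_reflectance(op, geom, t_grid), irf)
            # place the convolved curve back on the instrument channel axis
            n = instrument.n_channels
            dt = instrument.channel_width
            values = np.zeros(n)
            start = round(float(conv.times[0]) / dt)
            length = min(n - start, len(conv.values))
            if length > 0:
                values[start : start + length] = conv.values[:length]
            curve = ModelCurve(times=t_grid, values=values)
            amp = _positive_factor(rng, rep_model.amplitude_rel_sd)
            for acq in range(1, rep_model.n_acquisitions + 1):
                dtof = simulate_dtof(
                    curve,
                    rep_model.counts_per_dtof * amp,
                    rng,
                    wavelength=wl,
                    acquisition_time=1.0,
                )
                out.append(
                    ProtocolDTOF(
                        wavelength=wl,
                        repositioning_index=rep,
                        acquisition_index=acq,
                        dtof=dtof,
                    )
                )
    return out
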