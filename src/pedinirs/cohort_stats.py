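"""Cohort-level statistics: age clustering, gender-stratified summaries,
pooled totals, Pearson correlations with the standard strength classes,
repositioning precision (coefficient of variation), and the age/wavelength
DPF general equation with its single-offset refit.

Age clusters are two-year bins partitioning [2, 18]: half-open [lower, upper)
except the top cluster, which is closed at 18.  Summaries use the sample
(n - 1) standard deviation; the divisor is configurable for sensitivity
checks.  p-values are reported raw (no multiple-testing correction); an
optional Benjamini-Hochberg column can be requested on correlation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import COHORT_AGE_RANGE, CohortRangeWarning


@dataclass(frozen=True)
class AgeCluster:
    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.upper - self.lower != 2:
            raise ValueError("age clusters are two years wide")


AGE_CLUSTERS: tuple[AgeCluster, ...] = tuple(
    AgeCluster(label=f"{lo} to {lo + 2}", lower=float(lo), upper=float(lo + 2))
    for lo in range(2, 18, 2)
)


def assign_age_cluster(age: float) -> AgeCluster:
    """Map an age to its two-year cluster ([lower, upper), top cluster closed)."""
    lo, hi = COHORT_AGE_RANGE
    if not lo <= age <= hi:
        warnings.warn(
            f"age {age} outside the reference range {lo}-{hi} y",
            CohortRangeWarning,
            stacklevel=2,
        )
    idx = int(np.clip((age - lo) // 2, 0, len(AGE_CLUSTERS) - 1))
    return AGE_CLUSTERS[idx]


def cluster_summary(
    df: pd.DataFrame,
    variable: str,
    gender: str | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-cluster count, mean and sample SD of one variable.

    ``df`` needs ``age_years`` (and ``gender`` if a gender is requested)
    columns.  Cells with fewer than ddof + 1 values report SD as NaN.
    """
    if gender is not None:
        df = df[df["gender"] == gender]
    rows = []
    for cluster in AGE_CLUSTERS:
        if cluster is AGE_CLUSTERS[-1]:
            mask = (df["age_years"] >= cluster.lower) & (df["age_years"] <= cluster.upper)
        else:
            mask = (df["age_years"] >= cluster.lower) & (df["age_years"] < cluster.upper)
        values = df.loc[mask, variable].dropna().to_numpy()
        n = len(values)
        mean = float(values.mean()) if n else np.nan
        sd = float(values.std(ddof=ddof)) if n > ddof else np.nan
        rows.append({"cluster": cluster.label, "n": n, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def pooled_total(cluster_means: Sequence[float], cluster_counts: Sequence[int]) -> float:
    """Count-weighted mean of cluster means (the tables' Total row)."""
    means = np.asarray(cluster_means, dtype=float)
    counts = np.asarray(cluster_counts, dtype=float)
    if means.shape != counts.shape:
        raise ValueError("cluster means and counts must have equal length")
    if np.any(counts <= 0):
        raise ValueError("cluster counts must be positive")
    return float(np.dot(means, counts) / counts.sum())


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

CorrelationClass = Literal["none", "low", "moderate", "high"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    class_label: CorrelationClass

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("r must lie in [-1, 1]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def classify_correlation(r: float) -> CorrelationClass:
    """Strength class on |r|: none < 0.3 <= low < 0.5 <= moderate < 0.7 <= high.

    Boundary values belong to the upper class (left-closed intervals).
    """
    a = abs(r)
    if a > 1:
        raise ValueError("|r| cannot exceed 1")
    if a < 0.3:
        return "none"
    if a < 0.5:
        return "low"
    if a < 0.7:
        return "moderate"
    return "high"


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment r with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(r=r, p_value=float(res.pvalue), class_label=classify_correlation(r))


def correlation_table(
    df: pd.DataFrame,
    variables: Sequence[str],
    against: Sequence[str] = ("age_years", "bmi_z", "head_circ_cm"),
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Gender-stratified Pearson correlations of ``variables`` against the
    auxological covariates; one row per (covariate, variable, gender)."""
    rows = []
    for gender in sorted(df["gender"].unique()):
        sub = df[df["gender"] == gender]
        for cov in against:
            for var in variables:
                pair = sub[[cov, var]].dropna()
                res = pearson_with_p(pair[cov], pair[var])
                rows.append(
                    {
                        "covariate": cov,
                        "variable": var,
                        "gender": gender,
                        "n": len(pair),
                        "r": res.r,
                        "p_value": res.p_value,
                        "class": res.class_label,
                    }
                )
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# repositioning precision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecisionResult:
    variable: str
    cv: pd.Series  # per-subject CV, %
    quartiles: tuple[float, float, float]  # 25/50/75 percentiles, %


def repositioning_cv(values: Sequence[float], ddof: int = 1) -> float:
    """Coefficient of variation CV = 100 * SD / mean over the per-repositioning
    means of one subject (sample SD by default)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("CV undefined for fewer than 2 repositionings")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=ddof) / abs(mean))


def precision_summary(
    per_subject_reps: pd.DataFrame,
    variable: str,
    subject_col: str = "subject_id",
    ddof: int = 1,
) -> PrecisionResult:
    """Per-subject repositioning CV of one variable plus cohort quartiles.

    ``per_subject_reps`` holds one row per (subject, repositioning) with the
    per-repositioning mean of the variable.
    """
    cv = (
        per_subject_reps.groupby(subject_col)[variable]
        .apply(lambda v: repositioning_cv(v.to_numpy(), ddof=ddof))
        .rename("cv_pct")
    )
    q = np.percentile(cv.to_numpy(), [25, 50, 75])
    return PrecisionResult(variable=variable, cv=cv, quartiles=(float(q[0]), float(q[1]), float(q[2])))


# ---------------------------------------------------------------------------
# DPF general equation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DPFModelParams:
    """Coefficients of the age/wavelength DPF general equation

        DPF(A, lambda) = alpha + beta * A^gamma
                         + delta * lambda^3 + epsilon * lambda^2 + zeta * lambda

    with A in years and lambda in nm (cubic + quadratic + linear wavelength
    polynomial, as in the published general equation)."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float
    zeta: float


#: Published general-equation coefficients (Scholkmann-Wolf parametrization).
SCHOLKMANN_WOLF_PARAMS = DPFModelParams(
    alpha=223.3,
    beta=0.05624,
    gamma=0.8493,
    delta=-5.723e-7,
    epsilon=0.001245,
    zeta=-0.9025,
)


def dpf_general_equation(params: DPFModelParams, age: float, wavelength: float) -> float:
    """Evaluate the DPF general equation at one (age, wavelength)."""
    if age <= 0:
        raise ValueError("age must be positive")
    value = (
        params.alpha
        + params.beta * age**params.gamma
        + params.delta * wavelength**3
        + params.epsilon * wavelength**2
        + params.zeta * wavelength
    )
    if not np.isfinite(value):
        raise ArithmeticError("DPF model evaluated to a non-finite value")
    return float(value)


def refit_alpha(
    observations: Iterable[tuple[float, float, float]],
    params: DPFModelParams = SCHOLKMANN_WOLF_PARAMS,
) -> float:
    """Offset refit of the general equation: the alpha minimizing the mean
    squared error against (age, wavelength, DPF) observations with all other
    coefficients fixed.  Closed form: mean(observed - model-without-alpha)."""
    obs = list(observations)
    if not obs:
        raise ValueError("need at least one observation")
    residuals = [
        dpf - (dpf_general_equation(params, age, lam) - params.alpha)
        for age, lam, dpf in obs
    ]
    return float(np.mean(residuals))
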