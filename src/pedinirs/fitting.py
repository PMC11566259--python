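"""Recover (mua, musp) from a measured DTOF + IRF and compute the DPF.

The fit minimizes the weighted sum of squared residuals between the
amplitude-scaled, IRF-convolved diffusion-model curve and the measured counts
inside a fit window running from the channel where the rising edge first
reaches 80% of the peak to the last channel above 1% of the peak on the tail
(both fractions configurable).  The amplitude is profiled analytically at
every iteration, so the search runs over (log mua, log musp) only; the log
transform keeps the iterates positive.  Poisson weighting uses a per-channel
variance of max(count, 1).

The DPF is computed as DPF = v * <t> / rho with v = c/n.  By default <t> is
the instrument-corrected first moment of the background-subtracted measured
DTOF (measured moment minus IRF barycenter); an alternative mode evaluates
the moment of the fitted model curve instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_io import (
    SPEED_OF_LIGHT_CM_S,
    DPFResult,
    DTOFHistogram,
    FitReport,
    InstrumentResponse,
    OpticalProperties,
)
from .forward_model import MediumGeometry, ModelCurve, convolve_irf, mean_time, tr_reflectance


@dataclass(frozen=True)
class FitConfig:
    window_rise_fraction: float = 0.8
    window_tail_fraction: float = 0.01
    weighting: Literal["poisson", "uniform"] = "poisson"
    initial_mua: float = 0.1  # 1/cm
    initial_musp: float = 10.0  # 1/cm
    max_iterations: int = 400
    tolerance: float = 1e-10
    background_channels: int = 32
    dpf_mode: Literal["measured_moment", "model_moment"] = "measured_moment"

    def __post_init__(self) -> None:
        if not 0 < self.window_tail_fraction <= self.window_rise_fraction <= 1:
            raise ValueError("require 0 < tail fraction <= rise fraction <= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.initial_mua <= 0 or self.initial_musp <= 0:
            raise ValueError("initial parameters must be positive")


def subtract_background(counts: np.ndarray, n_background: int) -> np.ndarray:
    """Subtract the median of the first ``n_background`` channels (clipped at 0)."""
    counts = np.asarray(counts, dtype=float)
    if n_background <= 0:
        return counts.copy()
    bg = float(np.median(counts[:n_background]))
    return np.clip(counts - bg, 0.0, None)


def select_fit_window(h: DTOFHistogram, cfg: FitConfig) -> tuple[int, int]:
    """Inclusive channel range [first rise-crossing, last tail-crossing]."""
    counts = subtract_background(h.counts, cfg.background_channels)
    peak = counts.max()
    if peak <= 0:
        raise ValueError("cannot select a fit window on an all-zero histogram")
    ipk = int(np.argmax(counts))
    rise_level = cfg.window_rise_fraction * peak
    tail_level = cfg.window_tail_fraction * peak
    lo = int(np.argmax(counts[: ipk + 1] >= rise_level))
    above_tail = np.nonzero(counts >= tail_level)[0]
    hi = int(above_tail[-1])
    if hi < lo:
        hi = lo
    return lo, hi


def _aligned_kernel(h: DTOFHistogram, irf: InstrumentResponse, background_channels: int):
    """Unit-area IRF kernel and the integer channel shift between the IRF and
    DTOF time origins."""
    if not np.isclose(h.channel_width, irf.channel_width, rtol=1e-9):
        raise ValueError(
            f"channel-width mismatch: dtof {h.channel_width} ps vs irf {irf.channel_width} ps"
        )
    dt = h.channel_width
    rel = (irf.t_offset - h.t_offset) / dt
    shift = round(rel)
    if abs(rel - shift) > 1e-6:
        raise ValueError("IRF and DTOF time offsets differ by a non-integer channel count")
    kernel = subtract_background(irf.counts, background_channels)
    total = kernel.sum()
    if total <= 0:
        raise ValueError("IRF is empty after background subtraction")
    nz = np.nonzero(kernel)[0]
    first, last = int(nz[0]), int(nz[-1])
    return kernel[first : last + 1] / total, shift + first


def fit_optical_properties(
    h: DTOFHistogram,
    irf: InstrumentResponse,
    geom: MediumGeometry,
    cfg: FitConfig = FitConfig(),
) -> FitReport:
    """Nonlinear least-squares fit of the convolved diffusion model."""
    n = h.n_channels
    kernel, shift = _aligned_kernel(h, irf, cfg.background_channels)
    data = subtract_background(h.counts, cfg.background_channels)
    lo, hi = select_fit_window(h, cfg)
    window = slice(lo, hi + 1)
    d = data[window]
    if cfg.weighting == "poisson":
        sigma = np.sqrt(np.maximum(d, 1.0))
    else:
        sigma = np.ones_like(d)

    # model sampled on the DTOF's own grid, relative to the laser pulse
    t_model = np.arange(n) * h.channel_width

    def convolved(logp: np.ndarray) -> np.ndarray:
        mua, musp = np.exp(logp)
        curve = tr_reflectance(OpticalProperties(mua=mua, musp=musp), geom, t_model)
        m = np.convolve(curve.values, kernel)
        # place the convolved curve on the DTOF channel axis
        out = np.zeros(n)
        start = shift
        src = m
        if start < 0:
            src = src[-start:]
            start = 0
        length = min(n - start, len(src))
        if length > 0:
            out[start : start + length] = src[:length]
        return out[window]

    def residuals(logp: np.ndarray) -> np.ndarray:
        m = convolved(logp)
        mw = m / sigma
        dw = d / sigma
        denom = np.dot(mw, mw)
        amp = np.dot(mw, dw) / denom if denom > 0 else 0.0
        residuals.amplitude = amp  # type: ignore[attr-defined]
        return amp * mw - dw

    x0 = np.log([cfg.initial_mua, cfg.initial_musp])
    result = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=cfg.tolerance,
        ftol=cfg.tolerance,
        gtol=cfg.tolerance,
        max_nfev=cfg.max_iterations,
    )
    mua, musp = np.exp(result.x)
    dof = max(len(d) - 3, 1)  # mua, musp, amplitude
    report = FitReport(
        estimate=OpticalProperties(mua=float(mua), musp=float(musp)),
        fit_window=(lo, hi),
        reduced_residual=float(2.0 * result.cost / dof),
        converged=bool(result.status > 0 and result.nfev < cfg.max_iterations),
        iterations=int(result.nfev),
        amplitude=float(getattr(residuals, "amplitude", 1.0)),
    )
    return report


def dpf_from_mean_time(
    mean_t: float, geom: MediumGeometry, c: float = SPEED_OF_LIGHT_CM_S
) -> DPFResult:
    """DPF = v <t> / rho with v = c/n (c in cm/s, <t> in ps, rho in cm)."""
    if mean_t < 0:
        raise ValueError("mean time must be nonnegative")
    v = c / geom.refractive_index_tissue * 1e-12  # cm/ps
    return DPFResult(dpf=v * mean_t / geom.rho, mean_time=mean_t)


def measured_mean_time(
    h: DTOFHistogram, irf: InstrumentResponse | None, cfg: FitConfig = FitConfig()
) -> float:
    """Instrument-corrected mean time of flight (ps).

    First moment of the background-subtracted DTOF minus the IRF barycenter
    (and minus any residual offset between the two time axes).
    """
    counts = subtract_background(h.counts, cfg.background_channels)
    total = counts.sum()
    if total <= 0:
        raise ValueError("mean time undefined for an empty histogram")
    t = h.times
    mt = float(np.dot(counts, t) / total)
    if irf is not None:
        bg_irf = subtract_background(irf.counts, cfg.background_channels)
        mt -= float(np.dot(bg_irf, irf.times) / bg_irf.sum())
    return mt


def dpf_from_dtof(
    h: DTOFHistogram,
    irf: InstrumentResponse,
    geom: MediumGeometry,
    cfg: FitConfig = FitConfig(),
    fit: FitReport | None = None,
) -> DPFResult:
    """DPF of a single measurement, in the mode selected by ``cfg.dpf_mode``."""
    if cfg.dpf_mode == "measured_moment":
        mt = measured_mean_time(h, irf, cfg)
    else:
        if fit is None:
            fit = fit_optical_properties(h, irf, geom, cfg)
        t_model = np.arange(h.n_channels) * h.channel_width
        curve = tr_reflectance(fit.estimate, geom, t_model)
        mt = mean_time(curve)
    return dpf_from_mean_time(max(mt, 0.0), geom)


# ---------------------------------------------------------------------------
# subject-level aggregation
# ---------------------------------------------------------------------------


@dataclass
class SubjectEstimate:
    """Per-DTOF, per-repositioning and subject-level estimates.

    ``per_dtof`` has one row per (wavelength, repositioning, acquisition);
    ``per_repositioning`` averages the 5 acquisitions of each repositioning
    (the unit of the test-retest precision analysis); ``subject_mean`` is the
    arithmetic mean over all 25 per-DTOF estimates, per wavelength.
    """

    per_dtof: pd.DataFrame
    per_repositioning: pd.DataFrame
    subject_mean: pd.DataFrame


def estimate_subject(
    measurements: Iterable[tuple[int, int, DTOFHistogram]],
    irf: InstrumentResponse,
    geom: MediumGeometry,
    cfg: FitConfig = FitConfig(),
) -> SubjectEstimate:
    """Fit every DTOF of a subject's protocol and aggregate.

    ``measurements`` yields (repositioning_index, acquisition_index, dtof)
    triples; wavelength is taken from each histogram's metadata.  Missing
    acquisitions are tolerated (with a warning downstream of the caller) as
    long as every repositioning retains at least one DTOF per wavelength.
    """
    rows = []
    for rep, acq, h in measurements:
        report = fit_optical_properties(h, irf, geom, cfg)
        dpf = dpf_from_dtof(h, irf, geom, cfg, fit=report)
        rows.append(
            {
                "wavelength": h.wavelength,
                "repositioning_index": rep,
                "acquisition_index": acq,
                "mua": report.estimate.mua,
                "musp": report.estimate.musp,
                "dpf": dpf.dpf,
                "mean_time": dpf.mean_time,
                "converged": report.converged,
                "reduced_residual": report.reduced_residual,
            }
        )
    if not rows:
        raise ValueError("no measurements supplied")
    per_dtof = pd.DataFrame(rows)
    by_rep = per_dtof.groupby(["wavelength", "repositioning_index"], as_index=False)
    per_rep = by_rep[["mua", "musp", "dpf", "mean_time"]].mean()
    counts = by_rep.size()
    if (counts["size"] < 1).any():
        raise ValueError("every repositioning needs at least one DTOF")
    subject_mean = per_dtof.groupby("wavelength", as_index=False)[
        ["mua", "musp", "dpf", "mean_time"]
    ].mean()
    return SubjectEstimate(
        per_dtof=per_dtof, per_repositioning=per_rep, subject_mean=subject_mean
    )
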