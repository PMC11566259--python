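"""Time-resolved reflectance of a semi-infinite homogeneous diffusive medium.

The solution of the photon diffusion equation with extrapolated boundary
conditions is evaluated as an image-source expansion: the isotropic source at
depth ``z0 = 1/musp`` and its negative mirror image across the extrapolated
boundary at ``-zb``, where ``zb = 2*A*D`` and ``A`` accounts for the
refractive-index mismatch at the tissue surface.  With the modern convention
``D = 1/(3*musp)`` (absorption-independent diffusion coefficient) the
reflectance at source-detector distance ``rho`` reads

    R(rho, t) = (4 pi D v)^(-3/2) t^(-5/2) exp(-mua v t - rho^2/(4 D v t))
                * 1/2 * sum_m [ z_{+,m} exp(-z_{+,m}^2/(4 D v t))
                               + z_{-,m} exp(-z_{-,m}^2/(4 D v t)) ]

with one dipole (m = 0: z_+ = z0, z_- = 2 zb + z0) by default; additional
image pairs are available for accuracy studies but change the curve
negligibly in reflectance geometry at rho = 2.5 cm.

All times are picoseconds, all lengths centimeters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SPEED_OF_LIGHT_CM_S, DTOFHistogram, InstrumentResponse, OpticalProperties


class DomainError(ValueError):
    """Physically inadmissible model parameters."""


@dataclass(frozen=True)
class MediumGeometry:
    """Source-detector geometry and refractive indices of the half-space."""

    rho: float  # cm
    refractive_index_tissue: float = 1.4
    refractive_index_external: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.refractive_index_tissue < 1 or self.refractive_index_external < 1:
            raise ValueError("refractive indices must be >= 1")

    @property
    def v(self) -> float:
        """Speed of light in the medium, cm/ps."""
        return SPEED_OF_LIGHT_CM_S / self.refractive_index_tissue * 1e-12


@dataclass
class ModelCurve:
    """A model reflectance curve sampled on a uniform time grid (ps)."""

    times: np.ndarray  # ps
    values: np.ndarray  # 1/(cm^2 ps)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("empty time grid")

    @property
    def channel_width(self) -> float:
        if len(self.times) < 2:
            raise ValueError("channel width undefined for a single sample")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("time grid is not uniform")
        return float(dt[0])

    def integral(self) -> float:
        """Time integral by the trapezoidal rule (per cm^2)."""
        return float(np.trapezoid(self.values, self.times))


def internal_reflection_parameter(n_relative: float) -> float:
    """Boundary parameter A(n) of the extrapolated boundary condition.

    Uses the Groenhuis polynomial approximation of the internal diffuse
    reflectance r_d, A = (1 + r_d)/(1 - r_d); accurate to a few percent for
    1 <= n <= 1.6 and the conventional choice for tissue/air interfaces.
    """
    if n_relative < 1:
        raise DomainError("relative refractive index must be >= 1")
    r_d = -1.440 * n_relative**-2 + 0.710 / n_relative + 0.668 + 0.0636 * n_relative
    return (1.0 + r_d) / (1.0 - r_d)


def tr_reflectance(
    op: OpticalProperties,
    geom: MediumGeometry,
    t_grid: np.ndarray,
    n_dipoles: int = 1,
) -> ModelCurve:
    """Time-resolved reflectance R(rho, t) on ``t_grid`` (ps).

    Exactly zero at t <= 0 (causality); nonnegative and finite everywhere.
    """
    if op.musp <= 0:
        raise DomainError("musp must be positive")
    if op.mua < 0:
        raise DomainError("mua must be nonnegative")
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise DomainError("time grid must be nonnegative")

    v = geom.v
    D = 1.0 / (3.0 * op.musp)
    z0 = 1.0 / op.musp
    n_rel = geom.refractive_index_tissue / geom.refractive_index_external
    zb = 2.0 * internal_reflection_parameter(n_rel) * D

    out = np.zeros_like(t)
    pos = t > 0
    tt = t[pos]
    dvt4 = 4.0 * D * v * tt
    pref = (np.pi * dvt4) ** -1.5 * v * np.exp(-op.mua * v * tt - geom.rho**2 / dvt4)
    acc = np.zeros_like(tt)
    for m in range(n_dipoles):
        shift = 2.0 * m * (2.0 * zb + 2.0 * z0)
        sign = (-1.0) ** m
        z_p = shift + z0
        z_m = shift + 2.0 * zb + z0
        acc += sign * (z_p * np.exp(-z_p**2 / dvt4) + z_m * np.exp(-z_m**2 / dvt4))
    out[pos] = 0.5 * pref / (v * tt) * acc
    np.clip(out, 0.0, None, out=out)
    return ModelCurve(times=t, values=out)


def cw_reflectance(op: OpticalProperties, geom: MediumGeometry) -> float:
    """Steady-state (CW) reflectance of the same dipole solution (per cm^2).

    Equals the time integral of :func:`tr_reflectance`; used as the
    closed-form check of the time-resolved curve.
    """
    D = 1.0 / (3.0 * op.musp)
    z0 = 1.0 / op.musp
    n_rel = geom.refractive_index_tissue / geom.refractive_index_external
    zb = 2.0 * internal_reflection_parameter(n_rel) * D
    mueff = np.sqrt(op.mua / D)
    zp = 2.0 * zb + z0
    r1 = np.hypot(z0, geom.rho)
    r2 = np.hypot(zp, geom.rho)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = zp * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return float((term1 + term2) / (4.0 * np.pi))


def mean_time(curve: ModelCurve) -> float:
    """First moment of the curve over its grid (ps), by channel summation.

    Channel (rectangle-rule) quadrature keeps the first moment exactly
    additive under discrete convolution, matching histogram semantics.
    """
    total = curve.values.sum()
    if total <= 0:
        raise ValueError("mean time undefined for a zero-area curve")
    return float(np.dot(curve.values, curve.times) / total)


def convolve_irf(curve: ModelCurve, irf: InstrumentResponse) -> ModelCurve:
    """Discrete convolution of a model curve with a unit-area IRF kernel.

    The IRF is normalized to unit sum so that the convolution conserves the
    curve's channel sum; first moments add exactly (output grid offset is the
    sum of the input offsets).
    """
    dt = curve.channel_width
    if not np.isclose(dt, irf.channel_width, rtol=1e-9):
        raise ValueError(
            f"channel-width mismatch: curve {dt} ps vs irf {irf.channel_width} ps"
        )
    kernel = np.asarray(irf.counts, dtype=float)
    total = kernel.sum()
    if total <= 0:
        raise ValueError("IRF total counts must be positive")
    # trim to the kernel's support; zeros outside contribute nothing
    nz = np.nonzero(kernel)[0]
    first, last = int(nz[0]), int(nz[-1])
    kernel = kernel[first : last + 1] / total
    values = np.convolve(curve.values, kernel)
    t0 = curve.times[0] + irf.t_offset + first * dt
    times = t0 + np.arange(len(values)) * dt
    return ModelCurve(times=times, values=values)


def simulate_dtof(
    curve: ModelCurve,
    total_counts: float,
    seed: int | np.random.Generator,
    wavelength: float | None = None,
    acquisition_time: float = 1.0,
) -> DTOFHistogram:
    """Draw a Poisson DTOF whose expected total equals ``total_counts``."""
    if total_counts < 0:
        raise ValueError("total_counts must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    area = curve.values.sum()
    if total_counts == 0 or area <= 0:
        counts = np.zeros(len(curve.values), dtype=np.int64)
    else:
        lam = curve.values * (total_counts / area)
        counts = rng.poisson(lam).astype(np.int64)
    return DTOFHistogram(
        counts=counts,
        channel_width=curve.channel_width,
        t_offset=float(curve.times[0]),
        wavelength=wavelength,
        acquisition_time=acquisition_time,
    )
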