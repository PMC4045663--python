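"""Three-pool Gaussian forward model for multi-echo T2 relaxometry.

The transverse relaxation signal in a voxel is modeled as a discrete
multi-exponential decay over a log-spaced grid of T2 values,

    y_k = sum_i  x_i * exp(-TE_k / tau_i) + eps_k,

with the T2 distribution ``x`` restricted to three resolvable water
compartments: a fast-relaxing myelin water pool and an intermediate
intra/extra-cellular (IE) pool, each modeled as a Gaussian peak over tau,
plus a single very long T2 cerebrospinal-fluid (CSF) component.  Eight
parameters per voxel (height, mean and width of each Gaussian pool, height
and location of the CSF pool) determine the full distribution; the myelin
water fraction is the myelin height over the sum of all three heights.

The CSF location (~1800 ms) lies far outside the 5-300 ms analysis grid,
so that component is carried analytically in the signal model rather than
binned onto the grid.  Gaussian pool heights follow the *area* convention:
each pool's grid profile is renormalized to unit sum before scaling by its
height, so heights behave as volume fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "N_PARAMS",
    "PARAM_NAMES",
    "DegenerateModelError",
    "T2Grid",
    "EchoSchedule",
    "VoxelTheta",
    "ParamBounds",
    "T2Distribution",
    "build_grid",
    "mese_schedule",
    "spiral_schedule",
    "decay_basis",
    "theta_to_distribution",
    "predict_signal",
    "mwf",
    "field_weights",
    "field_signals",
    "field_mwf",
]

#: Number of fitted parameters per voxel.
N_PARAMS = 8

#: Canonical parameter order used for all flat arrays of shape (..., 8).
PARAM_NAMES = (
    "c_my", "mu_my", "sigma_my",
    "c_ie", "mu_ie", "sigma_ie",
    "c_csf", "mu_csf",
)

_TINY = 1e-300


class DegenerateModelError(ValueError):
    """A pool with nonzero height carries no mass on the T2 grid."""


@dataclass(frozen=True)
class T2Grid:
    """Strictly increasing, positive grid of T2 relaxation times in ms."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("T2 grid needs at least two points")
        if np.any(pts <= 0):
            raise ValueError("T2 grid points must be positive")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("T2 grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def count(self) -> int:
        return self.points.size

    @property
    def span(self) -> float:
        """Grid extent in ms (used as the time scale for unit mixing)."""
        return float(self.points[-1] - self.points[0])


@dataclass(frozen=True)
class EchoSchedule:
    """Echo times TE_k in ms, strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("echo schedule needs at least two echoes")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def count(self) -> int:
        return self.times.size


def build_grid(count: int = 40, t2_min: float = 5.0, t2_max: float = 300.0) -> T2Grid:
    """Log-spaced T2 grid; default 40 points over 5-300 ms."""
    if count < 2:
        raise ValueError("grid needs count >= 2")
    if not (0 < t2_min < t2_max):
        raise ValueError("require 0 < t2_min < t2_max")
    pts = np.geomspace(t2_min, t2_max, count)
    pts[0], pts[-1] = t2_min, t2_max  # exact endpoints
    return T2Grid(pts)


def mese_schedule() -> EchoSchedule:
    """32-echo multi-echo spin echo preset: 5 ms, then 10-310 ms in 10 ms steps."""
    return EchoSchedule(np.r_[5.0, np.arange(10.0, 311.0, 10.0)])


def spiral_schedule(count: int = 20) -> EchoSchedule:
    """T2-prep spiral preset: ``count`` echoes log-spaced over 5-300 ms."""
    return EchoSchedule(np.geomspace(5.0, 300.0, count))


@dataclass
class VoxelTheta:
    """The eight per-voxel model parameters.

    Heights (``c_*``) are unitless volume fractions; means, widths and the
    CSF location are in ms.
    """

    c_my: float
    mu_my: float
    sigma_my: float
    c_ie: float
    mu_ie: float
    sigma_ie: float
    c_csf: float
    mu_csf: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "VoxelTheta":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected shape ({N_PARAMS},), got {arr.shape}")
        return cls(*arr)


@dataclass(frozen=True)
class ParamBounds:
    """Per-parameter lower/upper bounds and initial guess, in PARAM_NAMES order."""

    lower: np.ndarray
    upper: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        x0 = np.asarray(self.initial, dtype=float)
        for name, a in (("lower", lo), ("upper", hi), ("initial", x0)):
            if a.shape != (N_PARAMS,):
                raise ValueError(f"{name} must have shape ({N_PARAMS},)")
        if np.any(lo > x0) or np.any(x0 > hi):
            raise ValueError("require lower <= initial <= upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "initial", x0)

    @classmethod
    def defaults(cls) -> "ParamBounds":
        """Standard initial guesses and allowable ranges for brain fitting.

        Heights of the Gaussian pools are confined to [0, 1]; the myelin mean
        to [10, 40] ms and the IE mean to [60, 200] ms.  Pool widths carry no
        published range — a floor of 0.5 ms is imposed for conditioning.  The
        CSF location is kept above the grid ceiling (>= 300 ms).
        """
        return cls(
            lower=np.array([0.0, 10.0, 0.5, 0.0, 60.0, 0.5, 0.0, 300.0]),
            upper=np.array([1.0, 40.0, np.inf, 1.0, 200.0, np.inf, np.inf, np.inf]),
            initial=np.array([0.1, 15.0, 10.0, 0.9, 80.0, 100.0, 0.0, 1800.0]),
        )

    def initial_theta(self) -> VoxelTheta:
        return VoxelTheta.from_array(self.initial)


@dataclass
class T2Distribution:
    """Nonnegative weights on a T2 grid plus a separately carried CSF term."""

    weights: np.ndarray
    csf_height: float = 0.0
    csf_location: float = 1800.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("distribution weights must be nonnegative")
        if self.csf_height < 0:
            raise ValueError("csf_height must be nonnegative")
        self.weights = w

    def total(self) -> float:
        return float(self.weights.sum() + self.csf_height)

    def with_csf_bin(self, grid: T2Grid) -> tuple[np.ndarray, np.ndarray]:
        """Export for display: grid taus plus one extra bin at the CSF location."""
        taus = np.r_[grid.points, self.csf_location]
        w = np.r_[self.weights, self.csf_height]
        return taus, w


def decay_basis(grid: T2Grid, echoes: EchoSchedule) -> np.ndarray:
    """K x N matrix with entry (k, i) = exp(-TE_k / tau_i)."""
    return np.exp(-echoes.times[:, None] / grid.points[None, :])


def _pool_profiles(mu, sigma, points: np.ndarray) -> np.ndarray:
    """Unit-sum Gaussian profiles over grid points; broadcasts over leading dims.

    Profiles are truncated to the grid support and renormalized so the grid
    sum is exactly 1; zero-mass profiles are returned as all-zero (callers
    that require mass must check).
    """
    mu = np.asarray(mu, dtype=float)[..., None]
    sigma = np.asarray(sigma, dtype=float)[..., None]
    z = (points - mu) / np.maximum(sigma, _TINY)
    prof = np.exp(-0.5 * z * z)
    mass = prof.sum(axis=-1, keepdims=True)
    return prof / np.maximum(mass, _TINY)


def theta_to_distribution(theta: VoxelTheta, grid: T2Grid) -> T2Distribution:
    """Evaluate the two Gaussian pools on the grid; carry CSF separately.

    Each pool's profile is renormalized to unit grid sum, so the grid sum of
    the returned weights equals ``c_my + c_ie``.
    """
    weights = np.zeros(grid.count)
    for c, mu, sigma in ((theta.c_my, theta.mu_my, theta.sigma_my),
                         (theta.c_ie, theta.mu_ie, theta.sigma_ie)):
        if c < 0:
            raise ValueError("pool heights must be nonnegative")
        if c == 0:
            continue
        prof = np.exp(-0.5 * ((grid.points - mu) / max(sigma, _TINY)) ** 2)
        mass = prof.sum()
        if mass <= 0:
            raise DegenerateModelError(
                f"pool at mu={mu} ms, sigma={sigma} ms has no mass on the grid"
            )
        weights += c * prof / mass
    return T2Distribution(weights, csf_height=theta.c_csf, csf_location=theta.mu_csf)


def predict_signal(theta: VoxelTheta, grid: T2Grid, echoes: EchoSchedule) -> np.ndarray:
    """Forward signal: decay basis times grid weights plus the analytic CSF decay."""
    dist = theta_to_distribution(theta, grid)
    signal = decay_basis(grid, echoes) @ dist.weights
    if dist.csf_height:
        signal = signal + dist.csf_height * np.exp(-echoes.times / dist.csf_location)
    return signal


def mwf(theta: VoxelTheta, return_flag: bool = False):
    """Myelin water fraction c_my / (c_my + c_ie + c_csf).

    All-zero heights are degenerate: the value 0.0 is returned (with a flag
    when ``return_flag``), keeping maps finite.
    """
    heights = np.array([theta.c_my, theta.c_ie, theta.c_csf], dtype=float)
    if np.any(heights < 0):
        raise ValueError("pool heights must be nonnegative")
    total = heights.sum()
    degenerate = total == 0.0
    value = 0.0 if degenerate else float(theta.c_my / total)
    return (value, degenerate) if return_flag else value


# ---------------------------------------------------------------------------
# Vectorized field-level API (used by the solver and the simulator).
# theta arrays have shape (..., 8) in PARAM_NAMES order.

def field_weights(theta: np.ndarray, grid: T2Grid) -> np.ndarray:
    """Grid weights for a stack of parameter vectors; shape (..., N)."""
    theta = np.asarray(theta, dtype=float)
    g_my = _pool_profiles(theta[..., 1], theta[..., 2], grid.points)
    g_ie = _pool_profiles(theta[..., 4], theta[..., 5], grid.points)
    return theta[..., 0:1] * g_my + theta[..., 3:4] * g_ie


def field_signals(theta: np.ndarray, grid: T2Grid, echoes: EchoSchedule) -> np.ndarray:
    """Forward signals for a stack of parameter vectors; shape (..., K)."""
    theta = np.asarray(theta, dtype=float)
    weights = field_weights(theta, grid)
    signals = weights @ decay_basis(grid, echoes).T
    csf = theta[..., 6:7] * np.exp(-echoes.times / np.maximum(theta[..., 7:8], _TINY))
    return signals + csf


def field_mwf(theta: np.ndarray) -> np.ndarray:
    """Vectorized MWF; zero where all heights vanish."""
    theta = np.asarray(theta, dtype=float)
    total = theta[..., 0] + theta[..., 3] + theta[..., 6]
    out = np.zeros(total.shape)
    np.divide(theta[..., 0], total, out=out, where=total > 0)
    return out
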