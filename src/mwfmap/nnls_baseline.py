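"""Conventional per-voxel Tikhonov-regularized NNLS T2 fitting.

The benchmark inversion assigns nonnegative weights to every point of a
dense T2 grid by minimizing ||A x - y||^2 + lambda_T^2 ||x||^2 subject to
x >= 0, solved as plain NNLS on the row-augmented system [A; lambda_T I].
The regularization strength is chosen per voxel by the chi-squared
criterion: among 100 log-spaced lambda values, pick one whose misfit norm
lies between 102.0% and 102.5% of the unregularized misfit norm.  MWF is
read off the fitted distribution as the mass below a 40 ms cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _nnls

from .core_model import T2Grid, build_grid, decay_basis
from .volume import EchoVolume, normalization_factor

__all__ = [
    "NNLSConfig",
    "NNLSResult",
    "NNLSVolumeResult",
    "fit_nnls_voxel",
    "select_lambda",
    "mwf_from_distribution",
    "fit_nnls_volume",
]


@dataclass(frozen=True)
class NNLSConfig:
    """Regularization search and MWF readout settings."""

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-5, 1e-1, 100)
    )
    residual_window: tuple[float, float] = (1.020, 1.025)
    myelin_cutoff: float = 40.0  # ms

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_grid, dtype=float)
        if np.any(lam <= 0) or np.any(np.diff(lam) <= 0):
            raise ValueError("lambda grid must be positive and increasing")
        lo, hi = self.residual_window
        if not lo < hi:
            raise ValueError("residual window must satisfy lower < upper")
        object.__setattr__(self, "lambda_grid", lam)


@dataclass
class NNLSResult:
    """Per-voxel fit: grid weights, selected lambda and diagnostics."""

    weights: np.ndarray
    lambda_selected: float
    residual_ratio: float
    mwf_value: float
    in_window: bool
    degenerate: bool = False  # unregularized misfit ~ 0 (noiseless exact fit)


@dataclass
class NNLSVolumeResult:
    mwf_map: np.ndarray
    distributions: np.ndarray  # (Nv, N) weights for masked voxels
    lambda_map: np.ndarray
    mask: np.ndarray
    grid: T2Grid
    norm_factor: float


def fit_nnls_voxel(signal: np.ndarray, basis: np.ndarray, lambda_t: float = 0.0) -> np.ndarray:
    """Tikhonov-NNLS solve for one voxel.

    Minimizes ``||A x - y||^2 + lambda_t^2 ||x||^2`` over x >= 0 via NNLS on
    the augmented system.
    """
    y = np.asarray(signal, dtype=float)
    A = np.asarray(basis, dtype=float)
    if y.size == 0 or A.size == 0:
        raise ValueError("empty signal or basis")
    if A.shape[0] != y.size:
        raise ValueError("basis rows must match signal length")
    if lambda_t < 0:
        raise ValueError("lambda_t must be nonnegative")
    if lambda_t == 0:
        x, _ = _nnls(A, y)
        return x
    n = A.shape[1]
    A_aug = np.vstack([A, lambda_t * np.eye(n)])
    y_aug = np.r_[y, np.zeros(n)]
    x, _ = _nnls(A_aug, y_aug)
    return x


def _misfit(A: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.linalg.norm(A @ x - y))


def select_lambda(
    signal: np.ndarray, basis: np.ndarray, config: NNLSConfig | None = None
) -> NNLSResult:
    """Chi-squared lambda selection.

    Sweeps the lambda grid, computing the ratio of each regularized misfit
    norm to the unregularized one; returns a fit whose ratio falls inside
    the acceptance window.  If several lambdas qualify, the largest is taken
    (most regularization at acceptable misfit); if none do, the lambda whose
    ratio is closest to the window midpoint.  A near-zero unregularized
    misfit (noiseless, exactly representable signal) short-circuits to the
    smallest lambda with a degenerate flag.
    """
    config = config or NNLSConfig()
    y = np.asarray(signal, dtype=float)
    A = np.asarray(basis, dtype=float)
    x0 = fit_nnls_voxel(y, A, 0.0)
    r0 = _misfit(A, x0, y)
    scale = max(float(np.linalg.norm(y)), 1.0)
    if r0 <= 1e-10 * scale:
        lam = float(config.lambda_grid[0])
        x = fit_nnls_voxel(y, A, lam)
        return NNLSResult(x, lam, 1.0, 0.0, in_window=False, degenerate=True)

    lo, hi = config.residual_window
    mid = 0.5 * (lo + hi)
    best_in_window: tuple[float, np.ndarray, float] | None = None
    best_near: tuple[float, float, np.ndarray, float] | None = None
    for lam in config.lambda_grid:
        x = fit_nnls_voxel(y, A, float(lam))
        ratio = _misfit(A, x, y) / r0
        if lo <= ratio <= hi:
            best_in_window = (float(lam), x, ratio)  # grid increasing: keep largest
        dist = abs(ratio - mid)
        if best_near is None or dist < best_near[0]:
            best_near = (dist, float(lam), x, ratio)
        if ratio > hi and best_in_window is not None:
            break  # ratios only grow beyond the window
    if best_in_window is not None:
        lam, x, ratio = best_in_window
        in_window = True
    else:
        _, lam, x, ratio = best_near
        in_window = False
    return NNLSResult(x, lam, ratio, 0.0, in_window=in_window)


def mwf_from_distribution(
    x: np.ndarray, grid: T2Grid, cutoff: float = 40.0, return_flag: bool = False
):
    """Fraction of distribution mass at T2 below the myelin cutoff."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distribution weights must be nonnegative")
    total = x.sum()
    if total == 0:
        return (0.0, True) if return_flag else 0.0
    value = float(x[grid.points < cutoff].sum() / total)
    return (value, False) if return_flag else value


def fit_nnls_volume(
    volume: EchoVolume,
    config: NNLSConfig | None = None,
    grid: T2Grid | None = None,
) -> NNLSVolumeResult:
    """Independent chi-squared-regularized NNLS fit of every masked voxel."""
    config = config or NNLSConfig()
    grid = grid or build_grid()
    basis = decay_basis(grid, volume.schedule)
    mask = volume.mask
    y_all = volume.data[mask]
    if y_all.size == 0:
        raise ValueError("empty mask")
    norm = normalization_factor(y_all, volume.schedule.times)
    if norm <= 0:
        raise ValueError("volume has no signal at the first echo")
    y_all = y_all / norm

    n_vox = y_all.shape[0]
    weights = np.zeros((n_vox, grid.count))
    lam = np.zeros(n_vox)
    mwf_vals = np.zeros(n_vox)
    for v in range(n_vox):
        res = select_lambda(y_all[v], basis, config)
        res.mwf_value = mwf_from_distribution(res.weights, grid, config.myelin_cutoff)
        weights[v] = res.weights
        lam[v] = res.lambda_selected
        mwf_vals[v] = res.mwf_value

    mwf_map = np.zeros(mask.shape)
    mwf_map[mask] = mwf_vals
    lambda_map = np.zeros(mask.shape)
    lambda_map[mask] = lam
    return NNLSVolumeResult(mwf_map, weights, lambda_map, mask, grid, norm)
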