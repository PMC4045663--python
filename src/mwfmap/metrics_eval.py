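"""Quantitative evaluation of MWF maps: relative MSE against ground truth,
ROI coefficient of variation, group t-tests, and spatial-weight sweeps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .spatial_solver import FitConfig, RegState, fit_spatial
from .volume import EchoVolume

__all__ = [
    "ROIMask",
    "UndefinedMetricError",
    "rmse_mwf",
    "cov_roi",
    "group_ttest",
    "sweep_mu_s",
]


class UndefinedMetricError(ValueError):
    """Metric is undefined for this input (zero truth or zero mean)."""


@dataclass(frozen=True)
class ROIMask:
    """Named region of interest; fewer than 20 voxels triggers a warning."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        n = int(mask.sum())
        if n < 1:
            raise ValueError("ROI mask is empty")
        if n < 20:
            warnings.warn(
                f"ROI {self.name!r} has only {n} voxels; statistics may be "
                "unreliable (>= 20 recommended)",
                stacklevel=2,
            )
        object.__setattr__(self, "mask", mask)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def rmse_mwf(estimated: np.ndarray, truth: np.ndarray,
             mask: np.ndarray | None = None) -> float:
    """Relative MSE: sum (est - true)^2 / sum true^2 over masked voxels."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("estimate and truth shapes differ")
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    e = estimated[mask]
    t = truth[mask]
    denom = float(np.sum(t * t))
    if denom == 0:
        raise UndefinedMetricError("ground-truth MWF is zero everywhere in the mask")
    return float(np.sum((e - t) ** 2) / denom)


def cov_roi(values_map: np.ndarray, roi: ROIMask) -> float:
    """Coefficient of variation (sample sd / mean) inside the ROI."""
    vals = np.asarray(values_map, dtype=float)[roi.mask]
    mean = vals.mean()
    if mean == 0:
        raise UndefinedMetricError(f"ROI {roi.name!r} has zero mean")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(sd / mean)


def group_ttest(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Two-tailed t-test between two groups; paired or unpaired.

    Fully degenerate input (both groups constant with equal means) returns
    (0.0, 1.0) rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        if np.ptp(a - b) == 0:
            return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def sweep_mu_s(
    volume: EchoVolume,
    truth_mwf: np.ndarray,
    mu_s_grid,
    config: FitConfig | None = None,
    lambda_n: float = 0.013,
) -> tuple[pd.DataFrame, float]:
    """Fit the same volume at each spatial weight; report rMSE and the argmin.

    The sweep holds both weights fixed during each fit (rescaling off), so
    the swept value is actually the one in effect, and uses identical data
    across grid points.
    """
    mu_s_grid = np.asarray(list(mu_s_grid), dtype=float)
    if mu_s_grid.size == 0:
        raise ValueError("mu_s grid is empty")
    config = config or FitConfig()
    rows = []
    for mu in mu_s_grid:
        cfg = replace(
            config,
            reg=RegState(lambda_n=lambda_n, mu_s=float(mu)),
            rescale=False,
        )
        result = fit_spatial(volume, cfg)
        rows.append({
            "mu_s": float(mu),
            "rmse": rmse_mwf(result.mwf_map, truth_mwf, volume.mask),
        })
    table = pd.DataFrame(rows)
    best = float(table.loc[table["rmse"].idxmin(), "mu_s"])
    return table, best
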