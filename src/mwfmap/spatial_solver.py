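"""Spatially constrained multi-voxel fitting of the three-pool model.

All masked voxels are fit at once by bounded non-linear least squares on a
single stacked residual

    q(theta) = [ y_v - f(theta_v)  for every voxel v          (fidelity)
                 lambda_N (theta_v - theta_0) / s             (prior)
                 mu_S (theta_p(u) - theta_p(v)) / s_p         (spatial) ],

so that ||q||^2 is the sum of the data misfit, a quadratic pull of every
parameter toward its initial guess, and a first-difference smoothness
penalty over the face-adjacency graph of masked voxels, applied separately
to each of the 8 parameters.  Parameters with different units are made
commensurate by a per-parameter scale vector (heights: 1; times: the grid
span in ms).

The Jacobian of q is never formed in closed form: its sparsity pattern is
precomputed from the voxel graph and handed to a trust-region reflective
solver that estimates it by grouped finite differences and solves the
subproblems iteratively (LSMR).  Between outer iterations the two
regularization weights are rescaled so the penalty-to-fidelity norm ratios
are pulled toward fixed targets gamma_N = gamma_S = 0.1, with a relaxation
step to avoid discontinuous jumps — this removes the need to sweep
regularization values per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares

from .core_model import (
    N_PARAMS,
    PARAM_NAMES,
    ParamBounds,
    T2Grid,
    build_grid,
    decay_basis,
    field_mwf,
    field_signals,
)
from .volume import EchoVolume, normalization_factor

__all__ = [
    "VoxelGraph",
    "RegState",
    "FitConfig",
    "FitResult",
    "build_graph",
    "default_scales",
    "spatial_residual",
    "prior_residual",
    "assemble_residual",
    "jacobian_sparsity",
    "rescale_regularization",
    "fit_spatial",
]

_EPS = 1e-12


@dataclass(frozen=True)
class VoxelGraph:
    """Masked voxels and their face-adjacency edges (6-neighborhood in 3D)."""

    shape: tuple[int, int, int]
    coords: np.ndarray  # (Nv, 3) integer voxel coordinates
    edges: np.ndarray   # (E, 2) indices into coords, u < v, no duplicates

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def build_graph(mask: np.ndarray) -> VoxelGraph:
    """Face-adjacency graph over masked voxels; 2D masks get a singleton z."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        mask = mask[..., None]
    if mask.ndim != 3:
        raise ValueError("mask must be 2D or 3D")
    if not mask.any():
        raise ValueError("mask is empty")
    index = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    index[mask] = np.arange(coords.shape[0])
    edge_list = []
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        both = mask[tuple(lo)] & mask[tuple(hi)]
        if both.any():
            u = index[tuple(lo)][both]
            v = index[tuple(hi)][both]
            edge_list.append(np.column_stack([u, v]))
    if edge_list:
        edges = np.vstack(edge_list)
    else:
        edges = np.zeros((0, 2), dtype=np.int64)
    return VoxelGraph(mask.shape, coords, edges)


def default_scales(grid: T2Grid | None = None) -> np.ndarray:
    """Unit-mixing scales: 1 for heights, the grid span (ms) for times."""
    span = (grid or build_grid()).span
    return np.array([1.0, span, span, 1.0, span, span, 1.0, span])


@dataclass(frozen=True)
class RegState:
    """Regularization weights and the rescaling targets/step."""

    lambda_n: float = 0.013
    mu_s: float = 0.01
    gamma_n: float = 0.1
    gamma_s: float = 0.1
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_n < 0 or self.mu_s < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.gamma_n <= 0 or self.gamma_s <= 0:
            raise ValueError("target ratios must be positive")
        if not (0 < self.eta <= 1):
            raise ValueError("eta must lie in (0, 1]")


def spatial_residual(
    theta: np.ndarray, edges: np.ndarray, mu_s: float, scales: np.ndarray
) -> np.ndarray:
    """First-difference penalty residual, edge-major, 8 entries per edge."""
    theta = np.asarray(theta, dtype=float)
    if edges.shape[0] == 0 or mu_s == 0:
        return np.zeros(edges.shape[0] * N_PARAMS)
    diff = (theta[edges[:, 0]] - theta[edges[:, 1]]) / scales
    return (mu_s * diff).ravel()


def prior_residual(
    theta: np.ndarray, theta0: np.ndarray, lambda_n: float, scales: np.ndarray
) -> np.ndarray:
    """Pull toward the initial-guess prior, voxel-major, 8 entries per voxel."""
    theta = np.asarray(theta, dtype=float)
    if lambda_n == 0:
        return np.zeros(theta.size)
    return (lambda_n * (theta - theta0) / scales).ravel()


def assemble_residual(
    theta: np.ndarray,
    y: np.ndarray,
    basis: np.ndarray,
    echo_times: np.ndarray,
    theta0: np.ndarray,
    edges: np.ndarray,
    lambda_n: float,
    mu_s: float,
    scales: np.ndarray,
    grid: T2Grid,
) -> np.ndarray:
    """Stacked residual [fidelity; prior; spatial]; ||q||^2 is the objective."""
    theta = np.asarray(theta, dtype=float).reshape(-1, N_PARAMS)
    if y.shape[1] != basis.shape[0]:
        raise ValueError("echo count mismatch between data and basis")
    pred = _signals(theta, basis, echo_times, grid)
    fidelity = (y - pred).ravel()
    return np.concatenate([
        fidelity,
        prior_residual(theta, theta0, lambda_n, scales),
        spatial_residual(theta, edges, mu_s, scales),
    ])


def _signals(theta: np.ndarray, basis: np.ndarray, echo_times: np.ndarray,
             grid: T2Grid) -> np.ndarray:
    from .core_model import field_weights
    weights = field_weights(theta, grid)
    csf = theta[:, 6:7] * np.exp(-echo_times / np.maximum(theta[:, 7:8], _EPS))
    return weights @ basis.T + csf


def jacobian_sparsity(graph: VoxelGraph, n_echoes: int) -> sparse.csr_matrix:
    """Boolean Jacobian pattern of the stacked residual.

    Fidelity rows of a voxel touch only that voxel's 8 columns; prior rows
    are a diagonal; each spatial row touches the matching parameter column
    of both edge endpoints.
    """
    nv, ne = graph.n_voxels, graph.n_edges
    n_cols = nv * N_PARAMS
    rows, cols = [], []

    # fidelity block: voxel-major, n_echoes rows per voxel, dense in its 8 cols
    v = np.arange(nv)
    r = (v[:, None, None] * n_echoes + np.arange(n_echoes)[None, :, None])
    c = (v[:, None, None] * N_PARAMS + np.arange(N_PARAMS)[None, None, :])
    rows.append(np.broadcast_to(r, (nv, n_echoes, N_PARAMS)).ravel())
    cols.append(np.broadcast_to(c, (nv, n_echoes, N_PARAMS)).ravel())

    # prior block: identity
    off = nv * n_echoes
    rows.append(off + np.arange(n_cols))
    cols.append(np.arange(n_cols))

    # spatial block: edge-major, one row per (edge, parameter)
    if ne:
        off = nv * n_echoes + n_cols
        e = np.arange(ne)
        p = np.arange(N_PARAMS)
        r = (off + e[:, None] * N_PARAMS + p[None, :]).ravel()
        cu = (graph.edges[:, 0][:, None] * N_PARAMS + p[None, :]).ravel()
        cv = (graph.edges[:, 1][:, None] * N_PARAMS + p[None, :]).ravel()
        rows.extend([r, r])
        cols.extend([cu, cv])

    n_rows = nv * n_echoes + n_cols + ne * N_PARAMS
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    pattern = sparse.coo_matrix(
        (np.ones(rows.size, dtype=bool), (rows, cols)), shape=(n_rows, n_cols)
    )
    return pattern.tocsr()


def rescale_regularization(
    state: RegState,
    fidelity_norm: float,
    prior_norm: float,
    spatial_norm: float,
) -> RegState:
    """Pull penalty-to-fidelity norm ratios toward their gamma targets.

    The fully rescaled weight lambda* = gamma * ||fidelity|| / (||penalty|| /
    lambda) restores the ratio exactly; the update relaxes toward it with
    step eta.  Zero fidelity norm (perfect fit) leaves the state unchanged.
    """
    if fidelity_norm < 0 or prior_norm < 0 or spatial_norm < 0:
        raise ValueError("norms must be nonnegative")
    if fidelity_norm <= _EPS:
        return state

    def _target(gamma: float, weight: float, penalty_norm: float) -> float:
        if weight <= 0:
            return weight
        unweighted = penalty_norm / weight
        if unweighted <= _EPS:
            return weight
        return gamma * fidelity_norm / unweighted

    lam_star = _target(state.gamma_n, state.lambda_n, prior_norm)
    mu_star = _target(state.gamma_s, state.mu_s, spatial_norm)
    return replace(
        state,
        lambda_n=(1 - state.eta) * state.lambda_n + state.eta * lam_star,
        mu_s=(1 - state.eta) * state.mu_s + state.eta * mu_star,
    )


@dataclass
class FitConfig:
    """Knobs of the multi-voxel solve."""

    grid: T2Grid = field(default_factory=build_grid)
    bounds: ParamBounds = field(default_factory=ParamBounds.defaults)
    reg: RegState = field(default_factory=RegState)
    rescale: bool = True
    max_iter: int = 50          # outer iterations
    inner_nfev: int = 8         # trust-region step budget per outer iteration
    rel_tol: float = 1e-6       # relative cost change for convergence
    converge_runs: int = 3      # consecutive small changes required
    scales: np.ndarray | None = None
    x_scale: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 30.0, 20.0, 1.0, 140.0, 100.0, 1.0, 1500.0])
    )


@dataclass
class FitResult:
    """Outcome of a multi-voxel fit."""

    theta: np.ndarray           # (Nv, 8)
    graph: VoxelGraph
    mwf_map: np.ndarray         # 3D, in [0, 1]
    residual_history: list[dict]
    reg_trace: list[dict]
    iterations_run: int
    converged: bool
    norm_factor: float
    grid: T2Grid

    def param_maps(self) -> dict[str, np.ndarray]:
        maps = {}
        shape = self.graph.shape
        idx = tuple(self.graph.coords.T)
        for j, name in enumerate(PARAM_NAMES):
            m = np.zeros(shape)
            m[idx] = self.theta[:, j]
            maps[name] = m
        return maps


def fit_spatial(volume: EchoVolume, config: FitConfig | None = None) -> FitResult:
    """Fit all masked voxels jointly; see the module docstring for the model.

    The solve alternates a budgeted bounded trust-region pass over the full
    stacked residual with a rescaling of the two regularization weights,
    for at most ``max_iter`` outer iterations or until the relative cost
    change stays below ``rel_tol`` for ``converge_runs`` iterations.
    """
    config = config or FitConfig()
    grid = config.grid
    mask = volume.mask
    if not mask.any():
        raise ValueError("mask is empty")
    y_all = volume.data[mask]
    norm = normalization_factor(y_all, volume.schedule.times)
    if norm <= 0:
        raise ValueError("volume has no signal at the first echo")
    y = y_all / norm

    graph = build_graph(mask)
    nv = graph.n_voxels
    basis = decay_basis(grid, volume.schedule)
    echo_times = volume.schedule.times
    theta0 = config.bounds.initial
    scales = config.scales if config.scales is not None else default_scales(grid)
    lb = np.tile(config.bounds.lower, nv)
    ub = np.tile(config.bounds.upper, nv)
    x = np.tile(theta0, nv)
    x_scale = np.tile(config.x_scale, nv)
    pattern = jacobian_sparsity(graph, volume.schedule.count)

    state = config.reg
    history: list[dict] = []
    reg_trace: list[dict] = []
    converged = False
    small_changes = 0
    prev_cost = None
    iterations = 0

    for it in range(config.max_iter):
        lam, mu = state.lambda_n, state.mu_s

        def fun(xf, _lam=lam, _mu=mu):
            return assemble_residual(
                xf, y, basis, echo_times, theta0, graph.edges,
                _lam, _mu, scales, grid,
            )

        r_start = fun(x)
        cost_start = float(r_start @ r_start)
        sol = least_squares(
            fun, x, jac="2-point", bounds=(lb, ub), method="trf",
            tr_solver="lsmr", jac_sparsity=pattern, x_scale=x_scale,
            max_nfev=config.inner_nfev, ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
        x = sol.x
        theta = x.reshape(nv, N_PARAMS)

        pred = _signals(theta, basis, echo_times, grid)
        fid = float(np.linalg.norm(y - pred))
        pri = float(np.linalg.norm(prior_residual(theta, theta0, lam, scales)))
        spa = float(np.linalg.norm(spatial_residual(theta, graph.edges, mu, scales)))
        cost_end = fid * fid + pri * pri + spa * spa
        history.append({
            "iteration": it,
            "cost_start": cost_start,
            "cost_end": cost_end,
            "fidelity_norm": fid,
            "prior_norm": pri,
            "spatial_norm": spa,
        })
        reg_trace.append({"iteration": it, "lambda_n": lam, "mu_s": mu})
        iterations = it + 1

        if prev_cost is not None:
            rel = abs(cost_end - prev_cost) / max(prev_cost, _EPS)
            small_changes = small_changes + 1 if rel < config.rel_tol else 0
            if small_changes >= config.converge_runs:
                converged = True
                break
        prev_cost = cost_end

        if config.rescale:
            state = rescale_regularization(state, fid, pri, spa)

    theta = x.reshape(nv, N_PARAMS)
    mwf_map = np.zeros(graph.shape)
    mwf_map[tuple(graph.coords.T)] = np.clip(field_mwf(theta), 0.0, 1.0)
    return FitResult(
        theta=theta,
        graph=graph,
        mwf_map=mwf_map,
        residual_history=history,
        reg_trace=reg_trace,
        iterations_run=iterations,
        converged=converged,
        norm_factor=norm,
        grid=grid,
    )
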