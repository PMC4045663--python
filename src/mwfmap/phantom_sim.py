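"""Synthetic multi-echo data: brain-like tissue phantom, doped-water tubes,
peak-shape families, and the first-echo-referenced Gaussian noise model.

The brain phantom emulates probabilistic tissue maps (WM / GM / CSF summing
to one inside a brain mask, with smoothed boundaries producing partial
volume voxels) arranged as concentric shells: a CSF core, a WM annulus and
a GM rim.  Each pure tissue has a fixed three-pool T2 signature — myelin
and IE Gaussians centered at 25 ms and 100 ms, CSF at 1800 ms — and a pure
myelin fraction of 14.5% (WM), 4.5% (GM) and 0% (CSF).  A voxel's T2
distribution is the tissue-probability-weighted mixture of the pure
signatures, which is again an exact instance of the three-pool model, so
ground-truth parameter vectors accompany every simulation.

Noise is additive white Gaussian with standard deviation equal to the mean
first-echo signal divided by the requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_model import (
    EchoSchedule,
    T2Grid,
    build_grid,
    field_signals,
)
from .volume import EchoVolume

__all__ = [
    "MYELIN_T2", "IE_T2", "CSF_T2", "MYELIN_SIGMA", "IE_SIGMA",
    "WM_MWF", "GM_MWF",
    "Lesion", "PhantomSpec", "TissueMaps", "NoiseModel", "Tube", "TubeSpec",
    "GroundTruth",
    "make_tissue_maps", "true_theta_field", "true_mwf_map",
    "simulate_multiecho", "simulate_tubes",
    "make_peak_family", "decay_curve",
]

# Pure-tissue T2 signature: pool centers (ms) and pure myelin fractions.
MYELIN_T2 = 25.0
IE_T2 = 100.0
CSF_T2 = 1800.0
WM_MWF = 0.145
GM_MWF = 0.045
# Pool widths are not dictated by the recipe; these keep the pools well
# separated yet dispersed.
MYELIN_SIGMA = 5.0
IE_SIGMA = 20.0


@dataclass(frozen=True)
class Lesion:
    """Spherical demyelinating lesion: multiplier scales the WM myelin pool."""

    center: tuple[int, ...]
    radius: float
    multiplier: float  # in [0, 1]; 0 = complete myelin loss

    def __post_init__(self) -> None:
        if not 0 <= self.multiplier <= 1:
            raise ValueError("lesion multiplier must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Tissue T2 signature and lesion layout of the brain phantom."""

    myelin_t2: float = MYELIN_T2
    ie_t2: float = IE_T2
    csf_t2: float = CSF_T2
    myelin_sigma: float = MYELIN_SIGMA
    ie_sigma: float = IE_SIGMA
    wm_mwf: float = WM_MWF
    gm_mwf: float = GM_MWF
    lesions: tuple[Lesion, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.wm_mwf <= 1 and 0 <= self.gm_mwf <= 1):
            raise ValueError("pure-tissue myelin fractions must lie in [0, 1]")


@dataclass
class TissueMaps:
    """Probabilistic WM/GM/CSF maps summing to 1 inside the brain mask."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise at a first-echo-referenced SNR; None = noiseless."""

    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class GroundTruth:
    mwf: np.ndarray        # 3D fraction map
    theta: np.ndarray      # (x, y, z, 8) true parameter field
    maps: TissueMaps | None = None


def make_tissue_maps(shape, seed: int = 0, smooth: float = 1.0) -> TissueMaps:
    """Procedural concentric brain phantom with partial-volume boundaries.

    A CSF core, WM annulus and GM rim are laid out radially (with a mild
    seeded lumpy perturbation of the radius so boundaries are not perfect
    circles), then each indicator is smoothed and renormalized so the three
    maps sum to 1 inside the mask.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) == 2:
        shape = shape + (1,)
    if len(shape) != 3:
        raise ValueError("shape must be 2D or 3D")
    if min(shape[0], shape[1]) < 8:
        raise ValueError("in-plane dimensions must be at least 8")

    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) / (min(nx, ny) / 2.0 - 0.5)

    rng = np.random.default_rng(seed)
    lump = gaussian_filter(rng.standard_normal((nx, ny)), sigma=max(nx, ny) / 8.0)
    lump /= max(np.abs(lump).max(), 1e-12)
    r_eff = r + 0.04 * lump
    r_eff = np.repeat(r_eff[:, :, None], nz, axis=2)

    csf = (r_eff < 0.30).astype(float)
    wm = ((r_eff >= 0.30) & (r_eff < 0.65)).astype(float)
    gm = ((r_eff >= 0.65) & (r_eff < 0.95)).astype(float)
    mask = (csf + wm + gm) > 0.5

    sig = (smooth, smooth, 0) if nz == 1 else (smooth, smooth, smooth)
    csf = gaussian_filter(csf, sig)
    wm = gaussian_filter(wm, sig)
    gm = gaussian_filter(gm, sig)

    total = csf + wm + gm
    inside = mask & (total > 1e-6)
    for m in (csf, wm, gm):
        m[inside] /= total[inside]
        m[~inside] = 0.0
    mask = inside
    return TissueMaps(wm=wm, gm=gm, csf=csf, mask=mask)


def _lesion_multiplier(shape, lesions) -> np.ndarray:
    mult = np.ones(shape)
    if not lesions:
        return mult
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for les in lesions:
        center = tuple(les.center) + (0,) * (3 - len(les.center))
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        mult[d2 <= les.radius ** 2] = les.multiplier
    return mult


def true_theta_field(maps: TissueMaps, spec: PhantomSpec | None = None) -> np.ndarray:
    """Per-voxel true parameter vectors (x, y, z, 8).

    The tissue mixture of three-pool signatures with shared pool locations
    collapses to a single three-pool voxel: myelin height is the
    tissue-weighted myelin fraction, IE height the complement within
    parenchyma, CSF height the CSF probability.
    """
    spec = spec or PhantomSpec()
    shape = maps.wm.shape
    mult = _lesion_multiplier(shape, spec.lesions)
    c_my = maps.wm * spec.wm_mwf * mult + maps.gm * spec.gm_mwf
    c_ie = maps.wm * (1 - spec.wm_mwf * mult) + maps.gm * (1 - spec.gm_mwf)
    theta = np.zeros(shape + (8,))
    theta[..., 0] = c_my
    theta[..., 1] = spec.myelin_t2
    theta[..., 2] = spec.myelin_sigma
    theta[..., 3] = c_ie
    theta[..., 4] = spec.ie_t2
    theta[..., 5] = spec.ie_sigma
    theta[..., 6] = maps.csf
    theta[..., 7] = spec.csf_t2
    theta[~maps.mask] = 0.0
    theta[..., 1][~maps.mask] = spec.myelin_t2
    theta[..., 2][~maps.mask] = spec.myelin_sigma
    theta[..., 4][~maps.mask] = spec.ie_t2
    theta[..., 5][~maps.mask] = spec.ie_sigma
    theta[..., 7][~maps.mask] = spec.csf_t2
    return theta


def true_mwf_map(maps: TissueMaps, spec: PhantomSpec | None = None) -> np.ndarray:
    """Ground-truth MWF: wm_mwf * WM + gm_mwf * GM (lesions scale the WM term)."""
    spec = spec or PhantomSpec()
    mult = _lesion_multiplier(maps.wm.shape, spec.lesions)
    out = maps.wm * spec.wm_mwf * mult + maps.gm * spec.gm_mwf
    out[~maps.mask] = 0.0
    return out


def simulate_multiecho(
    maps: TissueMaps,
    spec: PhantomSpec | None = None,
    schedule: EchoSchedule | None = None,
    noise: NoiseModel | None = None,
    grid: T2Grid | None = None,
) -> tuple[EchoVolume, GroundTruth]:
    """Forward-simulate multi-echo data from the tissue phantom.

    Noise standard deviation is the mean first-echo signal inside the mask
    divided by the SNR; it is added everywhere (background included).
    """
    from .core_model import mese_schedule

    spec = spec or PhantomSpec()
    schedule = schedule or mese_schedule()
    noise = noise or NoiseModel()
    grid = grid or build_grid()

    theta = true_theta_field(maps, spec)
    signals = field_signals(theta, grid, schedule)
    if noise.snr is not None:
        rng = np.random.default_rng(noise.seed)
        sigma = float(signals[maps.mask, 0].mean()) / noise.snr
        signals = signals + rng.normal(0.0, sigma, size=signals.shape)
    volume = EchoVolume(data=signals, schedule=schedule, mask=maps.mask)
    truth = GroundTruth(mwf=true_mwf_map(maps, spec), theta=theta, maps=maps)
    return volume, truth


@dataclass(frozen=True)
class Tube:
    """A doped-water tube: single-exponential decay at one T2."""

    t2: float
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.t2 <= 0:
            raise ValueError("tube T2 must be positive")


@dataclass(frozen=True)
class TubeSpec:
    """Row of tubes; each occupies a ``tube_size``-square block."""

    tubes: tuple[Tube, ...]
    tube_size: int = 3
    gap: int = 1
    myelin_cutoff: float = 40.0  # ms: tubes below count as "all myelin"


def simulate_tubes(
    spec: TubeSpec,
    schedule: EchoSchedule | None = None,
    noise: NoiseModel | None = None,
) -> tuple[EchoVolume, GroundTruth, np.ndarray]:
    """Single-pool tube phantom; returns volume, truth and a tube label map.

    True MWF is 1 for tubes with T2 below the myelin cutoff, else 0 — the
    single pool either is or is not "myelin-like".
    """
    from .core_model import mese_schedule

    schedule = schedule or mese_schedule()
    noise = noise or NoiseModel()
    n = len(spec.tubes)
    if n == 0:
        raise ValueError("tube spec is empty")
    stride = spec.tube_size + spec.gap
    nx = n * stride + spec.gap
    ny = spec.tube_size + 2 * spec.gap
    shape = (nx, ny, 1)

    data = np.zeros(shape + (schedule.count,))
    mask = np.zeros(shape, dtype=bool)
    labels = -np.ones(shape, dtype=int)
    truth = np.zeros(shape)
    decay = np.exp(-schedule.times[None, :] / np.array([t.t2 for t in spec.tubes])[:, None])
    for i, tube in enumerate(spec.tubes):
        x0 = spec.gap + i * stride
        sl = (slice(x0, x0 + spec.tube_size),
              slice(spec.gap, spec.gap + spec.tube_size), slice(None))
        data[sl] = tube.density * decay[i]
        mask[sl] = True
        labels[sl] = i
        truth[sl] = 1.0 if tube.t2 < spec.myelin_cutoff else 0.0
    if noise.snr is not None:
        rng = np.random.default_rng(noise.seed)
        sigma = float(data[mask, 0].mean()) / noise.snr
        data = data + rng.normal(0.0, sigma, size=data.shape)
    volume = EchoVolume(data=data, schedule=schedule, mask=mask)
    theta = np.zeros(shape + (8,))
    return volume, GroundTruth(mwf=truth, theta=theta), labels


# ---------------------------------------------------------------------------
# Peak-shape families: moment-matched Gaussian / log-Gaussian / Laplacian
# peaks, used to show that peak shape is invisible to the decay curve.

def make_peak_family(
    mean: float,
    variance: float,
    shapes: tuple[str, ...] = ("gaussian", "log_gaussian", "laplacian"),
    lattice: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Unit-sum discrete peaks on a fine tau lattice, matched in mean/variance."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    if mean <= 0:
        raise ValueError("mean must be positive")
    tau = lattice if lattice is not None else np.linspace(1.0, 300.0, 3000)
    out: dict[str, np.ndarray] = {}
    for shape in shapes:
        if shape == "gaussian":
            w = np.exp(-0.5 * (tau - mean) ** 2 / variance)
        elif shape == "log_gaussian":
            s2 = np.log1p(variance / mean**2)
            mu = np.log(mean) - 0.5 * s2
            w = np.exp(-0.5 * (np.log(tau) - mu) ** 2 / s2) / tau
        elif shape == "laplacian":
            b = np.sqrt(variance / 2.0)
            w = np.exp(-np.abs(tau - mean) / b)
        else:
            raise ValueError(f"unknown peak shape {shape!r}")
        total = w.sum()
        if total <= 0:
            raise ValueError(f"{shape} peak has no mass on the lattice")
        out[shape] = w / total
    return out


def decay_curve(lattice: np.ndarray, weights: np.ndarray,
                schedule: EchoSchedule) -> np.ndarray:
    """Multi-exponential decay of a discrete distribution at the schedule."""
    return np.exp(-schedule.times[:, None] / lattice[None, :]) @ weights
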