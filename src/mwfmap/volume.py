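"""The in-memory multi-echo volume container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import EchoSchedule

__all__ = ["EchoVolume", "normalization_factor"]


def normalization_factor(signals: np.ndarray, times: np.ndarray) -> float:
    """Volume normalization amplitude for height-bounded fitting.

    Pool heights are volume fractions bounded by 1, which presumes the data
    are scaled so the (unmeasured) TE = 0 intensity of a voxel is about 1.
    The mean first-echo intensity alone underestimates that amplitude —
    already at the first echo a fast-decaying voxel has lost a significant
    share of its signal — so the mean decay over the first two echoes is
    extrapolated mono-exponentially back to TE = 0:

        A0 = s1 * (s1 / s2) ** (t1 / (t2 - t1)).

    The ratio is clipped below at 1 so noise cannot produce a growing
    "decay".  Falls back to the plain first-echo mean when the second echo
    carries no signal.
    """
    signals = np.asarray(signals, dtype=float)
    s1 = float(signals[:, 0].mean())
    s2 = float(signals[:, 1].mean())
    if s1 <= 0:
        return s1
    if s2 <= 0:
        return s1
    t1, t2 = float(times[0]), float(times[1])
    ratio = max(s1 / s2, 1.0)
    return s1 * ratio ** (t1 / (t2 - t1))


@dataclass
class EchoVolume:
    """4D multi-echo magnitude image (x, y, z, echo) with metadata.

    Intensities are in arbitrary scanner units; fitting routines normalize
    by the mean first-echo intensity inside the mask and record the factor.
    """

    data: np.ndarray
    schedule: EchoSchedule
    mask: np.ndarray
    norm_factor: float = 1.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"echo volume must be 4D (x, y, z, echo); got {data.ndim}D")
        if data.shape[-1] != self.schedule.count:
            raise ValueError(
                f"echo dimension {data.shape[-1]} does not match "
                f"{self.schedule.count} echo times"
            )
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))
            raise ValueError(f"non-finite intensities at indices {bad[:5].tolist()}...")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match spatial dims {data.shape[:3]}"
            )
        self.data = data
        self.mask = mask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-1]
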