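"""Trajectory container shared by every analysis stage.

Canonical units throughout the package: coordinates in nanometres, time in
seconds, frame indices 0-based, frame spacing uniform at 1/framerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Trajectory"]

_TIME_TOL = 1e-9  # s; allowed deviation from uniform frame spacing


@dataclass
class Trajectory:
    """Time-ordered sequence of 2D or 3D localizations.

    Parameters
    ----------
    position : (n, d) array, nm
        Lateral (x, y) or volumetric (x, y, z) coordinates per frame.
    framerate : float, frames/s
        Acquisition rate; frame j is at time ``frame_index[j] / framerate``.
    frame_index : (n,) int array, optional
        Defaults to ``arange(n)``.
    sigma_xy : float or (n,) array, nm
        Per-axis lateral localization precision (std), scalar or per point.
    sigma_z : float or (n,) array, nm, optional
        Axial precision for 3D trajectories.
    metadata : dict
        Free-form provenance record (model parameters, seeds, ...).
    """

    position: np.ndarray
    framerate: float
    frame_index: np.ndarray | None = None
    sigma_xy: float | np.ndarray = 0.0
    sigma_z: float | np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] not in (2, 3):
            raise ValueError(
                f"position must be (n, 2) or (n, 3); got {self.position.shape}"
            )
        if not np.isfinite(self.position).all():
            raise ValueError("position contains non-finite values")
        if self.framerate <= 0:
            raise ValueError("framerate must be positive")
        n = len(self.position)
        if self.frame_index is None:
            self.frame_index = np.arange(n)
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
            if self.frame_index.shape != (n,):
                raise ValueError("frame_index length mismatch")
            if np.any(np.diff(self.frame_index) <= 0):
                raise ValueError("frame_index must be strictly increasing")
        if np.any(np.asarray(self.sigma_xy) < 0):
            raise ValueError("sigma_xy must be >= 0")
        if self.sigma_z is not None and np.any(np.asarray(self.sigma_z) < 0):
            raise ValueError("sigma_z must be >= 0")
        # uniform spacing check (the analyses assume it)
        t = self.time
        if n >= 2:
            dt = np.diff(t)
            if np.any(np.abs(dt - 1.0 / self.framerate) > _TIME_TOL):
                raise ValueError("frame times deviate from uniform 1/framerate spacing")

    @property
    def n_frames(self) -> int:
        return len(self.position)

    @property
    def ndim(self) -> int:
        """Spatial dimensionality (2 or 3)."""
        return self.position.shape[1]

    @property
    def time(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.frame_index / self.framerate

    @property
    def xy(self) -> np.ndarray:
        """Lateral coordinates (n, 2), nm."""
        return self.position[:, :2]

    @property
    def z(self) -> np.ndarray | None:
        """Axial coordinate (n,), nm, or None for 2D trajectories."""
        return self.position[:, 2] if self.ndim == 3 else None

    def sigma_xy_array(self) -> np.ndarray:
        """Per-point lateral precision, broadcast to (n,)."""
        return np.broadcast_to(np.asarray(self.sigma_xy, dtype=float), (self.n_frames,))
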