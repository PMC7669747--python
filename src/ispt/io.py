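"""Trajectory file I/O and analysis configuration.

Trajectory files are delimited text with a header row; required columns
``frame, x_nm, y_nm``, optional ``t_s, z_nm, sigma_xy_nm, sigma_z_nm``.
The framerate comes from a ``# framerate_hz=<value>`` comment line or is
inferred from the spacing of ``t_s``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = ["read_trajectory", "write_trajectory", "AnalysisConfig"]

logger = logging.getLogger("ispt")

_REQUIRED = ("frame", "x_nm", "y_nm")
_OPTIONAL = ("t_s", "z_nm", "sigma_xy_nm", "sigma_z_nm")


def read_trajectory(path, framerate: float | None = None) -> Trajectory:
    """Read and validate a trajectory table.

    Rows are sorted by frame (with a warning if they arrived shuffled);
    duplicate frame indices and non-uniform time spacing are errors.
    """
    path = Path(path)
    header_fps = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "framerate_hz=" in line:
                header_fps = float(line.split("framerate_hz=")[1].strip())
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    unknown = [c for c in df.columns if c not in _REQUIRED + _OPTIONAL]
    if unknown:
        raise ValueError(f"unrecognized column(s): {', '.join(unknown)}")
    if not df["frame"].is_monotonic_increasing:
        warnings.warn("rows out of frame order; sorting")
        logger.warning("input rows out of frame order; sorted by frame")
        df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    if df["frame"].duplicated().any():
        raise ValueError("duplicate frame index in trajectory file")

    fps = framerate or header_fps
    if "t_s" in df.columns and len(df) >= 2:
        dt = np.diff(df["t_s"].to_numpy())
        dframe = np.diff(df["frame"].to_numpy())
        per_frame = dt / dframe
        mean_dt = per_frame.mean()
        if np.any(np.abs(per_frame - mean_dt) > 1e-6 * mean_dt):
            raise ValueError("non-uniform time spacing; the analyses assume "
                             "uniform frames")
        if fps is None:
            fps = 1.0 / mean_dt
    if fps is None:
        raise ValueError("framerate unknown: supply it, add a "
                         "'# framerate_hz=' header, or include a t_s column")

    cols = ["x_nm", "y_nm"] + (["z_nm"] if "z_nm" in df.columns else [])
    pos = df[cols].to_numpy(dtype=float)
    sigma_xy = df["sigma_xy_nm"].to_numpy(dtype=float) if "sigma_xy_nm" in df else 0.0
    sigma_z = df["sigma_z_nm"].to_numpy(dtype=float) if "sigma_z_nm" in df else None
    if sigma_z is not None and pos.shape[1] != 3:
        sigma_z = None
    return Trajectory(position=pos, framerate=float(fps),
                      frame_index=df["frame"].to_numpy(dtype=int),
                      sigma_xy=sigma_xy, sigma_z=sigma_z,
                      metadata={"source": str(path)})


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory in the canonical CSV dialect (round-trips
    bit-identically in values through :func:`read_trajectory`)."""
    path = Path(path)
    cols = {"frame": traj.frame_index, "t_s": traj.time,
            "x_nm": traj.position[:, 0], "y_nm": traj.position[:, 1]}
    if traj.ndim == 3:
        cols["z_nm"] = traj.position[:, 2]
    s = np.asarray(traj.sigma_xy)
    if s.ndim or float(s) != 0.0:
        cols["sigma_xy_nm"] = traj.sigma_xy_array()
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# framerate_hz={traj.framerate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # exact round trip


@dataclass
class AnalysisConfig:
    """Parameters of the end-to-end trajectory analysis pipeline."""

    window: int = 1000  # frames, rolling-window length
    stride: int = 100  # frames between window starts
    tau: int = 5  # frames, directional-correlation step separation
    sigma_xy: float | None = None  # nm; None = take from the trajectory
    bin_size: float = 4.0  # nm, ATOM bin
    residence_threshold: float = 1e-3  # s, patch ("sticky") threshold
    min_patch_bins: int = 3
    smoothing_window: int = 50  # frames, step extraction
    prominence: float = 2.0  # nm, step extraction
    max_lag_fraction: float = 0.25  # whole-trajectory MSD
    seed: int = 0
    output_directory: str = "."

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError("window must be >= 4 frames")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.tau < 1 or 2 * self.tau >= self.window:
            raise ValueError("need 1 <= tau and 2*tau < window")
        if self.bin_size <= 0 or self.residence_threshold <= 0:
            raise ValueError("bin_size and residence_threshold must be > 0")
        if not (0 < self.max_lag_fraction <= 0.25):
            raise ValueError("max_lag_fraction must lie in (0, 0.25]")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path, section: str = "analyze") -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc.get(section, doc))
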