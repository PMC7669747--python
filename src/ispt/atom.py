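"""Accumulated total occupancy maps (ATOM) and extended-residency patches.

An ATOM is a 2D histogram of trajectory points over square bins (default
4 × 4 nm²); counts × frame exposure time give the residence time per bin.
Patches of extra-ordinary occupancy — candidate confining nanodomains —
are detected by thresholding residence time (default 1 ms), labelling
8-connected components, and summarizing each by its area and equivalent
circular diameter d_eq = 2·sqrt(area/π).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .trajectory import Trajectory

__all__ = ["ATOMMap", "Patch", "compute_atom", "detect_patches"]

DEFAULT_BIN_SIZE = 4.0  # nm
DEFAULT_RESIDENCE_THRESHOLD = 1e-3  # s ("sticky": residency beyond 1 ms)


@dataclass
class ATOMMap:
    """2D occupancy histogram with bin geometry and exposure time."""

    origin: np.ndarray  # nm, lower-left corner of bin (0, 0)
    bin_size: float  # nm
    counts: np.ndarray  # (ny, nx) int, row = y bin
    exposure_time: float  # s per frame

    @property
    def residence_time(self) -> np.ndarray:
        """Seconds spent per bin (counts × exposure time)."""
        return self.counts * self.exposure_time

    @property
    def occupied_bins(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def total_points(self) -> int:
        return int(self.counts.sum())


@dataclass
class Patch:
    """One 8-connected component of bins above the residence threshold."""

    bin_coordinates: np.ndarray  # (k, 2) int (iy, ix)
    area: float  # nm² = n_bins · b²
    equivalent_circular_diameter: float  # nm = 2·sqrt(area/π)
    total_residence: float  # s
    centroid: np.ndarray  # nm (x, y)

    @property
    def n_bins(self) -> int:
        return len(self.bin_coordinates)


def compute_atom(traj: Trajectory, bin_size: float = DEFAULT_BIN_SIZE,
                 origin: np.ndarray | None = None) -> ATOMMap:
    """Bin the lateral trajectory into half-open square bins
    [origin + k·b, origin + (k+1)·b) and count occupancy.

    Default origin snaps to the bin grid containing the data's minimum so
    every point falls inside the map.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    xy = traj.xy
    if origin is None:
        origin = np.floor(xy.min(axis=0) / bin_size) * bin_size
    origin = np.asarray(origin, dtype=float)
    idx = np.floor((xy - origin) / bin_size).astype(int)
    if idx.min() < 0:
        raise ValueError("origin lies above some trajectory points")
    nx, ny = idx[:, 0].max() + 1, idx[:, 1].max() + 1
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (idx[:, 1], idx[:, 0]), 1)
    return ATOMMap(origin=origin, bin_size=bin_size, counts=counts,
                   exposure_time=1.0 / traj.framerate)


def detect_patches(atom: ATOMMap,
                   residence_threshold: float = DEFAULT_RESIDENCE_THRESHOLD,
                   min_bins: int = 3) -> list[Patch]:
    """Extended-residency patches: bins at residence ≥ threshold, labelled
    with 8-connectivity, components below ``min_bins`` discarded.

    Returned sorted by total residence, longest first.  An empty list is a
    valid result.
    """
    if residence_threshold <= 0:
        raise ValueError("residence_threshold must be > 0")
    above = atom.residence_time >= residence_threshold
    labels, n_lab = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    patches: list[Patch] = []
    b = atom.bin_size
    for lab in range(1, n_lab + 1):
        iy, ix = np.nonzero(labels == lab)
        if len(iy) < min_bins:
            continue
        area = len(iy) * b * b
        residence = float(atom.residence_time[iy, ix].sum())
        # bin-centre centroid weighted by counts
        w = atom.counts[iy, ix].astype(float)
        cx = float(np.average(atom.origin[0] + (ix + 0.5) * b, weights=w))
        cy = float(np.average(atom.origin[1] + (iy + 0.5) * b, weights=w))
        patches.append(Patch(
            bin_coordinates=np.column_stack([iy, ix]),
            area=area,
            equivalent_circular_diameter=2.0 * np.sqrt(area / np.pi),
            total_residence=residence,
            centroid=np.array([cx, cy]),
        ))
    patches.sort(key=lambda p: p.total_residence, reverse=True)
    return patches
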