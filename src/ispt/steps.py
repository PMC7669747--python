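"""Directed-transport analysis: projection of a trajectory segment onto its
global travel axis, plateau/step extraction, step-size histograms, and
track-width estimation.

The travel axis is the principal eigenvector of the segment's lateral
position covariance (robust to back-and-forth legs), sign-oriented along
the net displacement.  Steps are extracted from the smoothed on-axis
coordinate with a peak finder applied to its windowed difference; plateau
levels are medians between transitions and step sizes δ their consecutive
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .trajectory import Trajectory

__all__ = ["ProjectedWalk", "StepAnalysis", "project_onto_axis",
           "extract_steps", "track_width", "segment_by_direction_change"]

DEFAULT_SMOOTHING = 50  # frames
DEFAULT_PROMINENCE = 2.0  # nm


@dataclass
class ProjectedWalk:
    """Signed on-axis and perpendicular coordinates of one segment."""

    axis: np.ndarray  # unit 2-vector
    axis_origin: np.ndarray  # nm, segment centroid
    s: np.ndarray  # nm, signed on-axis coordinate
    perp: np.ndarray  # nm, signed perpendicular residual
    segment: tuple[int, int]  # [start, end) frames
    framerate: float
    isotropic_warning: bool = False  # eigenvalue ratio < 2


@dataclass
class StepAnalysis:
    """Plateaus and step sizes extracted from a projected walk."""

    transition_frames: np.ndarray  # frame offsets within the segment
    plateau_levels: np.ndarray  # nm
    step_sizes: np.ndarray  # nm, signed differences of plateau levels
    smoothing_window: int
    prominence: float
    histogram_edges: np.ndarray  # nm, 1 nm bins over |δ|
    histogram_counts: np.ndarray


def project_onto_axis(traj: Trajectory, start: int = 0,
                      end: int | None = None,
                      axis_mode: str = "pca") -> ProjectedWalk:
    """Project the lateral segment [start, end) onto its travel axis.

    ``axis_mode='pca'`` (default) uses the covariance principal axis;
    ``'endpoint'`` uses the normalized first-to-last displacement.
    """
    end = traj.n_frames if end is None else end
    if end - start < 10:
        raise ValueError("segment must span at least 10 frames")
    xy = traj.xy[start:end]
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    net = xy[-1] - xy[0]
    iso_warn = False
    if axis_mode == "endpoint":
        if np.linalg.norm(net) == 0:
            raise ValueError("degenerate segment: zero net displacement")
        axis = net / np.linalg.norm(net)
    elif axis_mode == "pca":
        cov = centered.T @ centered / len(xy)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] <= 0:
            raise ValueError("degenerate segment: all points identical")
        axis = evecs[:, -1]
        if evals[0] > 0 and evals[-1] / evals[0] < 2.0:
            iso_warn = True
            warnings.warn("segment is nearly isotropic; travel axis is "
                          "poorly defined (eigenvalue ratio < 2)")
    else:
        raise ValueError("axis_mode must be 'pca' or 'endpoint'")
    # orient along the net displacement
    if axis @ net < 0:
        axis = -axis
    perp_axis = np.array([-axis[1], axis[0]])
    return ProjectedWalk(axis=axis, axis_origin=centroid,
                         s=centered @ axis, perp=centered @ perp_axis,
                         segment=(start, end), framerate=traj.framerate,
                         isotropic_warning=iso_warn)


def extract_steps(walk: ProjectedWalk,
                  smoothing_window: int = DEFAULT_SMOOTHING,
                  prominence: float = DEFAULT_PROMINENCE) -> StepAnalysis:
    """Extract plateaus and step sizes from the on-axis coordinate.

    s(t) is smoothed with a centered moving average; transitions are the
    prominence-thresholded extrema of the difference of the smoothed signal
    taken across the smoothing window (a step of height δ appears there as
    a bump of height δ).  Plateau levels are medians of s between
    transitions, margins near each transition excluded; step sizes are
    their consecutive differences.  A walk with no prominent transition
    yields a single plateau and an empty step list.
    """
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    s = walk.s
    n = len(s)
    smooth = uniform_filter1d(s, size=smoothing_window, mode="nearest")
    h = max(smoothing_window // 2, 1)
    # windowed forward difference: g[k] = smooth[k+h] - smooth[k-h]
    g = np.empty(n)
    g[:] = 0.0
    g[h:n - h] = smooth[2 * h:] - smooth[:n - 2 * h]
    up, _ = find_peaks(g, prominence=prominence, height=prominence)
    down, _ = find_peaks(-g, prominence=prominence, height=prominence)
    transitions = np.sort(np.concatenate([up, down]))
    # merge transitions closer than the smoothing window (one physical step
    # can produce split extrema under noise)
    if len(transitions) > 1:
        keep = [transitions[0]]
        for t in transitions[1:]:
            if t - keep[-1] >= smoothing_window:
                keep.append(t)
        transitions = np.asarray(keep)
    bounds = np.concatenate([[0], transitions, [n]])
    levels = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo = a + (h if a > 0 else 0)
        hi = b - (h if b < n else 0)
        if hi <= lo:  # plateau shorter than the margins; use all of it
            lo, hi = a, b
        levels.append(np.median(s[lo:hi]))
    levels = np.asarray(levels)
    sizes = np.diff(levels)
    abs_sizes = np.abs(sizes)
    if len(abs_sizes):
        top = np.ceil(abs_sizes.max()) + 1
    else:
        top = 1
    edges = np.arange(0.0, top + 1.0)
    counts, _ = np.histogram(abs_sizes, bins=edges)
    return StepAnalysis(transition_frames=transitions, plateau_levels=levels,
                        step_sizes=sizes, smoothing_window=smoothing_window,
                        prominence=prominence, histogram_edges=edges,
                        histogram_counts=counts)


def segment_by_direction_change(traj: Trajectory, window: int = 500,
                                angle_threshold: float = np.pi / 4,
                                min_segment: int = 1000) -> list[tuple[int, int]]:
    """Best-effort split of a multi-leg directed trajectory into legs.

    The local travel direction is the window-averaged displacement; a
    change point is declared where it rotates by more than
    ``angle_threshold`` (default 45°) relative to the current leg's
    direction.  Returns [start, end) frame ranges.  Curated segment bounds
    are preferred for publication-grade analysis; this helper is a
    convenience and its output should be inspected.
    """
    xy = traj.xy
    n = len(xy)
    if n < 2 * min_segment:
        return [(0, n)]
    disp = xy[window:] - xy[:-window]
    angles = np.arctan2(disp[:, 1], disp[:, 0])
    cuts = [0]
    ref = angles[0]
    j = min_segment
    while j < len(angles):
        d = np.angle(np.exp(1j * (angles[j] - ref)))
        if abs(d) > angle_threshold:
            cut = j + window // 2
            if cut - cuts[-1] >= min_segment:
                cuts.append(cut)
                ref = angles[min(j + min_segment, len(angles) - 1)]
                j += min_segment
                continue
        j += 1
    cuts.append(n)
    return [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b - a >= 10]


def track_width(walk: ProjectedWalk) -> float:
    """Track width as 4 × std of the perpendicular residual (≈95% envelope
    of a Gaussian spread; the convention is recorded with every output)."""
    if len(walk.perp) < 10:
        raise ValueError("need at least 10 points")
    return float(4.0 * np.std(walk.perp))
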