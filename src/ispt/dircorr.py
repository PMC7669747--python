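"""Directional-correlation analysis.

For a step separation τ (in frames, default 5) define two consecutive
lateral steps Δr⃗₁ = r(t+τ) − r(t) and Δr⃗₂ = r(t+2τ) − r(t+τ).  The
directional correlation C_i of a window is the mean cosine of the angle
between the two steps over every start frame in the window: 0 for a
memoryless walk, negative under knock-back from obstacles, positive under
persistent/directed motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msd import WindowSeries, window_grid
from .trajectory import Trajectory

__all__ = ["StepPair", "step_vectors", "rolling_directional_correlation",
           "DEFAULT_TAU"]

DEFAULT_TAU = 5  # frames; step separation for the correlation statistic


@dataclass
class StepPair:
    """One pair of consecutive τ-frame steps and their angle cosine."""

    start_frame: int
    step1: np.ndarray  # nm, lateral
    step2: np.ndarray  # nm, lateral
    cosine: float  # NaN if either step has zero length


def _pair_arrays(xy: np.ndarray, tau: int, start: int, end: int,
                 overlapping: bool = True
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized step pairs: all start frames t with t+2τ < end
    (or every 2τ-th start frame in non-overlapping mode)."""
    t0 = np.arange(start, end - 2 * tau, 1 if overlapping else 2 * tau)
    s1 = xy[t0 + tau] - xy[t0]
    s2 = xy[t0 + 2 * tau] - xy[t0 + tau]
    return t0, s1, s2


def step_vectors(traj: Trajectory, tau: int, start: int = 0,
                 end: int | None = None,
                 overlapping: bool = True) -> list[StepPair]:
    """Enumerate every overlapping step pair in [start, end)
    (non-overlapping mode advances start frames by 2*tau).

    Pairs with a zero-length step get cosine = NaN (flagged, excluded from
    any mean downstream).
    """
    end = traj.n_frames if end is None else end
    if tau < 1:
        raise ValueError("tau must be >= 1 frame")
    if end - start <= 2 * tau:
        raise ValueError("segment must be longer than 2*tau frames")
    t0, s1, s2 = _pair_arrays(traj.xy, tau, start, end, overlapping)
    m1 = np.linalg.norm(s1, axis=1)
    m2 = np.linalg.norm(s2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("ij,ij->i", s1, s2) / (m1 * m2)
    cos[(m1 == 0) | (m2 == 0)] = np.nan
    return [StepPair(int(t), a, b, float(c))
            for t, a, b, c in zip(t0, s1, s2, cos)]


def rolling_directional_correlation(traj: Trajectory, tau: int = DEFAULT_TAU,
                                    window: int = 1000,
                                    stride: int | None = None,
                                    min_step: float = 0.0,
                                    series: WindowSeries | None = None,
                                    overlapping: bool = True
                                    ) -> WindowSeries:
    """Rolling directional correlation C_i with stderr per window.

    Within each window every start frame t with t+2τ inside the window
    contributes one cosine; pairs where either step magnitude falls below
    ``min_step`` (noise-dominated directions) are skipped and counted.
    Passing an existing ``series`` (e.g. from the rolling MSD) reuses its
    window grid so α_i and C_i share placements.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 frame")
    if window <= 2 * tau:
        raise ValueError("window must exceed 2*tau frames")
    if series is None:
        stride = max(window // 10, 1) if stride is None else stride
        series = window_grid(traj.n_frames, window, stride, traj.framerate)
    xy = traj.xy
    nw = series.n_windows
    C = np.full(nw, np.nan)
    C_se = np.full(nw, np.nan)
    n_skipped = np.zeros(nw, dtype=int)
    for i, (a, b) in enumerate(zip(series.window_start, series.window_end)):
        _, s1, s2 = _pair_arrays(xy, tau, int(a), int(b), overlapping)
        m1 = np.linalg.norm(s1, axis=1)
        m2 = np.linalg.norm(s2, axis=1)
        ok = (m1 >= max(min_step, 1e-300)) & (m2 >= max(min_step, 1e-300)) \
            & (m1 > 0) & (m2 > 0)
        n_skipped[i] = int(np.sum(~ok))
        if not ok.any():
            continue
        cos = np.einsum("ij,ij->i", s1[ok], s2[ok]) / (m1[ok] * m2[ok])
        C[i] = cos.mean()
        C_se[i] = cos.std(ddof=1) / np.sqrt(len(cos)) if len(cos) > 1 else 0.0
    series.C, series.C_stderr = C, C_se
    return series


def default_min_step(sigma_xy: float) -> float:
    """Noise floor for a τ-step: each endpoint carries per-axis noise
    σ_xy, so the displacement noise magnitude is ~σ_xy·√8 over two axes."""
    return float(sigma_xy) * np.sqrt(8.0)
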