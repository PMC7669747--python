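"""Time-averaged mean-square-displacement analysis.

The MSD of a trajectory segment is modelled as a power law
MSD(τ) = Γ_α · τ^α, whose temporal exponent α classifies the motion:
α = 1 normal diffusion, α < 1 sub-diffusion, α > 1 super-diffusion.
A rolling window applied along the trajectory resolves changes of α in
time.  Static localization error inflates the measured 2D MSD by a
constant offset 4·σ_xy² which, left uncorrected, biases α downward; the
fit subtracts it and excludes lags whose displacement is comparable to
the localization precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "WindowSeries",
    "default_fit_lags",
    "time_averaged_msd",
    "fit_temporal_exponent",
    "rolling_exponent",
    "whole_trajectory_msd",
]

# factor f in the low-displacement exclusion rule: drop lags with measured
# MSD < f · (4·sigma_xy²); displacements there are dominated by noise
LOW_DISPLACEMENT_FACTOR = 2.0


@dataclass
class MSDCurve:
    """Time-averaged MSD sampled at integer frame lags."""

    lag_frames: np.ndarray  # int
    lag_s: np.ndarray  # seconds
    msd: np.ndarray  # nm²
    n_pairs: np.ndarray  # displacement pairs averaged per lag
    corrected: bool = False
    offset_subtracted: float = 0.0  # nm²

    def __post_init__(self) -> None:
        if len(self.lag_s) == 0:
            raise ValueError("empty MSD curve")
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported lag needs at least one pair")


@dataclass
class PowerLawFit:
    """Weighted log-log power-law fit MSD(τ) = Γ_α · τ^α."""

    alpha: float
    gamma: float  # nm²/s^alpha
    alpha_stderr: float
    fit_lag_range: tuple[float, float]  # seconds
    n_lags_used: int
    n_lags_excluded_low: int = 0  # dropped by the noise-floor rule
    n_lags_excluded_nonpos: int = 0  # nonpositive after offset subtraction


@dataclass
class WindowSeries:
    """Per-rolling-window kinetic summaries along one trajectory.

    ``alpha``/``gamma`` come from the rolling MSD fit; ``C`` (directional
    correlation) is filled in by the directional-correlation stage when the
    same window grid is reused.  Failed windows carry NaN, never a
    fabricated value.
    """

    window_start: np.ndarray  # frames, inclusive
    window_end: np.ndarray  # frames, exclusive
    window_center_time: np.ndarray  # s
    T_w: float  # s, window duration
    stride: int  # frames
    alpha: np.ndarray = field(default=None)
    alpha_stderr: np.ndarray = field(default=None)
    gamma: np.ndarray = field(default=None)
    C: np.ndarray = field(default=None)
    C_stderr: np.ndarray = field(default=None)

    @property
    def n_windows(self) -> int:
        return len(self.window_start)

    def to_frame(self):
        """Tabular view (pandas DataFrame) for writing to disk."""
        import pandas as pd

        def col(a):
            return a if a is not None else np.full(self.n_windows, np.nan)

        return pd.DataFrame({
            "i": np.arange(self.n_windows),
            "t_center_s": self.window_center_time,
            "alpha": col(self.alpha),
            "alpha_se": col(self.alpha_stderr),
            "gamma": col(self.gamma),
            "C": col(self.C),
            "C_se": col(self.C_stderr),
        })


def window_grid(n_frames: int, window: int, stride: int,
                framerate: float) -> WindowSeries:
    """Lay out the shared rolling-window grid used by the MSD and the
    directional-correlation stages."""
    if window > n_frames:
        raise ValueError("window exceeds trajectory length")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = np.arange(0, n_frames - window + 1, stride)
    ends = starts + window
    centers = (starts + ends) / 2.0 / framerate
    return WindowSeries(window_start=starts, window_end=ends,
                        window_center_time=centers,
                        T_w=window / framerate, stride=stride)


def default_fit_lags(window: int, max_n_lags: int = 20) -> np.ndarray:
    """Frame lags 1..window/4, log-thinned to at most ``max_n_lags``.

    Capping at a quarter of the window keeps at least 3/4·window
    displacement pairs per lag.
    """
    max_lag = max(window // 4, 3)
    lags = np.unique(np.round(np.geomspace(1, max_lag, max_n_lags)).astype(int))
    return lags[lags >= 1]


def time_averaged_msd(traj: Trajectory, start: int = 0, end: int | None = None,
                      lags: np.ndarray | None = None,
                      use_z: bool = False) -> MSDCurve:
    """Time-averaged MSD of the segment [start, end) at the given frame lags.

    Averages |r(t_j+τ) − r(t_j)|² over every frame pair inside the segment.
    Lateral (x, y) components only unless ``use_z`` requests 3D.
    Lags not realizable in the segment are dropped with a warning.
    """
    n = traj.n_frames
    end = n if end is None else end
    if not (0 <= start < end <= n):
        raise ValueError(f"invalid segment [{start}, {end}) for {n} frames")
    seg = traj.position[start:end] if (use_z and traj.ndim == 3) else traj.xy[start:end]
    length = end - start
    if lags is None:
        lags = default_fit_lags(length)
    lags = np.unique(np.asarray(lags, dtype=int))
    if len(lags) == 0:
        raise ValueError("empty lag list")
    if np.any(lags < 1):
        raise ValueError("lags must be >= 1 frame")
    keep = lags < length
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} lag(s) >= segment length {length}")
    lags = lags[keep]
    if len(lags) == 0:
        raise ValueError("no usable lag below segment length")
    msd = np.empty(len(lags))
    n_pairs = np.empty(len(lags), dtype=int)
    for k, lag in enumerate(lags):
        d = seg[lag:] - seg[:-lag]
        msd[k] = np.mean(np.einsum("ij,ij->i", d, d))
        n_pairs[k] = length - lag
    return MSDCurve(lag_frames=lags, lag_s=lags / traj.framerate,
                    msd=msd, n_pairs=n_pairs)


def fit_temporal_exponent(curve: MSDCurve, sigma_xy: float = 0.0,
                          fit_lags: np.ndarray | None = None,
                          offset_mode: str = "subtract") -> PowerLawFit:
    """Fit MSD(τ) = Γ_α·τ^α on log-log axes with static-error handling.

    offset_mode:
      * ``"subtract"`` (default) — subtract the known static-error offset
        4·sigma_xy² from each MSD value, and exclude lags whose *measured*
        MSD is below ``LOW_DISPLACEMENT_FACTOR`` times that offset (steps
        comparable to the localization precision carry no exponent
        information).
      * ``"free"`` — co-fit the offset as a free parameter
        (MSD = Γτ^α + c) by nonlinear least squares.
      * ``"none"`` — no correction (used to demonstrate the α bias).

    The log-log fit is weighted least squares with weights ∝ n_pairs.
    """
    if sigma_xy < 0:
        raise ValueError("sigma_xy must be >= 0")
    mask = np.ones(len(curve.lag_s), dtype=bool)
    if fit_lags is not None:
        mask &= np.isin(curve.lag_frames, fit_lags)
    offset = 4.0 * sigma_xy ** 2

    if offset_mode == "free":
        return _fit_free_offset(curve, mask)
    if offset_mode == "none":
        offset = 0.0
    elif offset_mode != "subtract":
        raise ValueError("offset_mode must be 'subtract', 'free' or 'none'")

    n_low = 0
    if offset > 0:
        low = curve.msd < LOW_DISPLACEMENT_FACTOR * offset
        n_low = int(np.sum(low & mask))
        mask &= ~low
    y = curve.msd - offset
    nonpos = y <= 0
    n_nonpos = int(np.sum(nonpos & mask))
    mask &= ~nonpos
    if mask.sum() < 3:
        raise ValueError(
            "fewer than 3 usable lags for the power-law fit "
            f"({n_low} below the noise floor, {n_nonpos} nonpositive after "
            "offset subtraction)"
        )
    tau = curve.lag_s[mask]
    logt, logy = np.log(tau), np.log(y[mask])
    w = curve.n_pairs[mask].astype(float)
    # weighted linear regression of log MSD on log τ
    W = np.diag(w)
    X = np.column_stack([np.ones_like(logt), logt])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ logy)
    resid = logy - X @ beta
    dof = max(mask.sum() - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    stderr = float(np.sqrt(s2 * cov[1, 1]))
    return PowerLawFit(alpha=float(beta[1]), gamma=float(np.exp(beta[0])),
                       alpha_stderr=stderr,
                       fit_lag_range=(float(tau[0]), float(tau[-1])),
                       n_lags_used=int(mask.sum()),
                       n_lags_excluded_low=n_low,
                       n_lags_excluded_nonpos=n_nonpos)


def _fit_free_offset(curve: MSDCurve, mask: np.ndarray) -> PowerLawFit:
    from scipy.optimize import curve_fit

    if mask.sum() < 4:
        raise ValueError("free-offset fit needs at least 4 lags")
    tau, y = curve.lag_s[mask], curve.msd[mask]
    w = curve.n_pairs[mask].astype(float)

    def model(t, log_gamma, alpha, c):
        return np.exp(log_gamma) * t ** alpha + c

    p0 = [np.log(max(y[-1] / tau[-1], 1e-12)), 1.0, 0.0]
    popt, pcov = curve_fit(model, tau, y, p0=p0, sigma=1.0 / np.sqrt(w),
                           maxfev=10_000)
    return PowerLawFit(alpha=float(popt[1]), gamma=float(np.exp(popt[0])),
                       alpha_stderr=float(np.sqrt(pcov[1, 1])),
                       fit_lag_range=(float(tau[0]), float(tau[-1])),
                       n_lags_used=int(mask.sum()))


def rolling_exponent(traj: Trajectory, window: int, stride: int | None = None,
                     lags: np.ndarray | None = None,
                     sigma_xy: float | None = None,
                     offset_mode: str = "subtract") -> WindowSeries:
    """Rolling-window temporal exponent α_i along the trajectory.

    Each window [k·stride, k·stride+window) gets its own time-averaged MSD
    and power-law fit; α_i is reported at the window's centre time.
    Windows whose fit fails (too few usable lags) carry NaN.
    Default stride is window/10 (overlapping windows).
    """
    stride = max(window // 10, 1) if stride is None else stride
    series = window_grid(traj.n_frames, window, stride, traj.framerate)
    if lags is None:
        lags = default_fit_lags(window)
    if sigma_xy is None:
        sigma_xy = float(np.median(traj.sigma_xy_array()))
    nw = series.n_windows
    alpha = np.full(nw, np.nan)
    alpha_se = np.full(nw, np.nan)
    gamma = np.full(nw, np.nan)
    for i, (a, b) in enumerate(zip(series.window_start, series.window_end)):
        try:
            curve = time_averaged_msd(traj, int(a), int(b), lags=lags)
            fit = fit_temporal_exponent(curve, sigma_xy=sigma_xy,
                                        offset_mode=offset_mode)
        except ValueError:
            continue
        alpha[i], alpha_se[i], gamma[i] = fit.alpha, fit.alpha_stderr, fit.gamma
    series.alpha, series.alpha_stderr, series.gamma = alpha, alpha_se, gamma
    return series


def whole_trajectory_msd(traj: Trajectory, max_lag_fraction: float = 0.25,
                         n_lags: int = 30, sigma_xy: float | None = None,
                         min_lag_s: float | None = None,
                         max_lag_s: float | None = None,
                         offset_mode: str = "subtract"
                         ) -> tuple[MSDCurve, PowerLawFit]:
    """Single time-averaged MSD over the full trajectory with log-spaced
    lags up to ``max_lag_fraction`` of the duration, plus its fit.

    Explicit ``min_lag_s``/``max_lag_s`` override the fraction-based range.
    """
    if not (0 < max_lag_fraction <= 0.25):
        raise ValueError("max_lag_fraction must lie in (0, 0.25]")
    lo = 1 if min_lag_s is None else max(int(round(min_lag_s * traj.framerate)), 1)
    if max_lag_s is None:
        hi = max(int(traj.n_frames * max_lag_fraction), lo + 2)
    else:
        hi = int(round(max_lag_s * traj.framerate))
    hi = min(hi, traj.n_frames - 1)
    lags = np.unique(np.round(np.geomspace(lo, hi, n_lags)).astype(int))
    curve = time_averaged_msd(traj, lags=lags)
    if sigma_xy is None:
        sigma_xy = float(np.median(traj.sigma_xy_array()))
    fit = fit_temporal_exponent(curve, sigma_xy=sigma_xy, offset_mode=offset_mode)
    return curve, fit
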