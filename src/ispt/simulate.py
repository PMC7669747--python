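"""Ground-truth trajectory generators for every mobility mode the analyses
must distinguish: free Brownian motion, fractional-Brownian sub-diffusion,
reflecting circular corrals, hop diffusion between square compartments,
diffusion on a spherical-cap ("bowl") surface, processive stepper transport,
and 3D landing onto a membrane plane — plus the localization-noise
observation model.

All generators are seeded-deterministic: the same ``SimConfig`` (including
``seed``) reproduces the trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trajectory import Trajectory

__all__ = ["SimConfig", "simulate_trajectory", "add_localization_noise"]

_MODELS = ("brownian", "fbm", "corral", "hop", "bowl", "stepper", "landing")


@dataclass
class SimConfig:
    """Parameters for one synthetic trajectory.

    Only the fields relevant to the chosen ``model`` are required; a missing
    model-specific field raises a configuration error naming it.

    Units: lengths nm, rates 1/s, framerate frames/s, diffusion coefficient
    nm²/s (nm²/s^alpha for fbm, so that MSD(τ) = 4·D·τ^alpha in 2D).
    """

    model: str = "brownian"
    dimensionality: int = 2
    framerate: float = 30_000.0
    n_frames: int = 1_000
    diffusion_coefficient: float = 1e5  # D, nm²/s
    alpha_true: float | None = None  # fbm temporal exponent, (0, 2)
    corral_radius: float | None = None  # nm
    compartment_side: float | None = None  # L, nm (hop)
    hop_probability: float | None = None  # per boundary encounter
    bowl_radius: float | None = None  # nm
    bowl_cap_half_angle: float | None = None  # radians
    step_size: float | None = None  # δ, nm (stepper)
    dwell_rate: float | None = None  # 1/s (stepper)
    track_axis: Sequence[float] | None = None  # unit vector (stepper)
    jitter_sigma: float = 0.0  # nm (stepper)
    start_height: float | None = None  # nm (landing)
    binding_probability: float | None = None  # per membrane contact
    flow_velocity: Sequence[float] | None = None  # nm/s, advective drift
    #   (landing only; emulates micropipette-delivery flow)
    seed: int = 0
    start: Sequence[float] | None = None  # nm; defaults to the origin

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.framerate <= 0:
            raise ValueError("framerate must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        for name in ("corral_radius", "compartment_side", "bowl_radius",
                     "step_size", "start_height"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha_true is not None and not (0 < self.alpha_true < 2):
            raise ValueError("alpha_true must lie in (0, 2)")
        for name in ("hop_probability", "binding_probability"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    def _require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"model {self.model!r} requires parameter(s): {', '.join(missing)}"
            )


def _start_point(config: SimConfig, dim: int) -> np.ndarray:
    if config.start is None:
        return np.zeros(dim)
    s = np.asarray(config.start, dtype=float)
    if s.shape != (dim,):
        raise ValueError(f"start must have {dim} components")
    return s


def _finish(config: SimConfig, pos: np.ndarray, **extra) -> Trajectory:
    meta = {"model": config.model, "seed": config.seed,
            "D_nm2_per_s": config.diffusion_coefficient, **extra}
    return Trajectory(position=pos, framerate=config.framerate, metadata=meta)


# ---------------------------------------------------------------------------
# free and fractional Brownian motion

def _brownian_steps(rng: np.random.Generator, n_steps: int, dim: int,
                    D: float, dt: float) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_steps, dim))


def _simulate_brownian(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    dim = config.dimensionality
    dt = 1.0 / config.framerate
    steps = _brownian_steps(rng, config.n_frames - 1, dim,
                            config.diffusion_coefficient, dt)
    pos = np.vstack([np.zeros(dim), np.cumsum(steps, axis=0)]) + _start_point(config, dim)
    return _finish(config, pos)


def fractional_gaussian_noise(n: int, hurst: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise by circulant embedding
    (Davies–Harte).  Returns n unit-scale increments of fractional Brownian
    motion with Hurst exponent ``hurst`` at unit time step.
    """
    if n < 2:
        raise ValueError("need n >= 2 for circulant embedding")
    H = hurst
    k = np.arange(n)
    # autocovariance of fGn at unit step
    gamma = 0.5 * (np.abs(k - 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H)
                   + np.abs(k + 1) ** (2 * H))
    # first row of the 2n-circulant embedding
    row = np.concatenate([gamma, [0.0], gamma[-1:0:-1]])
    eigs = np.fft.fft(row).real
    if eigs.min() < -1e-8 * eigs.max():
        raise ValueError("circulant embedding not nonnegative-definite for this n/H")
    eigs = np.clip(eigs, 0.0, None)
    m = 2 * n
    z = rng.normal(size=m) + 1j * rng.normal(size=m)
    w = np.fft.fft(np.sqrt(eigs / m) * z)
    return w.real[:n]


def _simulate_fbm(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    config._require("alpha_true")
    dim = config.dimensionality
    dt = 1.0 / config.framerate
    H = config.alpha_true / 2.0
    n_steps = config.n_frames - 1
    # per-axis displacement variance over lag τ: 2·D·τ^alpha
    scale = np.sqrt(2.0 * config.diffusion_coefficient) * dt ** H
    incr = np.column_stack(
        [fractional_gaussian_noise(n_steps, H, rng) for _ in range(dim)]
    ) * scale
    pos = np.vstack([np.zeros(dim), np.cumsum(incr, axis=0)]) + _start_point(config, dim)
    return _finish(config, pos, alpha_true=config.alpha_true, hurst=H)


# ---------------------------------------------------------------------------
# reflecting circular corral

def _reflect_in_disk(p0: np.ndarray, step: np.ndarray, R: float) -> np.ndarray:
    """Advance p0 by step inside the disk |p| <= R with specular reflection
    of the out-of-bounds segment at the circular wall (one reflection)."""
    p1 = p0 + step
    r1 = np.hypot(p1[0], p1[1])
    if r1 <= R:
        return p1
    # fraction t of the segment at which it crosses the circle
    d = step
    a = d @ d
    b = 2.0 * (p0 @ d)
    c = p0 @ p0 - R * R
    disc = max(b * b - 4 * a * c, 0.0)
    t = (-b + np.sqrt(disc)) / (2 * a)
    t = min(max(t, 0.0), 1.0)
    hit = p0 + t * d
    normal = hit / max(np.hypot(hit[0], hit[1]), 1e-300)
    rest = (1.0 - t) * d
    reflected = rest - 2.0 * (rest @ normal) * normal
    p1 = hit + reflected
    r1 = np.hypot(p1[0], p1[1])
    if r1 > R:  # grazing double-crossing; clamp radially
        p1 *= R / r1
    return p1


def _simulate_corral(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    config._require("corral_radius")
    R = config.corral_radius
    dt = 1.0 / config.framerate
    D = config.diffusion_coefficient
    n = config.n_frames
    start = _start_point(config, 2)
    if np.hypot(*start) > R:
        raise ValueError("start point lies outside the corral")
    # substep so a typical move cannot tunnel through the wall
    sigma_step = np.sqrt(2.0 * D * dt)
    n_sub = max(1, int(np.ceil((4.0 * sigma_step) / (R / 4.0)) ** 2))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt / n_sub), size=(n - 1, n_sub, 2))
    pos = np.empty((n, 2))
    pos[0] = start
    p = start.copy()
    for j in range(n - 1):
        for s in range(n_sub):
            p = _reflect_in_disk(p, steps[j, s], R)
        pos[j + 1] = p
    return _finish(config, pos, corral_radius=R)


# ---------------------------------------------------------------------------
# hop diffusion between square compartments (picket-fence rejection model)

def _simulate_hop(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    config._require("compartment_side", "hop_probability")
    L = config.compartment_side
    p_hop = config.hop_probability
    dt = 1.0 / config.framerate
    n = config.n_frames
    steps = _brownian_steps(rng, n - 1, 2, config.diffusion_coefficient, dt)
    accept = rng.random(size=(n - 1, 2))
    pos = np.empty((n, 2))
    pos[0] = _start_point(config, 2) + L / 2.0  # centre of compartment (0,0)
    for j in range(n - 1):
        for ax in range(2):
            x = pos[j, ax]
            x_new = x + steps[j, ax]
            if np.floor(x_new / L) != np.floor(x / L):
                # boundary encounter: cross with probability p_hop, else
                # reflect off the fence
                if accept[j, ax] >= p_hop:
                    wall = L * (np.floor(x / L) + (1 if x_new > x else 0))
                    x_new = 2.0 * wall - x_new
                    # clamp pathological large steps inside the compartment
                    lo, hi = L * np.floor(x / L), L * (np.floor(x / L) + 1)
                    x_new = min(max(x_new, lo + 1e-12), hi - 1e-12)
            pos[j + 1, ax] = x_new
    pos -= L / 2.0
    return _finish(config, pos, compartment_side=L, hop_probability=p_hop)


# ---------------------------------------------------------------------------
# diffusion on a spherical-cap ("bowl") surface

def _simulate_bowl(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    config._require("bowl_radius", "bowl_cap_half_angle")
    R = config.bowl_radius
    theta_max = config.bowl_cap_half_angle
    if not (0 < theta_max <= np.pi):
        raise ValueError("bowl_cap_half_angle must lie in (0, pi]")
    dt = 1.0 / config.framerate
    sigma = np.sqrt(2.0 * config.diffusion_coefficient * dt)
    n = config.n_frames
    steps = rng.normal(0.0, sigma, size=(n - 1, 2))
    pos = np.empty((n, 3))
    # bowl opens upward: cap around the south pole (0, 0, -R), centre at origin
    p = np.array([0.0, 0.0, -R])
    pos[0] = p
    down = np.array([0.0, 0.0, -1.0])
    for j in range(n - 1):
        # orthonormal tangent basis at p
        nrm = p / np.linalg.norm(p)
        helper = np.array([1.0, 0.0, 0.0]) if abs(nrm[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(nrm, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        q = p + steps[j, 0] * e1 + steps[j, 1] * e2
        q *= R / np.linalg.norm(q)  # radial reprojection onto the sphere
        # reflecting cap boundary: fold the polar angle about theta_max
        cos_t = np.clip(-q[2] / R, -1.0, 1.0)
        theta = np.arccos(cos_t)
        if theta > theta_max:
            theta_ref = max(2.0 * theta_max - theta, 0.0)
            lat = np.hypot(q[0], q[1])
            if lat > 1e-12:
                u = q[:2] / lat
            else:
                u = np.array([1.0, 0.0])
            q = np.array([R * np.sin(theta_ref) * u[0],
                          R * np.sin(theta_ref) * u[1],
                          -R * np.cos(theta_ref)])
        p = q
        pos[j + 1] = p
    pos += _start_point(config, 3)  # interpreted as the bowl centre offset
    return _finish(config, pos, bowl_radius=R, bowl_cap_half_angle=theta_max)


# ---------------------------------------------------------------------------
# processive stepper (motor-like transport along a linear track)

def _simulate_stepper(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    config._require("step_size", "dwell_rate", "track_axis")
    dim = config.dimensionality
    axis = np.asarray(config.track_axis, dtype=float)
    if axis.shape != (dim,):
        raise ValueError(f"track_axis must have {dim} components")
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("track_axis must be nonzero")
    axis = axis / nrm
    dt = 1.0 / config.framerate
    n = config.n_frames
    # number of instantaneous jumps per frame interval (Poisson at dwell_rate)
    jumps = rng.poisson(config.dwell_rate * dt, size=n - 1)
    walked = np.concatenate([[0.0], np.cumsum(jumps) * config.step_size])
    pos = walked[:, None] * axis[None, :] + _start_point(config, dim)
    if config.jitter_sigma > 0:
        pos = pos + rng.normal(0.0, config.jitter_sigma, size=pos.shape)
    traj = _finish(config, pos, step_size=config.step_size,
                   dwell_rate=config.dwell_rate,
                   jitter_sigma=config.jitter_sigma)
    traj.metadata["true_walked_distance"] = walked
    traj.metadata["true_jump_frames"] = np.flatnonzero(jumps) + 1
    traj.metadata["true_jump_counts"] = jumps[jumps > 0]
    traj.metadata["track_axis"] = axis
    return traj


# ---------------------------------------------------------------------------
# 3D landing onto the membrane plane z = 0

def _simulate_landing(config: SimConfig, rng: np.random.Generator) -> Trajectory:
    config._require("start_height", "binding_probability")
    dt = 1.0 / config.framerate
    D = config.diffusion_coefficient
    n = config.n_frames
    p_bind = config.binding_probability
    steps = _brownian_steps(rng, n - 1, 3, D, dt)
    if config.flow_velocity is not None:
        flow = np.asarray(config.flow_velocity, dtype=float)
        if flow.shape != (3,):
            raise ValueError("flow_velocity must have 3 components")
        steps = steps + flow * dt
    u = rng.random(n - 1)
    pos = np.empty((n, 3))
    pos[0] = [0.0, 0.0, config.start_height]
    bound_at: int | None = None
    for j in range(n - 1):
        pos[j + 1, :2] = pos[j, :2] + steps[j, :2]
        if bound_at is not None:
            pos[j + 1, 2] = 0.0
            continue
        z_new = pos[j, 2] + steps[j, 2]
        if z_new <= 0.0:
            if u[j] < p_bind:  # membrane contact: stick ...
                z_new = 0.0
                bound_at = j + 1
            else:  # ... or reflect back into the medium
                z_new = -z_new
        pos[j + 1, 2] = z_new
    traj = _finish(config, pos, start_height=config.start_height,
                   binding_probability=p_bind)
    traj.metadata["bound_at_frame"] = bound_at
    return traj


_DISPATCH = {
    "brownian": _simulate_brownian,
    "fbm": _simulate_fbm,
    "corral": _simulate_corral,
    "hop": _simulate_hop,
    "bowl": _simulate_bowl,
    "stepper": _simulate_stepper,
    "landing": _simulate_landing,
}


def simulate_trajectory(config: SimConfig) -> Trajectory:
    """Generate one noiseless ground-truth trajectory for ``config.model``.

    The observation model (localization noise) is applied separately with
    :func:`add_localization_noise`, so the true positions remain available
    for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    return _DISPATCH[config.model](config, rng)


def add_localization_noise(traj: Trajectory, sigma_xy: float,
                           sigma_z: float = 0.0, seed: int = 0) -> Trajectory:
    """Add independent zero-mean Gaussian localization noise.

    ``sigma_xy`` is the per-axis lateral std (nm); the expected measured 2D
    MSD then exceeds the true MSD by 4·sigma_xy² at every lag.  The sigmas
    are recorded on the returned trajectory for downstream error correction.
    """
    if sigma_xy < 0 or sigma_z < 0:
        raise ValueError("noise sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    pos = traj.position.copy()
    if sigma_xy > 0:
        pos[:, :2] += rng.normal(0.0, sigma_xy, size=(traj.n_frames, 2))
    if traj.ndim == 3 and sigma_z > 0:
        pos[:, 2] += rng.normal(0.0, sigma_z, size=traj.n_frames)
    return Trajectory(
        position=pos,
        framerate=traj.framerate,
        frame_index=traj.frame_index.copy(),
        sigma_xy=sigma_xy,
        sigma_z=sigma_z if traj.ndim == 3 else None,
        metadata={**traj.metadata, "noise_seed": seed},
    )
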