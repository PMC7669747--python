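"""Bowl/pit geometry: sphere fitting of 3D confined trajectories and the
angular position ϕ(t) of the probe about the bowl axis.

Membrane pits (~350 nm, endocytosis-associated) confine the probe to a
spherical-cap surface.  The fit solves the linearized sphere equation by
least squares and refines the geometric distance with Gauss–Newton; the
bowl axis points from the sphere centre toward the data centroid (into
the cap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = ["BowlFit", "AngularSeries", "fit_bowl", "angular_series"]


@dataclass
class BowlFit:
    """Least-squares sphere fit of a cap-confined 3D trajectory."""

    center: np.ndarray  # nm
    radius: float  # nm
    axis: np.ndarray  # unit vector, centre -> cap centroid
    rms_residual: float  # nm, rms |dist(point, centre) − R|
    opening_diameter: float  # nm, max extent of points ⊥ axis

    @property
    def sphere_diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class AngularSeries:
    """Unwrapped angular position ϕ(t) about the bowl axis."""

    phi: np.ndarray  # radians, unwrapped (first frame = 0)
    reference_direction: np.ndarray  # unit vector ⊥ axis
    degenerate: np.ndarray  # bool; ϕ carried over (projection < 1 nm)


def _positions(traj3d: Trajectory | np.ndarray) -> np.ndarray:
    if isinstance(traj3d, Trajectory):
        if traj3d.ndim != 3:
            raise ValueError("bowl fitting requires a 3D trajectory")
        return traj3d.position
    pts = np.asarray(traj3d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected (n, 3) points")
    return pts


def fit_bowl(traj3d: Trajectory | np.ndarray) -> BowlFit:
    """Fit a sphere to 3D points: algebraic least squares on the linearized
    sphere equation, then one Gauss–Newton refinement of the geometric
    distance.  Coplanar or otherwise degenerate point sets raise."""
    pts = _positions(traj3d)
    n = len(pts)
    if n < 4:
        raise ValueError("need at least 4 points for a sphere fit")
    # coplanarity check on the point cloud covariance
    centered = pts - pts.mean(axis=0)
    evals = np.linalg.eigvalsh(centered.T @ centered / n)
    if evals[0] < 1e-10 * max(evals[-1], 1e-300):
        raise ValueError("degenerate point set: points are (nearly) coplanar; "
                         "the sphere is not identifiable")
    # |p|² = 2 p·c + (R² − |c|²): linear in (c, k)
    A = np.column_stack([2.0 * pts, np.ones(n)])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center, k = sol[:3], sol[3]
    r2 = k + center @ center
    if r2 <= 0:
        raise ValueError("degenerate sphere fit (nonpositive radius)")
    radius = float(np.sqrt(r2))
    # one Gauss–Newton step on the geometric distance residual
    for _ in range(1):
        d = pts - center
        dist = np.linalg.norm(d, axis=1)
        if np.any(dist < 1e-12):
            break
        res = dist - radius
        J = np.column_stack([-d / dist[:, None], -np.ones(n)])
        try:
            delta, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:
            break
        center = center + delta[:3]
        radius = float(radius + delta[3])
    d = pts - center
    dist = np.linalg.norm(d, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    axis = pts.mean(axis=0) - center
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-12:
        raise ValueError("cannot orient bowl axis: centroid coincides with centre")
    axis = axis / axis_norm
    # opening diameter: maximal extent of the in-plane projection
    inplane = d - np.outer(d @ axis, axis)
    u = inplane @ _any_perp(axis)
    v = inplane @ np.cross(axis, _any_perp(axis))
    opening = float(max(u.max() - u.min(), v.max() - v.min()))
    return BowlFit(center=center, radius=radius, axis=axis,
                   rms_residual=rms, opening_diameter=opening)


def _any_perp(axis: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(axis, helper)
    return p / np.linalg.norm(p)


def angular_series(traj3d: Trajectory | np.ndarray, fit: BowlFit,
                   min_projection: float = 1.0) -> AngularSeries:
    """Angular position ϕ(t) of each point about the bowl axis.

    Points are projected onto the plane ⊥ axis through the centre; ϕ is the
    signed angle versus the first frame's projection (reference), unwrapped
    for continuity.  A point projecting to less than ``min_projection`` nm
    carries the previous ϕ and is flagged.
    """
    pts = _positions(traj3d)
    d = pts - fit.center
    inplane = d - np.outer(d @ fit.axis, fit.axis)
    lengths = np.linalg.norm(inplane, axis=1)
    if lengths[0] < min_projection:
        raise ValueError("first frame projects onto the axis; no reference "
                         "direction definable")
    ref = inplane[0] / lengths[0]
    e2 = np.cross(fit.axis, ref)
    phi_raw = np.arctan2(inplane @ e2, inplane @ ref)
    degenerate = lengths < min_projection
    # carry over ϕ through degenerate frames before unwrapping
    phi_filled = phi_raw.copy()
    for j in np.flatnonzero(degenerate):
        phi_filled[j] = phi_filled[j - 1] if j > 0 else 0.0
    phi = np.unwrap(phi_filled)
    return AngularSeries(phi=phi, reference_direction=ref, degenerate=degenerate)
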