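"""Interferometric (iSCAT) image synthesis and 3D localization.

Image formation follows the interferometric detection law
I_det = |E_ref + E_sca|² = |E_ref|² + |E_sca|² + 2|E_ref||E_sca|cos(θ):
with intensities normalized to the reference level, a weak scatterer
(s = |E_sca|/|E_ref| ≤ 0.5) produces I ≈ 1 + cross term; the |E_sca|²
term, bounded by s² ≤ 0.25, is deliberately omitted from synthesis so the
axial calibration stays closed-form.

The interferometric PSF is modelled phenomenologically as a Gaussian
envelope times a cosine whose phase carries the physically correct axial
dependence 4π·n_m·z/λ plus a defocus-dependent quadratic radial term that
produces the characteristic alternating rings.  Lateral localization uses
the gradient-based radial-symmetry centre method on the squared contrast;
axial localization inverts a central-contrast calibration on a monotonic
branch chosen by temporal continuity, so reported heights are relative
within a branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .trajectory import Trajectory

__all__ = [
    "IPSFModel", "BackgroundParams", "FrameStack", "AxialCalibration",
    "Localization", "synthesize_frame", "synthesize_stack",
    "synthesize_background_stack", "remove_background", "localize_lateral",
    "build_axial_calibration", "localize_frame", "track_stack",
    "write_stack", "read_stack", "write_calibration", "read_calibration",
]


@dataclass
class IPSFModel:
    """Phenomenological interferometric PSF.

    central contrast: c(z) = 2·s·cos(θ₀ + 4π·n_m·z/λ)
    envelope: w(z) = w₀·sqrt(1 + ((z−z_f)/z_R)²)
    ring phase: β·(z−z_f)·r² (r in pixels)
    """

    wavelength: float = 635.0  # λ, nm
    medium_index: float = 1.33  # n_m
    scattering_amplitude: float = 0.05  # s = |E_sca|/|E_ref| ∈ (0, 0.5]
    phase_offset: float = 0.0  # θ₀, radians
    envelope_waist: float = 3.0  # w₀, pixels
    axial_range: float = 500.0  # z_R, nm
    ring_phase_coefficient: float = 2e-4  # β, rad/(nm·px²)
    pixel_size: float = 80.0  # nm/pixel
    focus_height: float = 0.0  # z_f, nm

    def __post_init__(self) -> None:
        if not (0 <= self.scattering_amplitude <= 0.5):
            raise ValueError("scattering_amplitude must lie in [0, 0.5]")
        for name in ("wavelength", "medium_index", "envelope_waist",
                     "axial_range", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def central_contrast(self, z: np.ndarray | float) -> np.ndarray | float:
        """c(z) = 2·s·cos(θ₀ + 4π·n_m·z/λ)."""
        return 2.0 * self.scattering_amplitude * np.cos(
            self.phase_offset
            + 4.0 * np.pi * self.medium_index * np.asarray(z) / self.wavelength)


@dataclass
class BackgroundParams:
    """Dynamic speckle background of the cell."""

    speckle_amplitude: float = 0.01  # contrast std of the speckle field
    correlation_length: float = 3.0  # pixels (Gaussian kernel sigma)
    ar_coefficient: float = 0.99  # temporal AR(1) coefficient, [0, 1]
    shot_noise: float = 0.001  # per-pixel Gaussian std

    def __post_init__(self) -> None:
        if self.correlation_length < 1:
            raise ValueError("correlation_length must be >= 1 pixel")
        if not (0 <= self.ar_coefficient <= 1):
            raise ValueError("ar_coefficient must lie in [0, 1]")
        if self.speckle_amplitude < 0 or self.shot_noise < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class FrameStack:
    """Stack of normalized interferometric frames (reference level = 1)."""

    pixels: np.ndarray  # (n_frames, ny, nx) float
    pixel_size: float  # nm/pixel
    frame_times: np.ndarray  # s
    background_params: BackgroundParams | None = None

    @property
    def n_frames(self) -> int:
        return len(self.pixels)


@dataclass
class AxialCalibration:
    """Tabulated central contrast c(z) with its monotonic branches."""

    z_grid: np.ndarray  # nm
    contrast: np.ndarray
    monotonic_branches: list[tuple[float, float]]  # (z_lo, z_hi) per branch

    def branch_containing(self, z: float) -> tuple[float, float]:
        for lo, hi in self.monotonic_branches:
            if lo <= z <= hi:
                return lo, hi
        raise ValueError(f"z = {z} nm outside every calibration branch")

    def invert_on_branch(self, contrast: float, branch: tuple[float, float]
                         ) -> tuple[float, bool]:
        """Invert c on one monotonic branch; returns (z, clipped_flag)."""
        lo, hi = branch
        m = (self.z_grid >= lo) & (self.z_grid <= hi)
        z_b, c_b = self.z_grid[m], self.contrast[m]
        if c_b[0] > c_b[-1]:  # np.interp needs ascending x
            z_b, c_b = z_b[::-1], c_b[::-1]
        clipped = not (c_b[0] <= contrast <= c_b[-1])
        return float(np.interp(contrast, c_b, z_b)), clipped


@dataclass
class Localization:
    """One 3D localization with its quality record."""

    frame_index: int
    x: float  # nm
    y: float  # nm
    z: float  # nm (relative, branch convention)
    central_contrast: float
    quality: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# synthesis

def synthesize_frame(model: IPSFModel, particle_xyz, shape=(64, 64)) -> np.ndarray:
    """One noiseless normalized frame with the particle's iPSF.

    I(p) = 1 + 2·s·exp(−r²/(2w(z)²))·cos(θ₀ + 4π·n_m·z/λ + β·(z−z_f)·r²)
    with r the pixel distance from the lateral particle position and
    particle coordinates in nm ((0, 0) = frame corner pixel centre).
    """
    x, y, z = (float(v) for v in particle_xyz)
    ny, nx = shape
    if ny < 16 or nx < 16:
        raise ValueError("frame must be at least 16x16 pixels")
    px, py = x / model.pixel_size, y / model.pixel_size
    if not (0 <= px <= nx - 1 and 0 <= py <= ny - 1):
        raise ValueError("particle lateral position outside the frame")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (xx - px) ** 2 + (yy - py) ** 2  # pixels²
    dz = z - model.focus_height
    w = model.envelope_waist * np.sqrt(1.0 + (dz / model.axial_range) ** 2)
    phase = (model.phase_offset
             + 4.0 * np.pi * model.medium_index * z / model.wavelength
             + model.ring_phase_coefficient * dz * r2)
    envelope = np.exp(-r2 / (2.0 * w * w))
    return 1.0 + 2.0 * model.scattering_amplitude * envelope * np.cos(phase)


def _speckle_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    white = rng.normal(size=shape)
    f = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def synthesize_background_stack(params: BackgroundParams, shape=(64, 64),
                                n_frames: int = 100, seed: int = 0,
                                pixel_size: float = 80.0,
                                framerate: float = 30_000.0) -> FrameStack:
    """Dynamic speckle background: spatially correlated Gaussian field
    evolving per pixel as an AR(1) process, plus optional shot noise,
    normalized around mean 1."""
    rng = np.random.default_rng(seed)
    rho = params.ar_coefficient
    a = params.speckle_amplitude
    frames = np.empty((n_frames, *shape))
    f = _speckle_field(rng, shape, params.correlation_length)
    frames[0] = f
    innov = np.sqrt(max(1.0 - rho * rho, 0.0))
    for t in range(1, n_frames):
        if innov > 0:
            f = rho * f + innov * _speckle_field(rng, shape, params.correlation_length)
        frames[t] = f
    stack = 1.0 + a * frames
    if params.shot_noise > 0:
        stack = stack + rng.normal(0.0, params.shot_noise, size=stack.shape)
    times = np.arange(n_frames) / framerate
    return FrameStack(pixels=stack, pixel_size=pixel_size, frame_times=times,
                      background_params=params)


def synthesize_stack(model: IPSFModel, traj: Trajectory,
                     shape=(64, 64), background: BackgroundParams | None = None,
                     seed: int = 0) -> FrameStack:
    """Render a 3D trajectory (nm; frame coordinates) into a frame stack,
    optionally on a dynamic speckle background (signal and background add
    as contrasts about the reference level 1)."""
    if traj.ndim != 3:
        raise ValueError("stack synthesis needs a 3D trajectory")
    n = traj.n_frames
    if background is not None:
        stack = synthesize_background_stack(
            background, shape=shape, n_frames=n, seed=seed,
            pixel_size=model.pixel_size, framerate=traj.framerate)
    else:
        stack = FrameStack(pixels=np.ones((n, *shape)),
                           pixel_size=model.pixel_size,
                           frame_times=traj.time.astype(float))
    for j in range(n):
        stack.pixels[j] += synthesize_frame(model, traj.position[j], shape) - 1.0
    return stack


# ---------------------------------------------------------------------------
# background removal

def remove_background(stack: FrameStack, median_window: int) -> FrameStack:
    """Subtract the sliding per-pixel temporal median and re-add the
    reference level 1.  Static or slowly varying background cancels while
    a particle occupying each pixel for less than half the window
    survives."""
    n = stack.n_frames
    if median_window < 3 or median_window % 2 == 0:
        raise ValueError("median_window must be odd and >= 3")
    if median_window > n:
        raise ValueError(f"median_window {median_window} exceeds stack length {n}")
    med = ndimage.median_filter(stack.pixels, size=(median_window, 1, 1),
                                mode="nearest")
    # clamp the window at the stack edges (replicated-boundary medians would
    # erase the particle in the first/last half-window of frames)
    h = median_window // 2
    med[:h] = np.median(stack.pixels[:median_window], axis=0)
    med[n - h:] = np.median(stack.pixels[n - median_window:], axis=0)
    return FrameStack(pixels=stack.pixels - med + 1.0,
                      pixel_size=stack.pixel_size,
                      frame_times=stack.frame_times,
                      background_params=stack.background_params)


# ---------------------------------------------------------------------------
# lateral localization: gradient-based radial-symmetry centre

def _radial_center(img: np.ndarray) -> tuple[float, float]:
    """Radial-symmetry centre of ``img`` in pixel coordinates.

    Gradient-line voting: each midpoint of the image grid defines a line
    through itself along the local intensity gradient; for a radially
    symmetric pattern all lines meet at the centre, found here as the
    weighted least-squares nearest point to all lines.
    """
    I = np.asarray(img, dtype=float)
    ny, nx = I.shape
    # gradients on the half-pixel midpoint grid, 45°-rotated (u, v) frame
    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    fdu = ndimage.uniform_filter(dIdu, 3)
    fdv = ndimage.uniform_filter(dIdv, 3)
    dImag2 = fdu * fdu + fdv * fdv
    s = dImag2.sum()
    if s <= 0 or not np.isfinite(s):
        raise ValueError("no detection: flat crop (zero intensity gradient)")
    # midpoint coordinates relative to the crop centre
    xm = np.arange(nx - 1) - (nx - 2) / 2.0
    ym = np.arange(ny - 1) - (ny - 2) / 2.0
    xm, ym = np.meshgrid(xm, ym)
    # gradient slope in (x, y) from the rotated-frame gradients
    denom = fdu - fdv
    tiny = denom == 0
    denom[tiny] = 1e-300
    m = -(fdv + fdu) / denom
    m[tiny] = np.sign(-(fdv + fdu))[tiny] * 1e12
    m[~np.isfinite(m)] = 1e12
    b = ym - m * xm
    xc0 = (dImag2 * xm).sum() / s
    yc0 = (dImag2 * ym).sum() / s
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2)
    w = dImag2 / np.maximum(dist, 0.1)
    wm2p1 = w / (m * m + 1.0)
    sw = wm2p1.sum()
    smmw = (m * m * wm2p1).sum()
    smw = (m * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    det = smw * smw - smmw * sw
    if det == 0:
        raise ValueError("no detection: degenerate gradient geometry")
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    # back to pixel coordinates of the crop
    return xc + (nx - 1) / 2.0, yc + (ny - 1) / 2.0


def localize_lateral(frame: np.ndarray, approximate_center,
                     crop_radius: int, pixel_size: float) -> tuple[float, float]:
    """Lateral particle position (nm) by radial symmetry of the squared
    contrast (I−1)² in a crop around ``approximate_center`` (pixels).
    Squaring makes the alternating black/white rings uniformly positive."""
    ny, nx = frame.shape
    cx, cy = (int(round(v)) for v in approximate_center)
    if not (crop_radius <= cx < nx - crop_radius
            and crop_radius <= cy < ny - crop_radius):
        raise ValueError("crop window extends outside the frame")
    crop = frame[cy - crop_radius: cy + crop_radius + 1,
                 cx - crop_radius: cx + crop_radius + 1]
    px, py = _radial_center((crop - 1.0) ** 2)
    return ((cx - crop_radius + px) * pixel_size,
            (cy - crop_radius + py) * pixel_size)


# ---------------------------------------------------------------------------
# axial calibration and 3D localization

def build_axial_calibration(model: IPSFModel, z_range: tuple[float, float],
                            dz: float) -> AxialCalibration:
    """Tabulate c(z) on a grid and split it into monotonic branches
    between consecutive extrema of the cosine."""
    if dz <= 0:
        raise ValueError("dz must be > 0")
    z_lo, z_hi = z_range
    if z_hi <= z_lo:
        raise ValueError("empty z range")
    z = np.arange(z_lo, z_hi + dz / 2, dz)
    c = np.asarray(model.central_contrast(z), dtype=float)
    d = np.diff(c)
    # indices where monotonicity flips = interior extrema
    turn = np.flatnonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0) + 1
    bounds = np.concatenate([[0], turn, [len(z) - 1]])
    branches = [(float(z[a]), float(z[b]))
                for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    return AxialCalibration(z_grid=z, contrast=c, monotonic_branches=branches)


def _bilinear(frame: np.ndarray, px: float, py: float) -> float:
    x0, y0 = int(np.floor(px)), int(np.floor(py))
    x0 = min(max(x0, 0), frame.shape[1] - 2)
    y0 = min(max(y0, 0), frame.shape[0] - 2)
    fx, fy = px - x0, py - y0
    f = frame[y0:y0 + 2, x0:x0 + 2]
    return float(f[0, 0] * (1 - fx) * (1 - fy) + f[0, 1] * fx * (1 - fy)
                 + f[1, 0] * (1 - fx) * fy + f[1, 1] * fx * fy)


def localize_frame(frame: np.ndarray, calibration: AxialCalibration,
                   previous_z: float | None, pixel_size: float,
                   approximate_center=None, crop_radius: int = 7,
                   frame_index: int = 0) -> Localization:
    """Full 3D localization of one frame.

    Lateral centre by radial symmetry; central contrast read as the
    bilinear interpolation of (I−1) at the recovered centre; z by
    inverting the calibration on the monotonic branch containing
    ``previous_z`` (temporal continuity).  The first frame requires
    ``previous_z`` (or an explicit branch hint via the same argument)."""
    if previous_z is None:
        raise ValueError("previous_z (or a branch hint) is required to pick "
                         "the calibration branch")
    if approximate_center is None:
        approximate_center = (frame.shape[1] // 2, frame.shape[0] // 2)
    x, y = localize_lateral(frame, approximate_center, crop_radius, pixel_size)
    px, py = x / pixel_size, y / pixel_size
    contrast = _bilinear(frame, px, py) - 1.0
    branch = calibration.branch_containing(previous_z)
    z, clipped = calibration.invert_on_branch(contrast, branch)
    quality = {"branch": branch, "contrast_clipped": clipped}
    if clipped:
        warnings.warn("central contrast outside the calibration branch; "
                      "z clipped to the branch endpoint")
    return Localization(frame_index=frame_index, x=x, y=y, z=z,
                        central_contrast=contrast, quality=quality)


def track_stack(stack: FrameStack, calibration: AxialCalibration,
                start_z: float, start_center_px=None,
                crop_radius: int = 7) -> list[Localization]:
    """Localize every frame of a stack, chaining the recovered position
    and height as the next frame's search centre and branch hint."""
    locs: list[Localization] = []
    center = start_center_px
    prev_z = start_z
    for j in range(stack.n_frames):
        loc = localize_frame(stack.pixels[j], calibration, prev_z,
                             stack.pixel_size, approximate_center=center,
                             crop_radius=crop_radius, frame_index=j)
        locs.append(loc)
        center = (loc.x / stack.pixel_size, loc.y / stack.pixel_size)
        prev_z = loc.z
    return locs


# ---------------------------------------------------------------------------
# file formats

def write_stack(path, stack: FrameStack) -> None:
    """Multi-page 32-bit float TIFF, frame order = time."""
    import tifffile

    tifffile.imwrite(path, stack.pixels.astype(np.float32),
                     metadata={"pixel_size_nm": stack.pixel_size})


def read_stack(path, pixel_size: float, framerate: float) -> FrameStack:
    import tifffile

    pixels = tifffile.imread(path).astype(float)
    if pixels.ndim == 2:
        pixels = pixels[None]
    times = np.arange(len(pixels)) / framerate
    return FrameStack(pixels=pixels, pixel_size=pixel_size, frame_times=times)


def write_calibration(path, calibration: AxialCalibration) -> None:
    np.savetxt(path, np.column_stack([calibration.z_grid, calibration.contrast]),
               delimiter=",", header="z_nm,contrast", comments="")


def read_calibration(path) -> AxialCalibration:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    z, c = data[:, 0], data[:, 1]
    d = np.diff(c)
    turn = np.flatnonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0) + 1
    bounds = np.concatenate([[0], turn, [len(z) - 1]])
    branches = [(float(z[a]), float(z[b]))
                for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    return AxialCalibration(z_grid=z, contrast=c, monotonic_branches=branches)
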