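# Methods

This note records the models behind `ispt`, the estimator conventions, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Units and conventions

Coordinates are nanometres, time is seconds, frame indices are 0-based,
frame spacing is uniform at 1/framerate, and histogram bins are half-open
`[lo, hi)`. These conventions are validated at the `Trajectory` container
and assumed everywhere downstream.

## Synthetic trajectory generators

Each mobility model draws from a `numpy` `Generator` seeded by the config,
so a config fully determines its trajectory. All generators emit noiseless
ground truth; measurement noise is a separate, explicitly seeded step
(`add_localization_noise`) that adds i.i.d. Gaussian noise of per-axis std
σ_xy (σ_z axially) and records the sigmas for downstream error correction.

- **brownian** — Gaussian increments of per-axis variance 2DΔt. The 2D MSD
  is 4Dτ (6Dτ in 3D).
- **fbm** — fractional Brownian motion with Hurst exponent H = α/2,
  generated by circulant-embedding (Davies–Harte) fractional Gaussian
  noise. The embedding is exact in covariance, which is what makes tight
  exponent-recovery tests possible; increments are scaled so the per-axis
  displacement variance over lag τ is 2Dτ^α (MSD = 4Dτ^α in 2D, with D in
  nm²/s^α). fBm is used as the sub-diffusion test generator without any
  claim that it is the mechanism behind membrane sub-diffusion (obstructed
  walks and transient binding produce similar exponents); tests that pass
  on fBm validate the estimator, not the biology.
- **corral** — Brownian steps inside a reflecting disk of radius R.
  Out-of-bounds step segments are specularly reflected at the wall, one
  reflection per substep; steps are subdivided whenever their 4σ length
  exceeds R/4 so fast diffusion cannot tunnel through the wall. Uniform
  points in a disk satisfy E|r₁−r₂|² = R², which fixes the large-lag MSD
  plateau used as the generator's oracle.
- **hop** — Brownian motion on a square compartment lattice of side L
  (picket-fence picture). A step that would cross a compartment wall
  crosses with probability p_hop and is otherwise specularly reflected at
  that wall, per axis. p_hop = 1 reduces to free Brownian motion step for
  step under a shared seed.
- **bowl** — diffusion constrained to a spherical cap: a tangent-plane
  Gaussian step followed by radial reprojection onto the sphere, with the
  cap edge reflecting (polar angle folded at the cap half-angle). The cap
  opens upward (south pole of the sphere), matching a membrane pit viewed
  from the coverslip.
- **stepper** — processive transport: jump events from a Poisson process
  (rate = dwell_rate) move the particle by exactly δ along the track axis
  within a single frame interval, plus i.i.d. isotropic positional jitter.
  The noiseless on-axis walk is therefore a staircase whose jumps are
  exact multiples of δ — the ground truth for step-detection tests.
- **landing** — 3D Brownian motion above a reflecting membrane plane at
  z = 0; on contact the probe binds with a configurable probability and
  subsequently diffuses in-plane. An optional advective `flow_velocity`
  emulates micropipette-delivery flow. This matters for the imaging loop:
  a purely diffusing particle is recurrent, so a sliding temporal median
  of the frames always contains the particle near its current position and
  subtracting it distorts the PSF; with flow the probe sweeps across
  pixels fast enough that the median is particle-free.

## MSD estimation and exponent fitting

`time_averaged_msd` averages |r(t_j+τ)−r(t_j)|² over all overlapping frame
pairs inside a segment, lateral components only unless 3D is requested.

`fit_temporal_exponent` fits log MSD vs log τ by weighted least squares
with weights proportional to the pair count per lag. Localization noise
adds a constant offset to the measured 2D MSD equal to 4σ²_xy (two
localizations per displacement, two lateral axes); the fit subtracts it
before taking logs. Lags whose *measured* MSD is below 2 × 4σ²_xy are
excluded: displacements there are comparable to the precision and carry
essentially no exponent information, and the factor 2 is a configurable
default. A free-offset mode (`MSD = Γτ^α + c` by nonlinear least squares)
is provided for data whose precision is unknown; subtract-known is the
default. No motion-blur (finite-exposure) correction is applied.

Rolling analysis applies the same fit to windows of `window` frames
advanced by `stride` (default window/10, i.e. overlapping windows), with
α_i reported at the window centre time. Default fit lags are 1..window/4
frames log-thinned to ≤ 20 — capping at a quarter window keeps ≥ 3/4·window
pairs per lag; window/4 for a 1,000-frame window is 250 frames. Windows
whose fit fails carry NaN, never a fabricated value. Finite windows bias
single-window exponents slightly low (the mean rolling α of free Brownian
motion at window 1,000 is ≈ 0.98), which is well inside the ±0.05 band the
calibration tests use.

## Directional correlation

All overlapping start frames contribute a step pair (the non-overlapping
variant is an option); τ is expressed in frames and defaults to 5
regardless of framerate. Pairs with a step shorter than `min_step` are
skipped and counted — the cosine of noise-dominated steps is meaningless —
with the suggested floor σ_xy·√8, the magnitude of a displacement between
two σ_xy-noisy 2D points. C_i and its standard error are reported per
window, on the same window grid as α_i when the series object is shared.

## Occupancy maps and patches

Binning uses half-open square bins anchored at a configurable origin
(default: the bin grid containing the data minimum). Residence time is
counts × exposure time. Patch detection formalizes "extraordinary
occupancy" as: residence ≥ 1 ms (configurable), 8-connected labelling,
components with ≥ 3 bins kept. The equivalent circular diameter of a patch
is 2√(area/π) of its thresholded bin set; for digitized disks this
converges to the true diameter as the bin shrinks. Published occupancy
outlines are typically drawn by eye, so this thresholded d_eq is a
reproducible surrogate rather than a re-implementation of any manual
procedure.

## Directed-transport steps

The travel axis is the principal eigenvector of the segment's lateral
covariance, sign-oriented along net displacement (an endpoint-vector mode
exists for short segments); segments with eigenvalue ratio < 2 are flagged
as isotropic. Step extraction smooths the on-axis coordinate with a
centred moving average (default 50 frames), forms the difference of the
smoothed signal across the smoothing window — a step of height δ appears
as a bump of height δ — and takes prominence-thresholded extrema (default
2 nm) as transitions, merging transitions closer than one smoothing
window. Plateau levels are medians between transitions with half-window
margins excluded, so noiseless staircases are recovered exactly. Absolute
step sizes are histogrammed in 1 nm bins; the signed list is retained.
Track width is reported as 4 × std of the perpendicular residual (≈ 95%
Gaussian envelope); the convention travels with the number.

## Bowl fitting

The sphere fit solves the linearized sphere equation |p|² = 2p·c + k by
least squares and applies one Gauss–Newton refinement of the geometric
distance. Coplanar point sets (smallest covariance eigenvalue ~0) raise a
degeneracy error rather than returning an arbitrary sphere. Both the
sphere diameter 2R and the opening diameter (maximal extent of the points
projected perpendicular to the axis) are reported, since "bowl diameter"
is ambiguous between the two; the sphere diameter is the headline. The
bowl axis runs from the centre toward the point centroid (into the cap).
ϕ(t) is the signed angle of each point's in-plane projection about the
axis, referenced to the first frame's projection (the reference direction
is otherwise arbitrary) and unwrapped for continuity; projections shorter
than 1 nm carry the previous angle and are flagged.

## Interferometric imaging model

Detection follows I = |E_ref + E_sca|² normalized to the reference level:
1 + |s|² + 2s·cos(θ) with s = |E_sca|/|E_ref|. The |s|² term (≤ 0.25 for
s ≤ 0.5) is omitted from synthesis, keeping the axial calibration
closed-form; the package targets the weak-scatterer regime where the
cross term dominates. The PSF is phenomenological — Gaussian envelope
w(z) = w₀√(1+((z−z_f)/z_R)²) times a cosine whose phase is the physically
correct round-trip term 4π·n_m·z/λ plus a defocus-dependent quadratic
radial term β(z−z_f)r² that produces alternating rings. Exact vectorial
PSF models exist but are out of scope; the phenomenological model
preserves the two properties the analyses rely on: an axially oscillating
central contrast and defocus-dependent rings.

The speckle background is a spatially correlated Gaussian field (white
noise filtered with a Gaussian kernel of the stated correlation length,
unit-variance normalized) evolving per pixel as an AR(1) process, plus
optional Gaussian shot noise, about mean 1. Background removal subtracts
a sliding per-pixel temporal median (window clamped inside the stack at
the edges — replicated-boundary medians would erase the particle in the
first and last half-window) and re-adds 1. This is a standard, testable
subtraction scheme; symmetry-exploiting and learned background models from
the iSCAT literature are intentionally not reproduced.

Lateral localization applies gradient-based radial-symmetry centre finding
to the squared contrast (I−1)² — squaring makes the alternating ring signs
uniformly positive — inside a crop around the predicted position. Axial
localization reads the central contrast by bilinear interpolation at the
recovered centre and inverts the tabulated calibration
c(z) = 2s·cos(θ₀ + 4πn_m z/λ) on the monotonic branch containing the
previous frame's height. Heights are therefore *relative* within a branch
chosen by temporal continuity; no absolute-height method is provided, and
contrasts outside the branch are clipped with a quality flag. Branch
length is λ/(4n_m) ≈ 119 nm at λ = 635 nm in water.

## Problem sizes and tolerances in the test suite

Calibration checks use 1e5-frame trajectories at 30,000 fps (the regime
high-speed iSPT actually records), windows of 1,000 frames and stride 100;
fBm recovery uses ensembles of 10 runs per exponent; the imaging loop uses
150 frames of 160×160 px at 50 nm/px with speckle amplitude 0.002 and a
51-frame median. The imaging-loop accuracy bounds (lateral RMSE < 0.05 px,
axial < 2 nm) hold in this weak-speckle regime; a full-strength cell
background would require the out-of-scope background models.

## Known limitations

- The exponent fit assumes uniform frame spacing and a single power law
  per window; mixed regimes inside one window yield intermediate α.
- fBm is the only sub-diffusion generator; continuous-time random walks
  and obstructed percolation walks (which break ergodicity differently)
  are not emulated, so ergodicity-sensitive conclusions should not be
  extrapolated from these tests.
- Step detection merges true steps closer than the smoothing window;
  dwell times below ~smoothing_window/framerate are unresolvable.
- The imaging module's background and PSF are deliberately simplified;
  it validates the localization pipeline, not a specific microscope.
- Automatic segmentation of multi-leg directed trajectories is best-effort
  (axis-rotation change points) and flagged; curated segment bounds are
  preferred.
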