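# ispt

Trajectory analysis for interferometric single-particle tracking (iSPT).

High-speed iSCAT microscopy tracks a gold-nanoparticle-labelled membrane
protein (e.g. EGF-bound EGFR on a live cell) at tens of thousands of frames
per second with nanometre precision in 3D. The resulting trajectories mix
free diffusion, compartment-confined ("hop") diffusion, trapping in
nanodomains and membrane pits, and motor-driven directed transport — often
within a single recording. `ispt` provides the analysis chain that resolves
these regimes, together with synthetic generators for every mobility mode
and for iSCAT-like image stacks, so every stage can be validated against
known ground truth.

## What it computes

**Rolling-window anomalous diffusion.** The time-averaged mean square
displacement of window *i* is modelled as a power law

> MSD_i(τ) = Γ_α τ^α_i

whose temporal exponent α classifies motion (α = 1 free, α < 1
sub-diffusive, α > 1 super-diffusive). Fits are weighted log–log
regressions with the static localization-error offset 4σ²_xy subtracted
and noise-dominated lags excluded — omitting this correction biases α low
at high frame rates.

**Directional correlation.** For steps Δr⃗₁ = r(t+τ)−r(t) and
Δr⃗₂ = r(t+2τ)−r(t+τ) (τ = 5 frames by default),

> C_i = ⟨ Δr⃗₁·Δr⃗₂ / (|Δr⃗₁||Δr⃗₂|) ⟩_i

is 0 for memoryless walks, negative under obstacle knock-back, positive
under persistent transport.

**Occupancy (ATOM) maps.** 2D histograms of trajectory points over 4 × 4 nm
bins; counts × exposure time give per-bin residence. Bins stickier than
1 ms are grouped into 8-connected patches summarized by their equivalent
circular diameter d_eq = 2√(area/π).

**Directed transport.** Projection onto the principal travel axis, plateau
and step extraction by prominence-thresholded peak finding (motor step
sizes δ, e.g. the 4/8 nm ladder), and track-width estimation (4σ of the
perpendicular residual).

**Bowl geometry.** Least-squares sphere fits of pit-confined 3D
trajectories (sphere and opening diameters) and the unwrapped angular
position ϕ(t) of the probe about the bowl axis.

**iSCAT imaging.** Synthesis of interferometric frames from
I = 1 + 2s·cos(θ) with a ring-patterned point-spread function and dynamic
speckle background; 3D localization by radial-symmetry centre finding plus
central-contrast axial calibration.

## Worked example

A receptor confined in a reflecting 50 nm corral (D = 5×10⁵ nm²/s,
30,000 fps, 2 s) with 2 nm localization noise:

```python
import numpy as np
from ispt import (SimConfig, simulate_trajectory, add_localization_noise,
                  rolling_exponent, rolling_directional_correlation,
                  compute_atom, detect_patches, whole_trajectory_msd)

cfg = SimConfig(model="corral", corral_radius=50.0,
                diffusion_coefficient=5e5, framerate=30_000,
                n_frames=60_000, seed=4)
traj = add_localization_noise(simulate_trajectory(cfg), sigma_xy=2.0, seed=5)

series = rolling_exponent(traj, window=1000, stride=100, sigma_xy=2.0)
series = rolling_directional_correlation(traj, tau=5, series=series)
curve, fit = whole_trajectory_msd(traj, min_lag_s=1e-4, max_lag_s=1e-2,
                                  sigma_xy=2.0)
atom = compute_atom(traj, bin_size=4.0)
patches = detect_patches(atom, residence_threshold=1e-3, min_bins=3)

print(f"whole-trajectory alpha = {fit.alpha:.2f}")
print(f"rolling mean alpha_i = {np.nanmean(series.alpha):.2f}, "
      f"mean C_i = {np.nanmean(series.C):.2f}")
print(f"largest patch: d_eq = {patches[0].equivalent_circular_diameter:.0f} nm")
```

prints

```
whole-trajectory alpha = 0.60
rolling mean alpha_i = 0.70, mean C_i = -0.10
largest patch: d_eq = 104 nm
```

The confinement shows up three ways at once: a sub-diffusive exponent over
supra-corral lags, a negative directional correlation (knock-back off the
corral wall), and a single occupancy patch whose equivalent diameter
matches the 100 nm corral.

The same analyses are available from the shell:

```sh
ispt simulate --model corral --corral-radius 50 --d 5e5 --n 60000 \
     --sigma-xy 2 --seed 4 --out traj.csv
ispt analyze all traj.csv --window 1000 --stride 100 --out-dir results/
```

which writes `windows.csv` (α_i, C_i per window), `msd_whole.csv`,
`atom.csv`, `patches.csv` and a reproducibility manifest.

## Documentation

`docs/methods.md` describes the models, estimators, parameter conventions
and known limitations in detail.
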