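"""Generator correctness: degenerate limits, closed-form statistics, and
seeded determinism for every mobility model."""

import numpy as np
import pytest

from ispt import (SimConfig, Trajectory, add_localization_noise,
                  simulate_trajectory, time_averaged_msd)


def test_zero_diffusion_is_static():
    cfg = SimConfig(model="brownian", diffusion_coefficient=0.0,
                    n_frames=100, seed=3, start=[5.0, -2.0])
    traj = simulate_trajectory(cfg)
    assert np.all(traj.position == traj.position[0])
    assert np.all(traj.position[0] == [5.0, -2.0])


@pytest.mark.parametrize("model,extra", [
    ("brownian", {}),
    ("fbm", {"alpha_true": 0.6}),
    ("corral", {"corral_radius": 80.0}),
    ("hop", {"compartment_side": 100.0, "hop_probability": 0.2}),
    ("bowl", {"bowl_radius": 175.0, "bowl_cap_half_angle": 1.2,
              "dimensionality": 3}),
    ("stepper", {"step_size": 8.0, "dwell_rate": 5.0,
                 "track_axis": [0.6, 0.8], "jitter_sigma": 1.0}),
    ("landing", {"start_height": 500.0, "binding_probability": 0.5,
                 "dimensionality": 3}),
])
def test_seeded_determinism(model, extra):
    """Same config + seed reproduces the trajectory exactly."""
    cfg = SimConfig(model=model, n_frames=500, seed=42, **extra)
    a = simulate_trajectory(cfg)
    b = simulate_trajectory(cfg)
    np.testing.assert_array_equal(a.position, b.position)


def test_missing_model_parameter_names_field():
    cfg = SimConfig(model="corral", n_frames=100)
    with pytest.raises(ValueError, match="corral_radius"):
        simulate_trajectory(cfg)


def test_brownian_msd_matches_4d_dt():
    """Sample MSD at small lags within 3 standard errors of 4·D·Δt·τ."""
    D, fps = 2e5, 10_000.0
    cfg = SimConfig(model="brownian", diffusion_coefficient=D, framerate=fps,
                    n_frames=100_000, seed=9)
    traj = simulate_trajectory(cfg)
    curve = time_averaged_msd(traj, lags=np.array([1, 2, 5, 10]))
    for lag, msd, n in zip(curve.lag_s, curve.msd, curve.n_pairs):
        expected = 4.0 * D * lag
        # ~ 3 relative SE of a mean of squared Gaussians (pairs overlap, so
        # be generous with the effective n)
        tol = 3.0 * expected * np.sqrt(8.0 / n)
        assert abs(msd - expected) < tol


def test_brownian_3d_msd_matches_6d_dt():
    D, fps = 2e5, 10_000.0
    cfg = SimConfig(model="brownian", dimensionality=3,
                    diffusion_coefficient=D, framerate=fps,
                    n_frames=100_000, seed=10)
    traj = simulate_trajectory(cfg)
    curve = time_averaged_msd(traj, lags=np.array([1, 5]), use_z=True)
    for lag, msd, n in zip(curve.lag_s, curve.msd, curve.n_pairs):
        expected = 6.0 * D * lag
        assert abs(msd - expected) < 3.0 * expected * np.sqrt(8.0 / n)


def test_hop_probability_one_equals_brownian():
    """With every barrier crossing accepted the hop model degenerates to
    free Brownian motion, step for step under a shared seed."""
    common = dict(diffusion_coefficient=1e5, n_frames=2_000, seed=17)
    free = simulate_trajectory(SimConfig(model="brownian", **common))
    hop = simulate_trajectory(SimConfig(model="hop", compartment_side=100.0,
                                        hop_probability=1.0, **common))
    np.testing.assert_allclose(hop.position, free.position, atol=1e-9)


def test_hop_zero_probability_confines():
    cfg = SimConfig(model="hop", compartment_side=100.0, hop_probability=0.0,
                    diffusion_coefficient=1e6, n_frames=20_000, seed=4)
    traj = simulate_trajectory(cfg)
    # start is centred in compartment [-L/2, L/2)²; it can never leave
    assert np.all(np.abs(traj.position) <= 50.0)


def test_corral_msd_plateaus_at_r_squared():
    """Uniform-in-disk displacement pairs satisfy E|r1-r2|^2 = R^2: the
    ensemble time-averaged MSD at supra-corral lags plateaus there.
    Oracle: Monte-Carlo over 100 independent corral trajectories."""
    R, D, fps = 60.0, 5e5, 30_000.0
    lags = np.array([500, 1000])
    msds = []
    for seed in range(100):
        cfg = SimConfig(model="corral", corral_radius=R,
                        diffusion_coefficient=D, framerate=fps,
                        n_frames=2_000, seed=seed)
        traj = simulate_trajectory(cfg)
        assert np.all(np.hypot(*traj.position.T) <= R + 1e-9)
        msds.append(time_averaged_msd(traj, lags=lags).msd)
    mean_plateau = np.mean(msds)
    assert abs(mean_plateau - R * R) < 0.1 * R * R


def test_fbm_exponent_recovered():
    """Ensemble MSD of exact-covariance fBm recovers alpha_true = 0.5.
    Oracle: ensemble MSD over 50 realizations, log-log fit."""
    from ispt import fit_temporal_exponent
    from ispt.msd import MSDCurve

    lags = np.unique(np.geomspace(1, 500, 12).astype(int))
    acc = np.zeros(len(lags))
    for seed in range(50):
        cfg = SimConfig(model="fbm", alpha_true=0.5, n_frames=5_000,
                        diffusion_coefficient=1e4, seed=100 + seed)
        traj = simulate_trajectory(cfg)
        acc += time_averaged_msd(traj, lags=lags).msd
    curve = MSDCurve(lag_frames=lags, lag_s=lags / 30_000.0, msd=acc / 50,
                     n_pairs=np.full(len(lags), 5_000) - lags)
    fit = fit_temporal_exponent(curve)
    assert abs(fit.alpha - 0.5) < 0.05


def test_fbm_increment_variance_scaling():
    """Per-axis displacement variance over lag tau follows 2*D*tau^alpha."""
    alpha, D = 0.8, 1e4
    cfg = SimConfig(model="fbm", alpha_true=alpha, diffusion_coefficient=D,
                    framerate=1000.0, n_frames=50_000, seed=21)
    traj = simulate_trajectory(cfg)
    for lag in (1, 10):
        d = traj.position[lag:] - traj.position[:-lag]
        var = d.var(axis=0).mean()
        expected = 2.0 * D * (lag / 1000.0) ** alpha
        assert abs(var - expected) < 0.1 * expected


def test_stepper_noiseless_staircase_exact():
    """Noiseless on-axis walk is a staircase whose jumps are multiples of
    the step size delta."""
    cfg = SimConfig(model="stepper", step_size=8.0, dwell_rate=5.0,
                    framerate=1_000, n_frames=5_000, track_axis=[1.0, 0.0],
                    jitter_sigma=0.0, seed=2)
    traj = simulate_trajectory(cfg)
    s = traj.position[:, 0]
    assert np.all(traj.position[:, 1] == 0.0)
    jumps = np.diff(s)
    moved = jumps[jumps != 0]
    assert np.allclose(moved % 8.0, 0.0)
    np.testing.assert_allclose(s, traj.metadata["true_walked_distance"])


def test_bowl_constrained_to_cap():
    R, half = 175.0, 1.0
    cfg = SimConfig(model="bowl", dimensionality=3, bowl_radius=R,
                    bowl_cap_half_angle=half, diffusion_coefficient=1e5,
                    framerate=10_000, n_frames=5_000, seed=8)
    traj = simulate_trajectory(cfg)
    r = np.linalg.norm(traj.position, axis=1)
    np.testing.assert_allclose(r, R, rtol=1e-9)
    polar = np.arccos(np.clip(-traj.position[:, 2] / R, -1, 1))
    assert polar.max() <= half + 1e-9


def test_landing_sticks_after_binding():
    cfg = SimConfig(model="landing", dimensionality=3,
                    diffusion_coefficient=1e6, framerate=30_000,
                    n_frames=5_000, start_height=300.0,
                    binding_probability=1.0, seed=6)
    traj = simulate_trajectory(cfg)
    j = traj.metadata["bound_at_frame"]
    assert j is not None
    assert np.all(traj.position[j:, 2] == 0.0)
    assert np.all(traj.position[:j, 2] > 0.0)
    assert traj.position[0, 2] == 300.0


# ---------------------------------------------------------------------------
# localization-noise observation model

def test_noise_zero_sigma_is_identity(brownian_traj):
    out = add_localization_noise(brownian_traj, 0.0, seed=1)
    np.testing.assert_array_equal(out.position, brownian_traj.position)


def test_noise_reproducible_and_recorded(brownian_traj):
    a = add_localization_noise(brownian_traj, 3.0, seed=7)
    b = add_localization_noise(brownian_traj, 3.0, seed=7)
    np.testing.assert_array_equal(a.position, b.position)
    assert float(np.asarray(a.sigma_xy)) == 3.0


def test_static_trajectory_noise_msd_is_4_sigma_squared():
    """Measured MSD of a noisy static point equals 4·sigma² at every lag.
    Oracle: closed form vs sample over 1e5 frames."""
    sigma = 3.0
    static = Trajectory(position=np.zeros((100_000, 2)), framerate=1000.0)
    noisy = add_localization_noise(static, sigma, seed=12)
    curve = time_averaged_msd(noisy, lags=np.array([1, 7, 50]))
    np.testing.assert_allclose(curve.msd, 4.0 * sigma ** 2, rtol=0.03)


def test_negative_sigma_rejected(brownian_traj):
    with pytest.raises(ValueError):
        add_localization_noise(brownian_traj, -1.0)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(model="warp")
    with pytest.raises(ValueError):
        SimConfig(alpha_true=2.5, model="fbm")
    with pytest.raises(ValueError):
        SimConfig(hop_probability=1.5, model="hop", compartment_side=100.0)
    with pytest.raises(ValueError):
        SimConfig(n_frames=1)
    with pytest.raises(ValueError):
        SimConfig(framerate=0.0)
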