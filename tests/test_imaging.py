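"""iSCAT frame synthesis, speckle background, background removal, and 3D
localization (radial-symmetry lateral + central-contrast axial)."""

import numpy as np
import pytest

from ispt import (BackgroundParams, FrameStack, IPSFModel, SimConfig,
                  Trajectory, build_axial_calibration, localize_frame,
                  localize_lateral, remove_background, simulate_trajectory,
                  synthesize_background_stack, synthesize_frame,
                  synthesize_stack, track_stack)
from ispt.imaging import read_calibration, read_stack, write_calibration, write_stack


@pytest.fixture
def model():
    return IPSFModel(scattering_amplitude=0.1, phase_offset=0.0,
                     envelope_waist=3.0, ring_phase_coefficient=2e-4,
                     pixel_size=80.0, wavelength=635.0, medium_index=1.33)


class TestFrameSynthesis:
    def test_no_scatterer_uniform(self, model):
        m = IPSFModel(scattering_amplitude=0.0, pixel_size=80.0)
        frame = synthesize_frame(m, (32 * 80, 32 * 80, 0.0), (64, 64))
        np.testing.assert_array_equal(frame, 1.0)

    def test_central_contrast_limit(self, model):
        """At the particle pixel with zero total phase, I = 1 + 2s."""
        frame = synthesize_frame(model, (32 * 80, 32 * 80, 0.0), (64, 64))
        assert frame[32, 32] == pytest.approx(1.0 + 2 * 0.1)

    def test_axial_phase_period(self, model):
        """Central contrast repeats every lambda/(2 n_m) in z."""
        period = model.wavelength / (2 * model.medium_index)
        a = synthesize_frame(model, (32 * 80, 32 * 80, 50.0), (64, 64))
        b = synthesize_frame(model, (32 * 80, 32 * 80, 50.0 + period), (64, 64))
        assert a[32, 32] == pytest.approx(b[32, 32], abs=1e-9)

    def test_particle_outside_frame_rejected(self, model):
        with pytest.raises(ValueError):
            synthesize_frame(model, (-100.0, 0.0, 0.0), (64, 64))

    def test_deterministic(self, model):
        a = synthesize_frame(model, (1000.0, 1500.0, 30.0), (32, 32))
        b = synthesize_frame(model, (1000.0, 1500.0, 30.0), (32, 32))
        np.testing.assert_array_equal(a, b)


class TestBackground:
    def test_zero_amplitude_shot_only(self):
        p = BackgroundParams(speckle_amplitude=0.0, shot_noise=0.0)
        stack = synthesize_background_stack(p, (32, 32), 5, seed=1)
        np.testing.assert_array_equal(stack.pixels, 1.0)

    def test_frozen_speckle_ar_one(self):
        p = BackgroundParams(speckle_amplitude=0.01, ar_coefficient=1.0,
                             shot_noise=0.0)
        stack = synthesize_background_stack(p, (32, 32), 10, seed=2)
        for j in range(1, 10):
            np.testing.assert_array_equal(stack.pixels[j], stack.pixels[0])

    def test_mean_near_one(self):
        p = BackgroundParams(speckle_amplitude=0.01, shot_noise=0.002)
        stack = synthesize_background_stack(p, (64, 64), 20, seed=3)
        assert abs(stack.pixels.mean() - 1.0) < 3 * 0.01

    def test_spatial_autocorrelation_width(self):
        """Autocorrelation of a Gaussian-filtered white field is Gaussian
        with width sqrt(2) x kernel sigma (oracle: closed form)."""
        sigma = 4.0
        p = BackgroundParams(speckle_amplitude=0.01, correlation_length=sigma,
                             shot_noise=0.0)
        stack = synthesize_background_stack(p, (256, 256), 1, seed=4)
        f = stack.pixels[0] - stack.pixels[0].mean()
        ac = np.fft.fftshift(np.fft.ifft2(np.abs(np.fft.fft2(f)) ** 2).real)
        row = ac[128] / ac[128, 128]
        x = np.arange(256) - 128
        measured = np.sqrt(np.sum(row[118:139] * x[118:139] ** 2)
                           / np.sum(row[118:139]))
        assert measured == pytest.approx(np.sqrt(2) * sigma, rel=0.2)

    def test_seeded_determinism(self):
        p = BackgroundParams()
        a = synthesize_background_stack(p, (16, 16), 3, seed=9)
        b = synthesize_background_stack(p, (16, 16), 3, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestRemoveBackground:
    def test_static_background_removed(self):
        p = BackgroundParams(speckle_amplitude=0.02, ar_coefficient=1.0,
                             shot_noise=0.0)
        stack = synthesize_background_stack(p, (32, 32), 21, seed=5)
        clean = remove_background(stack, 21)
        np.testing.assert_allclose(clean.pixels, 1.0, atol=1e-12)

    def test_window_validation(self):
        stack = FrameStack(pixels=np.ones((10, 16, 16)), pixel_size=80.0,
                           frame_times=np.arange(10.0))
        with pytest.raises(ValueError):
            remove_background(stack, 11)  # larger than the stack
        with pytest.raises(ValueError):
            remove_background(stack, 4)  # even

    def test_fast_particle_contrast_preserved(self, model):
        """Frozen speckle + particle sweeping the field: post-removal
        contrast at the particle matches the synthesized contrast within
        5%."""
        n, fsz = 55, 128
        x = (10.0 + 2.0 * np.arange(n)) * 80.0  # 2 px/frame sweep
        pos = np.column_stack([x, np.full(n, 64 * 80.0), np.zeros(n)])
        traj = Trajectory(position=pos, framerate=1000.0)
        bgp = BackgroundParams(speckle_amplitude=0.01, ar_coefficient=1.0,
                               shot_noise=0.0)
        stack = synthesize_stack(model, traj, (fsz, fsz), background=bgp, seed=6)
        clean = remove_background(stack, 15)
        j = n // 2
        px = int(round(pos[j, 0] / 80.0))
        expected = 2 * model.scattering_amplitude  # phase 0 at z=0
        measured = clean.pixels[j, 64, px] - 1.0
        assert measured == pytest.approx(expected, rel=0.05)


class TestLateralLocalization:
    def test_pixel_centered_psf(self, model):
        frame = synthesize_frame(model, (32 * 80.0, 32 * 80.0, 40.0), (64, 64))
        x, y = localize_lateral(frame, (32, 32), 7, 80.0)
        assert abs(x / 80.0 - 32) < 1e-3
        assert abs(y / 80.0 - 32) < 1e-3

    def test_subpixel_offset_recovered(self, model):
        truth = ((32 + 0.30) * 80.0, (32 - 0.30) * 80.0)
        frame = synthesize_frame(model, (*truth, 40.0), (64, 64))
        x, y = localize_lateral(frame, (32, 32), 7, 80.0)
        assert abs(x - truth[0]) / 80.0 < 0.05
        assert abs(y - truth[1]) / 80.0 < 0.05

    def test_flat_frame_no_detection(self):
        with pytest.raises(ValueError, match="no detection"):
            localize_lateral(np.ones((64, 64)), (32, 32), 7, 80.0)

    def test_crop_outside_frame(self, model):
        frame = synthesize_frame(model, (32 * 80.0, 32 * 80.0, 0.0), (64, 64))
        with pytest.raises(ValueError, match="crop"):
            localize_lateral(frame, (2, 2), 7, 80.0)


class TestAxialCalibration:
    def test_branch_length_is_quarter_wavelength(self, model):
        cal = build_axial_calibration(model, (0.0, 500.0), 0.1)
        expected = model.wavelength / (4 * model.medium_index)  # ~119.4 nm
        interior = cal.monotonic_branches[1:-1]
        for lo, hi in interior:
            assert hi - lo == pytest.approx(expected, abs=0.5)

    def test_contrast_extremes(self, model):
        cal = build_axial_calibration(model, (0.0, 1000.0), 0.1)
        assert cal.contrast.max() == pytest.approx(2 * 0.1, abs=1e-4)
        assert cal.contrast.min() == pytest.approx(-2 * 0.1, abs=1e-4)

    def test_round_trip_inversion(self, model):
        dz = 0.2
        cal = build_axial_calibration(model, (0.0, 500.0), dz)
        for z in (30.0, 75.0, 150.0, 200.0):
            branch = cal.branch_containing(z)
            zhat, clipped = cal.invert_on_branch(
                float(model.central_contrast(z)), branch)
            assert not clipped
            assert abs(zhat - z) < dz

    def test_empty_range_rejected(self, model):
        with pytest.raises(ValueError):
            build_axial_calibration(model, (100.0, 100.0), 1.0)

    def test_calibration_file_round_trip(self, model, tmp_path):
        cal = build_axial_calibration(model, (0.0, 300.0), 0.5)
        path = tmp_path / "calib.csv"
        write_calibration(path, cal)
        back = read_calibration(path)
        np.testing.assert_allclose(back.contrast, cal.contrast, atol=1e-12)
        assert back.monotonic_branches == cal.monotonic_branches


class TestLocalizeFrame:
    def test_missing_branch_hint_errors(self, model):
        cal = build_axial_calibration(model, (0.0, 300.0), 0.5)
        frame = synthesize_frame(model, (32 * 80.0, 32 * 80.0, 50.0), (64, 64))
        with pytest.raises(ValueError, match="previous_z"):
            localize_frame(frame, cal, None, 80.0)

    def test_z_ramp_recovered_within_2nm(self, model):
        """Noiseless frames along a z ramp inside one branch: RMS error
        below 2 nm."""
        cal = build_axial_calibration(model, (0.0, 300.0), 0.25)
        zs = np.linspace(20.0, 100.0, 30)  # inside branch (0, ~119)
        errors = []
        prev = 25.0
        for z in zs:
            frame = synthesize_frame(model, (32 * 80.0, 32 * 80.0, z), (64, 64))
            loc = localize_frame(frame, cal, prev, 80.0)
            errors.append(loc.z - z)
            prev = loc.z
        assert np.sqrt(np.mean(np.square(errors))) < 2.0

    def test_contrast_clipped_flag(self, model):
        cal = build_axial_calibration(model, (0.0, 300.0), 0.5)
        frame = synthesize_frame(model, (32 * 80.0, 32 * 80.0, 0.0), (64, 64))
        frame = 1.0 + (frame - 1.0) * 1.5  # contrast beyond 2s
        with pytest.warns(UserWarning, match="clipped"):
            loc = localize_frame(frame, cal, 10.0, 80.0)
        assert loc.quality["contrast_clipped"]


def test_stack_tiff_round_trip(tmp_path):
    stack = FrameStack(pixels=np.random.default_rng(0).normal(1, 0.01, (5, 32, 32)),
                       pixel_size=80.0, frame_times=np.arange(5) / 1000.0)
    path = tmp_path / "stack.tif"
    write_stack(path, stack)
    back = read_stack(path, pixel_size=80.0, framerate=1000.0)
    np.testing.assert_allclose(back.pixels, stack.pixels, atol=1e-6)


def test_landing_loop_closure():
    """Full loop: landing trajectory -> interferometric frames on dynamic
    speckle -> temporal-median background removal -> 3D localization.
    Lateral RMSE < 0.05 px and axial RMSE < 2 nm within one branch."""
    px, fps, fsz, n = 50.0, 30_000.0, 160, 150
    m = IPSFModel(scattering_amplitude=0.1, phase_offset=-np.pi / 4,
                  envelope_waist=3.0, ring_phase_coefficient=2e-4,
                  pixel_size=px)
    cal = build_axial_calibration(m, (-120.0, 60.0), 0.25)
    cfg = SimConfig(model="landing", dimensionality=3, framerate=fps,
                    n_frames=n, diffusion_coefficient=5e3, start_height=10.0,
                    binding_probability=0.0,
                    flow_velocity=(0.7 * px * fps, 0.0, 0.0), seed=7)
    traj = simulate_trajectory(cfg)
    pos = traj.position.copy()
    pos[:, 0] += 20 * px
    pos[:, 1] += (fsz // 2) * px
    traj = Trajectory(position=pos, framerate=fps)
    bg = BackgroundParams(speckle_amplitude=0.002, correlation_length=3.0,
                          ar_coefficient=0.995, shot_noise=2e-4)
    stack = synthesize_stack(m, traj, (fsz, fsz), background=bg, seed=107)
    clean = remove_background(stack, 51)
    locs = track_stack(clean, cal, start_z=10.0,
                       start_center_px=(20, fsz // 2), crop_radius=8)
    rec = np.array([[l.x, l.y, l.z] for l in locs])
    lat_rmse = np.sqrt(np.mean((rec[:, :2] - pos[:, :2]) ** 2)) / px
    z_rmse = np.sqrt(np.mean((rec[:, 2] - pos[:, 2]) ** 2))
    assert lat_rmse < 0.05
    assert z_rmse < 2.0
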