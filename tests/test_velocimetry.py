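"""PIV displacement recovery, profile averaging, shear-rate extraction."""

import numpy as np
import pytest

from hemorheo.errors import (ConfigurationError, DetectionError, DomainError,
                             FitError)
from hemorheo.velocimetry import (ParticleImagePair, VelocityProfile,
                                  detect_blood_layer,
                                  displacement_to_velocity,
                                  estimate_shear_rate, piv_multipass,
                                  remove_background, select_dt_ms,
                                  temporal_average_profile, velocity_rms)

from conftest import render_particles


@pytest.fixture(scope="module")
def particle_scene():
    rng = np.random.default_rng(5)
    shape = (256, 256)
    n = int(0.03 * shape[0] * shape[1])
    pos = rng.uniform([0, 0], list(shape), (n, 2))
    return rng, shape, pos


class TestBackgroundRemoval:
    def test_identical_frames_become_zero(self):
        f = np.random.default_rng(0).uniform(0, 10, (32, 32))
        out = remove_background([f, f.copy(), f.copy()])
        for o in out:
            np.testing.assert_allclose(o, 0.0)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(1)
        frames = [rng.uniform(0, 50, (32, 32)) for _ in range(4)]
        base = remove_background(frames)
        shifted = remove_background([f + 17.3 for f in frames])
        for a, b in zip(base, shifted):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_moving_particle_on_constant_background(self):
        a = np.full((16, 16), 5.0)
        b = a.copy()
        a[4, 4] += 100.0
        b[4, 10] += 100.0
        out = remove_background([a, b])
        assert out[0][4, 10] == 0.0 and out[1][4, 4] == 0.0
        assert out[0][4, 4] == 100.0

    def test_single_frame_rejected(self):
        with pytest.raises(ConfigurationError):
            remove_background([np.zeros((8, 8))])

    def test_illumination_gradient_does_not_shift_peak(self, particle_scene):
        """Static ramp removed by background subtraction leaves the
        recovered displacement within 0.05 px of the gradient-free case."""
        rng, shape, pos = particle_scene
        shift = 6.0
        a = render_particles(rng, shape, pos)
        b = render_particles(rng, shape, pos + [0, shift])
        ramp = 40.0 * np.linspace(0, 1, shape[1])[None, :]
        # the temporal minimum needs several frames with independent
        # particle positions to converge to the static background
        others = [render_particles(rng, shape,
                                   rng.uniform([0, 0], list(shape),
                                               (len(pos), 2))) + ramp
                  for _ in range(8)]
        a_r, b_r, *_ = remove_background([a + ramp, b + ramp] + others)
        clean = piv_multipass(ParticleImagePair(a, b, 1.0, 1.0))
        ramped = piv_multipass(ParticleImagePair(a_r, b_r, 1.0, 1.0))
        sel = clean.valid & ramped.valid
        diff = np.abs(clean.u[sel] - ramped.u[sel])
        # a handful of windows keep residue where particles overlapped in
        # the minimum image; the bulk must be gradient-free
        assert np.percentile(diff, 95) < 0.05
        assert diff.mean() < 0.02


class TestPivMultipass:
    def test_identical_frames_give_zero_displacement(self, particle_scene):
        rng, shape, pos = particle_scene
        a = render_particles(rng, shape, pos)
        f = piv_multipass(ParticleImagePair(a, a.copy(), 1.0, 1.0))
        assert np.abs(f.u[f.valid]).max() < 0.01
        assert np.abs(f.v[f.valid]).max() < 0.01

    @pytest.mark.parametrize("shift", [2.0, 6.0, 10.0])
    def test_uniform_shift_recovery(self, particle_scene, shift):
        """Displacement error stays below 0.1 px RMS across the working
        6-10 px range (and below)."""
        rng, shape, pos = particle_scene
        noise = np.random.default_rng(int(shift))
        a = render_particles(rng, shape, pos) + noise.normal(0, 2, shape)
        b = render_particles(rng, shape, pos + [0, shift]) \
            + noise.normal(0, 2, shape)
        f = piv_multipass(ParticleImagePair(a, b, 1.0, 1.0))
        err = f.u[f.valid] - shift
        assert np.sqrt(np.mean(err ** 2)) <= 0.1
        assert f.valid.mean() > 0.9

    def test_linear_shear_slope_recovery(self, particle_scene):
        """Recovered transverse slope of u within 5% of the generator's."""
        rng, shape, pos = particle_scene
        slope = 0.03
        disp = 2.0 + slope * pos[:, 0]
        a = render_particles(rng, shape, pos)
        b = render_particles(rng, shape,
                             np.column_stack([pos[:, 0], pos[:, 1] + disp]))
        f = piv_multipass(ParticleImagePair(a, b, 1.0, 1.0))
        # frame-edge windows see a truncated particle field; use interior
        rows = slice(1, -1)
        row_u = np.array([f.u[i][f.valid[i]].mean()
                          for i in range(f.u.shape[0])])
        fit = np.polyfit(f.y[rows], row_u[rows], 1)[0]
        assert fit == pytest.approx(slope, rel=0.05)

    def test_blank_windows_flagged_not_raised(self):
        rng = np.random.default_rng(2)
        shape = (128, 128)
        pos = rng.uniform([0, 0], [64, 128], (200, 2))  # bottom half empty
        a = render_particles(rng, shape, pos)
        f = piv_multipass(ParticleImagePair(a, a.copy(), 1.0, 1.0))
        assert f.u.shape == f.valid.shape  # flat windows did not raise

    def test_small_frames_rejected(self):
        with pytest.raises(DomainError):
            piv_multipass(ParticleImagePair(np.zeros((32, 32)),
                                            np.zeros((32, 32)), 1.0, 1.0))


class TestScaling:
    def test_printed_scale_example(self):
        f = _unit_field(10.0)
        out = displacement_to_velocity(f, dt_ms=2.0, pixel_scale_um=0.27)
        assert out.u.flat[0] == pytest.approx(1.35)
        assert out.units == "mm/s"

    def test_zero_displacement_zero_velocity(self):
        out = displacement_to_velocity(_unit_field(0.0), 2.0, 0.27)
        assert out.u.flat[0] == 0.0

    def test_second_arithmetic_example(self):
        out = displacement_to_velocity(_unit_field(8.0), 15.0, 0.2)
        assert out.u.flat[0] == pytest.approx(0.10667, abs=1e-5)

    def test_dt_equivariance(self):
        c = 3.0
        a = displacement_to_velocity(_unit_field(7.0), 2.0, 0.27)
        b = displacement_to_velocity(_unit_field(7.0), 2.0 * c, 0.27)
        assert a.u.flat[0] == pytest.approx(c * b.u.flat[0], rel=1e-12)

    def test_dt_selection_targets_working_range(self):
        dt = select_dt_ms(max_speed_mm_s=2.0, pixel_scale_um=0.27)
        assert 2.0 * dt / 0.27 == pytest.approx(8.0)


def _unit_field(px):
    from hemorheo.velocimetry import VectorField

    one = np.full((1, 1), float(px))
    return VectorField(x=np.zeros(1), y=np.zeros(1), u=one, v=one * 0,
                       valid=np.ones((1, 1), bool),
                       replaced=np.zeros((1, 1), bool))


class TestAveragingAndRms:
    def test_rms_hand_examples(self):
        assert velocity_rms(np.array([1.0, 2.0, 3.0])) == pytest.approx(1.0)
        assert velocity_rms(np.array([0.0, 2.0])) == pytest.approx(np.sqrt(2))
        assert velocity_rms(np.array([4.0, 4.0, 4.0])) == 0.0

    def test_rms_equals_sample_standard_deviation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(2.0, 0.5, 40)
            assert velocity_rms(x) == pytest.approx(np.std(x, ddof=1),
                                                    rel=1e-12)

    def test_single_field_rejected(self):
        with pytest.raises(DomainError):
            velocity_rms(np.array([1.0]))

    def test_profile_mean_and_rms(self):
        fields = [_grid_field(v) for v in (1.0, 2.0, 3.0)]
        prof = temporal_average_profile(fields, pixel_scale_um=0.5)
        np.testing.assert_allclose(prof.u_mm_s, 2.0)
        np.testing.assert_allclose(prof.rms_mm_s, 1.0)
        assert prof.n_fields == 3
        np.testing.assert_allclose(prof.y_um, fields[0].y * 0.5)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(DomainError):
            temporal_average_profile([_grid_field(1.0, n=4),
                                      _grid_field(1.0, n=5)])


def _grid_field(value, n=4):
    from hemorheo.velocimetry import VectorField

    u = np.full((n, n), float(value))
    return VectorField(x=np.arange(n, dtype=float),
                       y=np.arange(n, dtype=float), u=u, v=0 * u,
                       valid=np.ones((n, n), bool),
                       replaced=np.zeros((n, n), bool))


class TestBloodLayer:
    def test_block_profile(self):
        y = np.linspace(0, 110, 221)
        d = np.where(y <= 22.0, 1.0, 0.0)
        lo, hi = detect_blood_layer(y, d)
        assert lo == pytest.approx(0.0, abs=0.5)
        assert hi == pytest.approx(22.0, abs=0.5)

    def test_uniform_density_spans_channel(self):
        y = np.linspace(0, 110, 100)
        lo, hi = detect_blood_layer(y, np.ones_like(y))
        assert (lo, hi) == (0.0, 110.0)

    def test_empty_profile_raises(self):
        with pytest.raises(DetectionError):
            detect_blood_layer(np.linspace(0, 1, 10), np.zeros(10))

    def test_synthetic_layer_width(self, coflow_bundle):
        """Detected layer width matches the generated blood-stream width."""
        pairs = coflow_bundle["pairs"]
        truth = coflow_bundle["truth"]
        mean_img = np.mean([p.frame_a for p in pairs], axis=0)
        dens = mean_img.mean(axis=1)
        scale = pairs[0].pixel_scale_um
        y = (np.arange(dens.size) + 0.5) * scale
        lo, hi = detect_blood_layer(y, dens)
        true_width = (0.5 + truth.interface_Y) * truth.geometry.width_um
        assert (hi - lo) == pytest.approx(true_width, abs=2.0)


class TestShearRate:
    def test_exact_line(self):
        y = np.linspace(0, 100, 21)
        prof = VelocityProfile(y_um=y, u_mm_s=0.002 * y,
                               rms_mm_s=np.zeros_like(y), n_fields=10)
        est = estimate_shear_rate(prof, (0.0, 100.0))
        assert est.shear_rate_s1 == pytest.approx(2.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_uniform_profile_zero_shear(self):
        y = np.linspace(0, 100, 21)
        prof = VelocityProfile(y, np.full_like(y, 1.5), np.zeros_like(y), 5)
        assert estimate_shear_rate(prof, (0, 100)).shear_rate_s1 \
            == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points(self):
        prof = VelocityProfile(np.array([0.0, 50.0, 100.0]),
                               np.zeros(3), np.zeros(3), 5)
        with pytest.raises(FitError):
            estimate_shear_rate(prof, (40.0, 60.0))

    def test_fd_mid_plane_slope(self, coflow_bundle):
        """Shear from the FD field profile matches the recorded truth."""
        field = coflow_bundle["field"]
        truth = coflow_bundle["truth"]
        y, u = field.mid_plane_profile()
        w = field.geometry.width_um
        prof = VelocityProfile(y_um=y + 0.5 * w, u_mm_s=u,
                               rms_mm_s=np.zeros_like(u), n_fields=2)
        layer = (0.0, (0.5 + truth.interface_Y) * w)
        est = estimate_shear_rate(prof, layer)
        assert est.shear_rate_s1 == pytest.approx(
            truth.mid_plane_shear_rate_s1, rel=0.01)


class TestEndToEnd:
    def test_shear_rate_recovery_within_five_percent(self, coflow_bundle,
                                                     piv_fields):
        pairs = coflow_bundle["pairs"]
        truth = coflow_bundle["ptruth"]
        prof = temporal_average_profile(piv_fields,
                                        pixel_scale_um=pairs[0].pixel_scale_um)
        mean_img = np.mean([p.frame_a for p in pairs], axis=0)
        dens = mean_img.mean(axis=1)
        y = (np.arange(dens.size) + 0.5) * pairs[0].pixel_scale_um
        layer = detect_blood_layer(y, dens)
        est = estimate_shear_rate(prof, layer)
        assert est.shear_rate_s1 == pytest.approx(truth.shear_rate_s1,
                                                  rel=0.05)
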