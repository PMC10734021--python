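"""Microbubble transport simulation and frame rendering."""

import numpy as np
import pytest

import ulmflow as uf
from ulmflow.simulate import CPS_WEIGHTS, _sample_flux_weighted_offsets
from conftest import gaussian_frame


class TestSeeding:
    def test_zero_concentration_never_arrives(self, rng):
        for _ in range(20):
            assert uf.seed_bubbles(0.0, 0.02, 0.1, rng) == []

    def test_zero_interval_never_arrives(self, rng):
        assert uf.seed_bubbles(6.4e6, 0.02, 0.0, rng) == []

    def test_arrival_rate_matches_concentration_times_flow(self, rng):
        # lambda = C * Q = 6.4e6 /mL * 0.02 mL/min = 128000/min ~ 2133.3/s
        lam = 6.4e6 * 0.02 / 60.0
        dt, n_steps = 0.001, 2000
        counts = [len(uf.seed_bubbles(6.4e6, 0.02, dt, rng)) for _ in range(n_steps)]
        total = sum(counts)
        expected = lam * dt * n_steps
        se = np.sqrt(expected)
        assert abs(total - expected) < 3 * se

    def test_entry_offsets_flux_weighted(self, rng):
        """Entry density across the width follows the parabolic profile."""
        u = _sample_flux_weighted_offsets(20000, rng)
        assert np.all(np.abs(u) <= 0.95)
        # E[u^2] of the truncated density ~ int u^2 (1-u^2) / int (1-u^2)
        um = 0.95
        num = um**3 / 3 - um**5 / 5
        den = um - um**3 / 3
        assert np.mean(u**2) == pytest.approx(num / den, abs=0.01)


class TestAdvection:
    def test_zero_dt_is_identity(self, bifurcation_net, rng):
        b = uf.Bubble(0, "main_in", 0.2, 0.3)
        out = uf.advect([b], bifurcation_net, 0.0, rng)
        assert out[0].s_mm == b.s_mm and out[0].segment == "main_in"

    def test_centerline_moves_at_peak_speed(self, bifurcation_net, rng):
        b = uf.Bubble(0, "main_in", 0.1, 0.0)
        dt = 0.004
        out = uf.advect([b], bifurcation_net, dt, rng)
        v = bifurcation_net["main_in"].mean_velocity_mm_s
        assert out[0].s_mm - 0.1 == pytest.approx(1.5 * v * dt)

    def test_outlet_exit_removes_bubble(self, bifurcation_net, rng):
        b = uf.Bubble(0, "main_out", bifurcation_net["main_out"].length_mm - 1e-6, 0.0)
        out = uf.advect([b], bifurcation_net, 1.0, rng)
        assert out == []

    def test_junction_choice_proportional_to_flow(self, rng):
        net = uf.flow_split(
            uf.build_bifurcation(300, 100, 45), uf.FlowConfig(0.02, "resistance")
        )
        # place many bubbles just before the junction and step across it
        n = 4000
        eps = 1e-6
        bubbles = [
            uf.Bubble(i, "main_in", net["main_in"].length_mm - eps, 0.0)
            for i in range(n)
        ]
        out = uf.advect(bubbles, net, 0.002, rng)
        frac_branch = np.mean([b.segment == "branch" for b in out])
        expected = net["branch"].flow_rate_ml_min / 0.02  # 1/28
        assert frac_branch == pytest.approx(expected, abs=3 * np.sqrt(expected / n) + 0.01)

    def test_radiation_drift_sticks_at_far_wall_only(self, bifurcation_net, rng):
        rf = uf.RadiationForce(drift_mm_s=2.0, stick_probability=0.5)
        bubbles = [
            uf.Bubble(i, "main_in", 0.01, u)
            for i, u in enumerate(np.linspace(-0.9, 0.9, 50))
        ]
        for _ in range(100):
            bubbles = uf.advect(bubbles, bifurcation_net, 0.004, rng, rf)
        stuck = [b for b in bubbles if b.stuck]
        assert stuck, "expected some bubbles to stick under strong drift"
        # far wall is +z; the main channel normal has n_z > 0 at u > 0
        assert all(b.lateral_offset > 0.9 for b in stuck)


class TestScattererField:
    def test_zero_density_empty(self, rng):
        pos, amp = uf.make_scatterer_field(0.0, 64, 64, rng)
        assert pos.shape == (0, 2)

    def test_count_binomial(self, rng):
        counts = [
            uf.make_scatterer_field(0.005, 128, 128, rng)[0].shape[0]
            for _ in range(50)
        ]
        expected = 0.005 * 128 * 128  # ~82
        se = np.sqrt(expected / 50)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_same_seed_same_field(self):
        a = uf.make_scatterer_field(0.01, 64, 64, np.random.default_rng(7))
        b = uf.make_scatterer_field(0.01, 64, 64, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestRendering:
    def test_cps_cancels_linear_scatterers_exactly(self, rng):
        assert sum(CPS_WEIGHTS) == 0.0
        cfg = uf.AcquisitionConfig(rows=64, cols=64, noise_sd=0.0, mode="CPS")
        scat = uf.make_scatterer_field(0.01, 64, 64, rng)
        frame = uf.render_frame(np.empty((0, 2)), None, scat, cfg)
        assert np.all(frame == 0.0)

    def test_empty_scene_is_zero(self):
        cfg = uf.AcquisitionConfig(rows=32, cols=32, noise_sd=0.0)
        frame = uf.render_frame(np.empty((0, 2)), None, None, cfg)
        assert np.all(frame == 0.0)

    def test_bmode_single_bubble_equals_psf_oracle(self):
        cfg = uf.AcquisitionConfig(
            rows=32, cols=32, noise_sd=0.0, mode="BMODE", pixel_size_mm=0.025,
            origin_z_mm=0.0,
        )
        # bubble at pixel centre (row 10, col 14)
        x = (14 + 0.5) * 0.025
        z = (10 + 0.5) * 0.025
        frame = uf.render_frame(np.array([[x, z]]), None, None, cfg)
        oracle = gaussian_frame((32, 32), [(10, 14)], [1.0], cfg.psf_sigma_px)
        # renderer truncates the PSF support at 4 sigma; tails beyond that
        # are below 3.4e-4 of the peak
        np.testing.assert_allclose(frame, oracle, atol=4e-4)
        np.testing.assert_allclose(
            frame[4:17, 8:21], oracle[4:17, 8:21], atol=1e-12
        )

    def test_bmode_includes_scatterers(self, rng):
        cfg = uf.AcquisitionConfig(rows=64, cols=64, noise_sd=0.0, mode="BMODE")
        scat = uf.make_scatterer_field(0.01, 64, 64, rng)
        frame = uf.render_frame(np.empty((0, 2)), None, scat, cfg)
        assert frame.max() > 0


class TestGenerateSequence:
    @pytest.fixture(scope="class")
    @staticmethod
    def sequence():
        net = uf.build_bifurcation(300, 300, 45, lengths_mm=(0.5, 1.0, 1.0))
        flow = uf.FlowConfig(0.02, "symmetric")
        acq = uf.AcquisitionConfig(rows=64, cols=64, n_frames=200, rng_seed=11)
        return net, flow, acq, uf.generate_sequence(net, flow, acq)

    def test_shapes_and_metadata(self, sequence):
        _, _, acq, (stack, truth) = sequence
        assert stack.shape == (200, 64, 64)
        assert stack.frame_rate_hz == 250.0
        assert truth.channel_mask.shape == (64, 64)

    def test_reproducible_from_seed(self, sequence):
        net, flow, acq, (stack, truth) = sequence
        stack2, truth2 = uf.generate_sequence(net, flow, acq)
        np.testing.assert_array_equal(stack.data, stack2.data)
        assert truth.positions.equals(truth2.positions)

    def test_true_positions_inside_channel_mask(self, sequence):
        _, _, acq, (stack, truth) = sequence
        pos = truth.positions
        x0, z0 = acq.origin_mm
        cc = np.floor((pos.x_mm - x0) / acq.pixel_size_mm).astype(int).clip(0, 63)
        rr = np.floor((pos.z_mm - z0) / acq.pixel_size_mm).astype(int).clip(0, 63)
        assert truth.channel_mask[rr, cc].mean() > 0.99  # rounding at edges only

    def test_zero_concentration_gives_empty_ground_truth(self):
        net = uf.build_bifurcation(300, 300, 45, lengths_mm=(0.5, 1.0, 1.0))
        acq = uf.AcquisitionConfig(
            rows=64, cols=64, n_frames=20, concentration_per_ml=0.0, rng_seed=5
        )
        stack, truth = uf.generate_sequence(net, uf.FlowConfig(0.02), acq)
        assert len(truth.positions) == 0
        assert stack.n_frames == 20

    def test_track_speeds_match_profile(self, sequence):
        """Ground-truth step speeds agree with the configured laminar field."""
        net, _, acq, (stack, truth) = sequence
        pos = truth.positions
        main = pos[pos.segment == "main_in"]
        v_mean = None
        for tid, g in main.groupby("track_id"):
            if len(g) < 3:
                continue
            g = g.sort_values("frame")
            step = np.hypot(np.diff(g.x_mm), np.diff(g.z_mm)) * acq.frame_rate_hz
            expected = g.speed_mm_s.iloc[:-1].to_numpy()
            np.testing.assert_allclose(step, expected, rtol=0.05, atol=0.05)
            v_mean = True
        assert v_mean, "no track long enough to check"

    def test_tiff_round_trip(self, sequence, tmp_path):
        _, _, _, (stack, _) = sequence
        stack.save(tmp_path / "stack.tif")
        back = uf.FrameStack.load(tmp_path / "stack.tif")
        np.testing.assert_allclose(back.data, stack.data, atol=1e-6)
        assert back.frame_rate_hz == stack.frame_rate_hz
        assert back.pixel_size_mm == stack.pixel_size_mm


def test_population_flux_balance():
    """Mean bubbles per frame approaches arrival rate x mean transit time."""
    net = uf.build_single_channel(300, length_mm=1.2)
    net = uf.flow_split(net, uf.FlowConfig(0.02))
    acq = uf.AcquisitionConfig(
        rows=64, cols=64, n_frames=600, rng_seed=21, detectable_fraction=0.05
    )
    stack, truth = uf.generate_sequence(net, uf.FlowConfig(0.02), acq)
    lam = acq.concentration_per_ml * acq.detectable_fraction * 0.02 / 60.0
    # flux-weighted mean transit time over truncated offsets:
    # T(u) = L / (1.5 v (1-u^2)); E[T] under density ~ (1-u^2) on [-u_m, u_m]
    um, L, v = 0.95, 1.2, net["main"].mean_velocity_mm_s
    e_t = (2 * um) / (1.5 * v) * L / (2 * (um - um**3 / 3))
    expected = lam * e_t
    counts = truth.positions.groupby("frame").size().reindex(
        range(600), fill_value=0
    )
    steady = counts.iloc[300:].mean()  # after warm-up
    assert steady == pytest.approx(expected, rel=0.25)
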