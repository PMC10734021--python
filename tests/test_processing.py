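"""Upsampling, SVD clutter filtering, temporal filtering, detection and
subpixel localization."""

import numpy as np
import pytest
from scipy.signal import butter, freqz

import ulmflow as uf
from conftest import gaussian_frame


class TestUpsample:
    def test_constant_frame_preserved(self):
        frame = np.full((8, 8), 3.25)
        up = uf.upsample_frame(frame, 2)
        assert up.shape == (16, 16)
        np.testing.assert_allclose(up, 3.25, rtol=1e-8)

    def test_factor_one_identity(self):
        frame = np.random.default_rng(0).normal(size=(8, 8))
        np.testing.assert_array_equal(uf.upsample_frame(frame, 1), frame)

    def test_matches_independent_bicubic_oracle(self):
        # skimage's warp-based resize is an independent bicubic
        # implementation with the same extent-preserving grid convention;
        # away from the boundary the two agree to machine precision.
        from skimage.transform import resize

        rng = np.random.default_rng(1)
        frame = rng.normal(size=(16, 16))
        up = uf.upsample_frame(frame, 2)
        oracle = resize(frame, (32, 32), order=3, mode="symmetric",
                        anti_aliasing=False)
        np.testing.assert_allclose(up[4:-4, 4:-4], oracle[4:-4, 4:-4], atol=1e-6)

    def test_linear_ramp_interior(self):
        # Cubic splines reproduce linear ramps; boundary reflection ripples
        # decay geometrically away from the edges.
        rr, cc = np.mgrid[0:24, 0:24]
        ramp = 2.0 * rr + 0.5 * cc
        up = uf.upsample_frame(ramp, 2)
        rr2, cc2 = np.mgrid[0:48, 0:48]
        expected = 2.0 * ((rr2 + 0.5) / 2 - 0.5) + 0.5 * ((cc2 + 0.5) / 2 - 0.5)
        np.testing.assert_allclose(up[16:-16, 16:-16], expected[16:-16, 16:-16],
                                   atol=1e-3)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            uf.upsample_frame(np.zeros((4, 4)), 0)


class TestSvdClutterFilter:
    def test_static_scene_removed(self):
        frame = gaussian_frame((16, 16), [(8, 8)], [2.0], 2.0)
        stack = np.repeat(frame[None], 20, axis=0)
        out = uf.svd_clutter_filter(stack, 2)
        assert (out**2).sum() < 1e-10 * (stack**2).sum()

    def test_n_remove_zero_identity(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(size=(10, 6, 6))
        np.testing.assert_allclose(uf.svd_clutter_filter(stack, 0), stack, rtol=1e-6)

    def test_matches_brute_force_svd_truncation(self):
        """Gram-based removal equals zeroing singular values of a full SVD."""
        rng = np.random.default_rng(4)
        stack = rng.normal(size=(3, 2, 2)) + 5.0
        x = stack.reshape(3, 4).T  # Casorati pixels x frames
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        s[:2] = 0.0
        oracle = (u * s) @ vt
        out = uf.svd_clutter_filter(stack, 2)
        np.testing.assert_allclose(out.reshape(3, 4).T, oracle, atol=1e-10)

    def test_output_orthogonal_to_removed_subspace(self):
        rng = np.random.default_rng(5)
        stack = rng.normal(size=(30, 8, 8)) + np.linspace(0, 4, 30)[:, None, None]
        out = uf.svd_clutter_filter(stack, 2)
        x = stack.reshape(30, 64).T
        xf = out.reshape(30, 64).T
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        proj = u[:, :2].T @ xf
        assert np.abs(proj).max() < 1e-6 * np.linalg.norm(x)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            uf.svd_clutter_filter(np.zeros((5, 4, 4)), 5)
        with pytest.raises(ValueError):
            uf.svd_clutter_filter(np.zeros((5, 4, 4)), -1)


class TestTemporalHighpass:
    def test_dc_rejected(self):
        stack = np.full((100, 4, 4), 7.0)
        out = uf.temporal_highpass(stack, 2, 0.1)
        assert np.abs(out).max() < 1e-8 * 7.0

    def test_nyquist_passes_at_unity(self):
        t = np.arange(200)
        sig = ((-1.0) ** t)[:, None, None] * np.ones((200, 2, 2))
        out = uf.temporal_highpass(sig, 2, 0.1)
        mid = out[50:150, 0, 0]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_cutoff_attenuation_matches_butterworth_oracle(self):
        """Forward-backward response at the cutoff equals |H|^2 = 1/2."""
        order, cutoff, n = 2, 0.2, 4000
        t = np.arange(n)
        sig = np.sin(np.pi * cutoff * t)[:, None, None] * np.ones((n, 1, 1))
        out = uf.temporal_highpass(sig, order, cutoff)[:, 0, 0]
        amp = np.abs(out[1000:3000]).max()
        b, a = butter(order, cutoff, btype="highpass")
        _, h = freqz(b, a, worN=[np.pi * cutoff])
        expected = np.abs(h[0]) ** 2  # 0.5 at the -3 dB point, squared pass
        assert amp == pytest.approx(expected, rel=0.05)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            uf.temporal_highpass(np.zeros((5, 2, 2)), 2, 0.1)


class TestDetectPeaks:
    def test_uniform_frame_no_peaks(self):
        assert uf.detect_peaks(np.full((32, 32), 2.0)) == []

    def test_close_pair_yields_single_detection(self):
        # two equal Gaussians 3 px apart with min_separation 4: only the
        # brightest-then-lexicographic survivor remains
        frame = gaussian_frame((32, 32), [(16, 14), (16, 17)], [1.0, 1.0], 1.5)
        peaks = uf.detect_peaks(frame, min_separation=4)
        assert len(peaks) == 1

    def test_planted_bubbles_all_recovered(self):
        centers = [(5, 5), (5, 25), (16, 16), (26, 6), (26, 26)]
        frame = gaussian_frame((32, 32), centers, [1.0] * 5, 1.5)
        rng = np.random.default_rng(9)
        frame = frame + rng.normal(0, 0.02, frame.shape)  # SNR 50
        peaks = uf.detect_peaks(frame, min_separation=4)
        assert sorted(peaks) == sorted(centers)

    def test_deterministic_tie_break(self):
        frame = np.zeros((16, 16))
        frame[4, 4] = frame[4, 6] = 1.0  # equal maxima 2 px apart
        peaks = uf.detect_peaks(frame, min_separation=4)
        assert peaks == [(4, 4)]


class TestLocalize:
    def test_pixel_centered_psf_exact(self):
        frame = gaussian_frame((21, 21), [(10, 10)], [1.0], 1.5)
        loc = uf.localize(frame, (10, 10), window=5)
        assert loc.row == pytest.approx(10, abs=1e-6)
        assert loc.col == pytest.approx(10, abs=1e-6)

    def test_subpixel_offset_recovered(self):
        rr, cc = np.mgrid[0:21, 0:21]
        frame = np.exp(-((rr - 10.0) ** 2 + (cc - 10.30) ** 2) / (2 * 1.5**2))
        loc = uf.localize(frame, (10, 10), window=5)
        assert loc.col == pytest.approx(10.30, abs=0.1)
        assert loc.row == pytest.approx(10.0, abs=0.05)

    def test_single_pixel_mass(self):
        frame = np.zeros((9, 9))
        frame[3, 6] = 4.0
        loc = uf.localize(frame, (3, 6), window=5)
        assert (loc.row, loc.col) == (3.0, 6.0)

    def test_window_clipped_at_edge(self):
        frame = gaussian_frame((9, 9), [(0, 0)], [1.0], 1.0)
        loc = uf.localize(frame, (0, 0), window=5)
        assert 0 <= loc.row < 2 and 0 <= loc.col < 2

    def test_mm_conversion_uses_upsampled_pitch(self):
        frame = np.zeros((8, 8))
        frame[4, 6] = 1.0
        loc = uf.localize(
            frame, (4, 6), window=3, pixel_size_mm=0.025, upsample_factor=2,
            origin_mm=(0.0, -0.1),
        )
        assert loc.x_mm == pytest.approx((6 + 0.5) * 0.0125)
        assert loc.z_mm == pytest.approx(-0.1 + (4 + 0.5) * 0.0125)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            uf.localize(np.zeros((8, 8)), (4, 4), window=4)


class TestPipeline:
    def test_localization_error_small_on_clean_frames(self):
        """RMS localization error < 0.25 upsampled px for isolated bubbles."""
        rng = np.random.default_rng(17)
        errors = []
        for _ in range(40):
            r = rng.uniform(20, 40)
            c = rng.uniform(20, 40)
            rr, cc = np.mgrid[0:64, 0:64]
            frame = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 3.0**2))
            peaks = uf.detect_peaks(frame, 4)
            assert len(peaks) == 1
            loc = uf.localize(frame, peaks[0], window=5)
            errors.append((loc.row - r) ** 2 + (loc.col - c) ** 2)
        assert np.sqrt(np.mean(errors)) < 0.25

    def test_detection_recall_precision_well_separated(self):
        """Recall and precision >= 0.95 for <= 10 separated bubbles, SNR >= 10."""
        rng = np.random.default_rng(23)
        hits = total_true = total_det = 0
        for trial in range(20):
            n = rng.integers(3, 11)
            centers = []
            while len(centers) < n:
                cand = rng.uniform(8, 56, 2)
                if all(np.hypot(*(cand - c)) > 10 for c in centers):
                    centers.append(cand)
            frame = gaussian_frame((64, 64), centers, [1.0] * n, 1.5)
            frame = frame + rng.normal(0, 0.1, frame.shape)  # SNR 10
            peaks = uf.detect_peaks(frame, 4)
            total_true += n
            total_det += len(peaks)
            for p in peaks:
                if any(np.hypot(p[0] - c[0], p[1] - c[1]) < 3 for c in centers):
                    hits += 1
        assert hits / total_true >= 0.95  # recall
        assert hits / total_det >= 0.95  # precision

    def test_stack_pipeline_deterministic(self, tiny_run):
        locs2 = uf.localize_stack(tiny_run.stack, tiny_run.config.pipeline)
        assert locs2.equals(tiny_run.localizations)
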