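"""Temporal statistics, hotspot detection, and ΔI/I extraction checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flickermap as fm
from tests.conftest import make_stack


def brute_force_stats(frames):
    """Independent double-loop recomputation of the temporal mean and SD."""
    n, h, w = frames.shape
    mu = np.zeros((h, w))
    sigma = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            pix = frames[:, i, j].astype(float)
            m = pix.sum() / n
            mu[i, j] = m
            sigma[i, j] = np.sqrt(((pix - m) ** 2).sum() / n)
    return mu, sigma


class TestTemporalStats:
    def test_constant_sequence_has_zero_sd(self):
        frame = np.arange(16, dtype=np.uint16).reshape(4, 4) + 7
        stack = make_stack(np.stack([frame] * 6))
        amap = fm.temporal_stats(stack, normalize=False)
        np.testing.assert_array_equal(amap.mu, frame)
        np.testing.assert_array_equal(amap.sigma, 0.0)

    def test_two_point_alternation_population_sd(self):
        frames = np.zeros((10, 3, 3), dtype=np.uint16) + 100
        frames[1::2, 1, 1] = 200
        frames[::2, 1, 1] = 100
        amap = fm.temporal_stats(make_stack(frames), normalize=False)
        assert amap.mu[1, 1] == pytest.approx(150.0)
        assert amap.sigma[1, 1] == pytest.approx(50.0)

    def test_random_stack_matches_double_loop_oracle(self, rng):
        frames = rng.integers(0, 2**16, size=(100, 16, 16), dtype=np.uint16)
        amap = fm.temporal_stats(make_stack(frames), normalize=False)
        mu, sigma = brute_force_stats(frames)
        np.testing.assert_allclose(amap.mu, mu, rtol=1e-10)
        np.testing.assert_allclose(amap.sigma, sigma, rtol=1e-10, atol=1e-10)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        n=st.integers(2, 12),
        h=st.integers(2, 6),
        w=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_property(self, n, h, w, seed):
        frames = np.random.default_rng(seed).integers(
            0, 2**16, size=(n, h, w), dtype=np.uint16
        )
        amap = fm.temporal_stats(make_stack(frames), normalize=False)
        mu, sigma = brute_force_stats(frames)
        np.testing.assert_allclose(amap.mu, mu, rtol=1e-10)
        np.testing.assert_allclose(amap.sigma, sigma, rtol=1e-10, atol=1e-10)

    def test_sd_is_frame_order_invariant(self, rng):
        frames = rng.integers(0, 1000, size=(30, 8, 8), dtype=np.uint16)
        shuffled = frames[rng.permutation(30)]
        a = fm.temporal_stats(make_stack(frames), normalize=False)
        b = fm.temporal_stats(make_stack(shuffled), normalize=False)
        np.testing.assert_allclose(a.sigma, b.sigma, rtol=1e-12)
        np.testing.assert_allclose(a.mu, b.mu, rtol=1e-12)

    def test_normalization_cancels_global_illumination(self, rng):
        base = rng.integers(100, 1000, size=(20, 10, 10)).astype(float)
        gains = rng.uniform(0.5, 2.0, size=20)
        modulated = base * gains[:, None, None]
        a = fm.temporal_stats(make_stack(base), normalize=True)
        b = fm.temporal_stats(make_stack(modulated), normalize=True)
        np.testing.assert_allclose(a.sigma, b.sigma, rtol=1e-9, atol=1e-12)

    def test_zero_background_region_rejected(self):
        frames = np.zeros((5, 8, 8), dtype=np.uint16)
        frames[:, 4:, 4:] = 100
        bg = fm.Roi(center=(1.5, 1.5), radius=1.0, label="background")
        with pytest.raises(ValueError, match="zero"):
            fm.temporal_stats(make_stack(frames), normalize=True, background=bg)


class TestDetectHotspots:
    def amap(self, sigma, mask=None):
        if mask is None:
            mask = np.ones_like(sigma, dtype=bool)
        return fm.ActivityMap(
            mu=np.zeros_like(sigma), sigma=sigma, mask=mask, normalized=False
        )

    def test_flat_zero_map_yields_nothing(self):
        assert fm.detect_hotspots(self.amap(np.zeros((32, 32)))) == []

    def test_single_bump_centroid_matches_argmax_oracle(self):
        rr, cc = np.mgrid[0:41, 0:41]
        bump = 10.0 * np.exp(-((rr - 17.3) ** 2 + (cc - 24.6) ** 2) / (2 * 2.0**2))
        hotspots = fm.detect_hotspots(self.amap(bump), k_sigma=3.0, min_area=4)
        assert len(hotspots) == 1
        argmax = np.unravel_index(np.argmax(bump), bump.shape)  # exhaustive oracle
        assert abs(hotspots[0].centroid[0] - argmax[0]) <= 0.5
        assert abs(hotspots[0].centroid[1] - argmax[1]) <= 0.5

    def test_two_equal_bumps_tie_broken_lexicographically(self):
        rr, cc = np.mgrid[0:48, 0:48]
        sigma = np.exp(-((rr - 30) ** 2 + (cc - 35) ** 2) / 8.0)
        sigma += np.exp(-((rr - 12) ** 2 + (cc - 10) ** 2) / 8.0)
        hotspots = fm.detect_hotspots(self.amap(sigma), k_sigma=1.0, min_area=4)
        assert len(hotspots) == 2
        # flood-fill oracle: two 8-connected components above any threshold
        from scipy import ndimage

        _, n_comp = ndimage.label(sigma > sigma.mean() + sigma.std(), np.ones((3, 3)))
        assert n_comp == 2
        assert hotspots[0].peak_sigma == pytest.approx(hotspots[1].peak_sigma)
        assert hotspots[0].centroid[0] < hotspots[1].centroid[0]

    def test_min_area_filters_specks(self):
        sigma = np.zeros((20, 20))
        sigma[5, 5] = 100.0  # single-pixel speck
        assert fm.detect_hotspots(self.amap(sigma), min_area=4) == []

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            fm.detect_hotspots(self.amap(np.ones((8, 8)), mask=np.zeros((8, 8), bool)))


class TestExtractTrace:
    def stack_with_means(self, roi_means, bg_means):
        frames = np.zeros((len(roi_means), 32, 32), dtype=np.uint16)
        for k, (rv, bv) in enumerate(zip(roi_means, bg_means)):
            frames[k, 2:12, 2:12] = rv
            frames[k, 20:30, 20:30] = bv
        return make_stack(frames)

    def roi(self):
        return fm.Roi(center=(6.0, 6.0), radius=3.0)

    def bg(self):
        return fm.Roi(center=(24.0, 24.0), radius=3.0, label="background")

    def test_identical_roi_and_background_gives_zero(self):
        stack = self.stack_with_means([120, 130, 140], [120, 130, 140])
        trace = fm.extract_trace(stack, self.roi(), self.bg())
        np.testing.assert_allclose(trace.values, 0.0)

    def test_double_background_gives_unity(self):
        stack = self.stack_with_means([200, 240], [100, 120])
        trace = fm.extract_trace(stack, self.roi(), self.bg())
        np.testing.assert_allclose(trace.values, 1.0)

    def test_hand_computed_three_frame_example(self):
        stack = self.stack_with_means([110, 120, 130], [100, 100, 100])
        trace = fm.extract_trace(stack, self.roi(), self.bg())
        np.testing.assert_allclose(trace.values, [0.10, 0.20, 0.30])
        assert trace.kind == "delta_i_over_i"
        assert trace.sample_rate == stack.frame_rate

    def test_overlapping_rois_rejected(self):
        stack = self.stack_with_means([100, 100], [100, 100])
        overlapping = fm.Roi(center=(7.0, 7.0), radius=3.0, label="background")
        with pytest.raises(ValueError, match="overlap"):
            fm.extract_trace(stack, self.roi(), overlapping)

    def test_zero_background_mean_rejected(self):
        stack = self.stack_with_means([100, 100], [0, 0])
        with pytest.raises(ValueError, match="zero"):
            fm.extract_trace(stack, self.roi(), self.bg())


class TestZProfile:
    def test_identical_traces_correlate_perfectly_at_zero_lag(self, rng):
        bundle = fm.Trace(rng.normal(size=400), 1000.0)
        pairs = [(z, fm.Trace(bundle.values.copy(), 1000.0, "delta_i_over_i"))
                 for z in range(6)]
        table = fm.z_profile(pairs, bundle)
        assert list(table["z_index"]) == list(range(6))
        np.testing.assert_allclose(table["max_corr"], 1.0, atol=1e-12)
        assert (table["lag"] == 0).all()

    def test_independent_noise_stays_below_threshold(self, rng):
        # Monte-Carlo null: white-noise pairs of length 5000 never reach 0.2
        worst = 0.0
        for _ in range(100):
            a = fm.Trace(rng.normal(size=5000), 1000.0)
            b = fm.Trace(rng.normal(size=5000), 1000.0, "delta_i_over_i")
            res = fm.max_shift_correlation(a, b)
            worst = max(worst, abs(res.max_corr))
        assert worst < 0.2

    def test_attenuation_decaying_modulation_gives_non_increasing_profile(self, rng):
        bundle_values = np.sin(2 * np.pi * 12.0 * np.arange(3000) / 1000.0)
        bundle = fm.Trace(bundle_values, 1000.0)
        attenuation = (1.0, 0.85, 0.70, 0.55, 0.45, 0.35)
        pairs = []
        for z, att in enumerate(attenuation):
            noisy = att * bundle_values + 0.35 * rng.normal(size=3000)
            pairs.append((z, fm.Trace(noisy, 1000.0, "delta_i_over_i")))
        table = fm.z_profile(pairs, bundle)
        corr = table["max_corr"].to_numpy()
        # correlation falls with depth (small Monte-Carlo wiggle allowed)
        assert np.all(np.diff(corr) < 0.05)
        assert corr[0] > corr[-1]

    def test_rate_mismatch_rejected(self, rng):
        bundle = fm.Trace(rng.normal(size=100), 1000.0)
        with pytest.raises(ValueError, match="rate"):
            fm.z_profile([(0, fm.Trace(rng.normal(size=100), 500.0, "delta_i_over_i"))], bundle)
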