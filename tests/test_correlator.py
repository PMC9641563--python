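import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import events_from_dense
from virusxpcs.correlator import (
    average_accumulators,
    build_lags,
    correlate_multitau,
    flag_bad_pixels,
    normalize,
)
from virusxpcs.geometry import qmap_from_rings
from virusxpcs.simulate import SimulationConfig, static_speckle_sequence


# ---------------------------------------------------------------------------
# independent brute-force oracle: explicit loops, no shared code with the
# implementation
# ---------------------------------------------------------------------------

def brute_force_sums(stream, lag):
    """Symmetric-window G2/IF/IP of one pixel's stream at one lag."""
    T = len(stream)
    assert lag < T
    prod = if_sum = ip_sum = 0.0
    n = 0
    for t in range(T - lag):
        prod += stream[t] * stream[t + lag]
        if_sum += stream[t]
        ip_sum += stream[t + lag]
        n += 1
    return prod / n, if_sum / n, ip_sum / n


def bin_by_two(stream):
    out = []
    for i in range(len(stream) // 2):
        out.append(0.5 * (stream[2 * i] + stream[2 * i + 1]))
    return out


def single_ring_qmap(n_pixels, q=0.04):
    return qmap_from_rings([(q, n_pixels)])


class TestBuildLags:
    def test_level_zero_lags_are_consecutive(self):
        lags = build_lags(64, 52_000.0, channels_per_level=8)
        level0 = [d.lag_frames for d in lags.delays if d.level == 0]
        assert level0 == list(range(1, 9))

    def test_smallest_lag_is_frame_period(self):
        lags = build_lags(100_000, 52_000.0)
        assert min(lags.lag_seconds) == pytest.approx(1 / 52_000, rel=1e-12)
        assert min(lags.lag_seconds) == pytest.approx(19.23e-6, rel=1e-3)

    def test_lag_seconds_consistent_with_frames(self):
        lags = build_lags(5_000, 1000.0)
        for d in lags.delays:
            assert d.lag_seconds == d.lag_frames / 1000.0

    def test_lags_strictly_increasing(self):
        lags = build_lags(100_000, 52_000.0)
        assert np.all(np.diff(lags.lag_frames) > 0)

    def test_max_lag_quarter_of_sequence(self):
        lags = build_lags(10_000, 1000.0)
        assert lags.lag_frames.max() <= 2_500

    def test_level_spacing_doubles(self):
        lags = build_lags(100_000, 52_000.0, channels_per_level=8)
        for d in lags.delays:
            assert d.lag_frames == d.channel * 2**d.level

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_lags(8, 1000.0, channels_per_level=8)


class TestCorrelateMultitau:
    def test_constant_stream_identity_at_all_lags(self):
        c = 3.0
        dense = np.full((4, 256), c)
        events_dense = dense.copy()
        events_dense[:, 0] = c  # already constant; keep counts integral
        events = events_from_dense(events_dense)
        qmap = single_ring_qmap(4)
        lags = build_lags(256, 1000.0)
        acc = correlate_multitau(events, qmap, lags)
        assert np.all(acc.g2_sums == c * c)
        assert np.all(acc.if_sums == c)
        assert np.all(acc.ip_sums == c)

    def test_level_zero_matches_brute_force_exactly(self, rng):
        dense = rng.integers(0, 5, size=(4, 16)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(4)
        lags = build_lags(16, 1000.0, channels_per_level=4, max_lag_fraction=0.5)
        acc = correlate_multitau(events, qmap, lags)
        for j, d in enumerate(acc.lags.delays):
            if d.level != 0:
                continue
            for p in range(4):
                g2, if_m, ip_m = brute_force_sums(list(dense[p]), d.lag_frames)
                assert acc.g2_sums[p, j] == g2
                assert acc.if_sums[p, j] == if_m
                assert acc.ip_sums[p, j] == ip_m

    @given(
        dense=hnp.arrays(
            dtype=np.int64,
            shape=st.tuples(st.integers(1, 16), st.integers(17, 64)),
            elements=st.integers(0, 7),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_level_zero_oracle_property(self, dense):
        dense = dense.astype(float)
        n_pix, n_frames = dense.shape
        events = events_from_dense(dense)
        qmap = single_ring_qmap(n_pix)
        lags = build_lags(n_frames, 1000.0, channels_per_level=8)
        acc = correlate_multitau(events, qmap, lags)
        for j, d in enumerate(acc.lags.delays):
            if d.level != 0:
                continue
            for p in range(n_pix):
                g2, if_m, ip_m = brute_force_sums(list(dense[p]), d.lag_frames)
                assert acc.g2_sums[p, j] == g2
                assert acc.if_sums[p, j] == if_m
                assert acc.ip_sums[p, j] == ip_m

    def test_level_one_equals_brute_force_on_binned_stream(self, rng):
        dense = rng.integers(0, 5, size=(3, 64)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(3)
        lags = build_lags(64, 1000.0, channels_per_level=4, max_lag_fraction=0.5)
        acc = correlate_multitau(events, qmap, lags)
        for j, d in enumerate(acc.lags.delays):
            if d.level != 1:
                continue
            for p in range(3):
                binned = bin_by_two(list(dense[p]))
                g2, if_m, ip_m = brute_force_sums(binned, d.channel)
                assert acc.g2_sums[p, j] == pytest.approx(g2, rel=0, abs=0)
                assert acc.if_sums[p, j] == if_m
                assert acc.ip_sums[p, j] == ip_m

    def test_symmetric_normalization_suppresses_linear_drift(self):
        # I(t) = a + b t with bT/a = 0.01: |g2 - 1| < (bT/a)^2
        a, n_frames = 10_000.0, 1_000
        bT_over_a = 0.01
        b = bT_over_a * a / n_frames
        stream = np.round(a + b * np.arange(n_frames))
        dense = np.tile(stream, (1, 1))
        events = events_from_dense(dense)
        qmap = single_ring_qmap(1)
        lags = build_lags(n_frames, 1000.0)
        acc = correlate_multitau(events, qmap, lags)
        g2 = acc.g2_sums[0] / (acc.if_sums[0] * acc.ip_sums[0])
        assert np.max(np.abs(g2 - 1)) < bT_over_a**2

    def test_deterministic_given_same_events(self, rng):
        dense = rng.integers(0, 3, size=(6, 128)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(6)
        lags = build_lags(128, 1000.0)
        a = correlate_multitau(events, qmap, lags)
        b = correlate_multitau(events, qmap, lags)
        assert np.array_equal(a.g2_sums, b.g2_sums)

    def test_chunked_equals_unchunked(self, rng):
        dense = rng.integers(0, 3, size=(10, 64)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(10)
        lags = build_lags(64, 1000.0)
        a = correlate_multitau(events, qmap, lags, pixel_chunk=3)
        b = correlate_multitau(events, qmap, lags, pixel_chunk=512)
        assert np.array_equal(a.g2_sums, b.g2_sums)


class TestAverageAccumulators:
    def test_self_average_is_identity(self, rng):
        dense = rng.integers(0, 4, size=(4, 64)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(4)
        lags = build_lags(64, 1000.0)
        acc = correlate_multitau(events, qmap, lags)
        merged = average_accumulators([acc, acc])
        assert np.allclose(merged.g2_sums, acc.g2_sums, rtol=0, atol=0)
        assert np.array_equal(merged.weights, 2 * acc.weights)
        assert merged.n_repeats == 2

    def test_disjoint_halves_equal_gapped_concatenation(self, rng):
        # averaging two equal-length accumulators must equal correlating
        # the concatenated data with cross-boundary pairs excluded
        n_frames, n_pix = 32, 3
        a = rng.integers(0, 4, size=(n_pix, n_frames)).astype(float)
        b = rng.integers(0, 4, size=(n_pix, n_frames)).astype(float)
        qmap = single_ring_qmap(n_pix)
        lags = build_lags(n_frames, 1000.0, channels_per_level=4,
                          max_lag_fraction=0.25)
        acc_a = correlate_multitau(events_from_dense(a), qmap, lags)
        acc_b = correlate_multitau(events_from_dense(b), qmap, lags)
        merged = average_accumulators([acc_a, acc_b])
        cat = np.concatenate([a, b], axis=1)
        for j, d in enumerate(merged.lags.delays):
            if d.level != 0:
                continue
            lag = d.lag_frames
            for p in range(n_pix):
                prod = if_sum = ip_sum = 0.0
                n = 0
                for t in range(2 * n_frames - lag):
                    # skip pairs straddling the sequence boundary
                    if t < n_frames <= t + lag:
                        continue
                    prod += cat[p, t] * cat[p, t + lag]
                    if_sum += cat[p, t]
                    ip_sum += cat[p, t + lag]
                    n += 1
                assert merged.g2_sums[p, j] == pytest.approx(prod / n, rel=1e-14)
                assert merged.if_sums[p, j] == pytest.approx(if_sum / n, rel=1e-14)
                assert merged.ip_sums[p, j] == pytest.approx(ip_sum / n, rel=1e-14)

    def test_mismatched_structure_rejected(self, rng):
        dense = rng.integers(0, 4, size=(4, 64)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(4)
        acc1 = correlate_multitau(events, qmap, build_lags(64, 1000.0))
        acc2 = correlate_multitau(
            events, qmap, build_lags(64, 1000.0, channels_per_level=4)
        )
        with pytest.raises(ValueError, match="mismatched"):
            average_accumulators([acc1, acc2])


class TestFlagBadPixels:
    def test_null_flag_fraction_small(self):
        cfg = SimulationConfig(
            ring_spec=[(0.04, 400)], n_frames=4_000, mean_count_rate=0.1, seed=17
        )
        events = static_speckle_sequence(cfg)
        qmap = single_ring_qmap(400)
        acc = correlate_multitau(events, qmap, build_lags(4_000, cfg.frame_rate))
        flags = flag_bad_pixels(acc)
        assert flags.mean() <= 0.01

    def test_injected_correlated_pixel_is_flagged(self, rng):
        n_pix, n_frames = 64, 2_000
        dense = rng.poisson(2.0, size=(n_pix, n_frames)).astype(float)
        # doubled self-correlation: slow on/off blinking on top of noise
        blink = (np.sin(2 * np.pi * np.arange(n_frames) / 400) > 0) * 4.0
        dense[0] = rng.poisson(1.0, size=n_frames) + blink
        events = events_from_dense(dense)
        qmap = single_ring_qmap(n_pix)
        acc = correlate_multitau(events, qmap, build_lags(n_frames, 1000.0))
        flags = flag_bad_pixels(acc)
        assert flags[0]
        assert flags[1:].mean() < 0.05

    def test_identical_pixels_none_flagged(self):
        dense = np.tile(np.array([1.0, 0, 2, 0, 1, 1, 0, 3] * 8), (12, 1))
        events = events_from_dense(dense)
        qmap = single_ring_qmap(12)
        acc = correlate_multitau(events, qmap, build_lags(64, 1000.0))
        flags = flag_bad_pixels(acc)
        assert not flags.any()

    def test_small_partition_skipped_with_warning(self, rng):
        dense = rng.poisson(1.0, size=(5, 64)).astype(float)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(5)
        acc = correlate_multitau(events, qmap, build_lags(64, 1000.0))
        with pytest.warns(UserWarning, match="skipped"):
            flags = flag_bad_pixels(acc)
        assert not flags.any()


class TestNormalize:
    def test_constant_stream_gives_unit_g2(self):
        dense = np.full((6, 128), 2.0)
        events = events_from_dense(dense)
        qmap = single_ring_qmap(6)
        acc = correlate_multitau(events, qmap, build_lags(128, 1000.0))
        result = normalize(acc, qmap)
        assert np.allclose(result.g2, 1.0, rtol=0, atol=0)
        assert np.allclose(result.sigma_g2, 0.0, atol=1e-14)

    def test_static_speckle_plateau_matches_mode_count(self):
        cfg = SimulationConfig(
            ring_spec=[(0.04, 2_000)], n_frames=20_000, mean_count_rate=0.05,
            seed=23,
        )
        events = static_speckle_sequence(cfg)
        qmap = single_ring_qmap(2_000)
        acc = correlate_multitau(events, qmap, build_lags(20_000, cfg.frame_rate))
        result = normalize(acc, qmap)
        order = np.argsort(result.delays)[:5]
        plateau = result.g2[0, order].mean() - 1.0
        se = np.mean(result.sigma_g2[0, order] / np.sqrt(result.n_pixels[0]))
        assert abs(plateau - 1 / 7) < 3 * se

    def test_binned_normalization_less_biased_than_per_pixel_in_sparse_regime(self):
        # at ~7e-5 photons/pixel/frame the per-pixel ratio G2/(IF*IP) is
        # dominated by denominator shot noise; binning the sums first
        # must sit closer to the true plateau 1 + 1/7
        cfg = SimulationConfig(
            ring_spec=[(0.04, 3_000)], n_frames=20_000, mean_count_rate=7e-5,
            seed=31,
        )
        events = static_speckle_sequence(cfg)
        qmap = single_ring_qmap(3_000)
        acc = correlate_multitau(events, qmap, build_lags(20_000, cfg.frame_rate))
        result = normalize(acc, qmap)
        order = np.argsort(result.delays)[:5]
        binned = result.g2[0, order].mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            per_pixel = acc.g2_sums / (acc.if_sums * acc.ip_sums)
        per_pixel_mean = np.nanmean(per_pixel[:, order])
        truth = 1 + 1 / 7
        assert abs(binned - truth) < abs(per_pixel_mean - truth)

    def test_zero_intensity_partition_reported_missing(self):
        dense = np.zeros((4, 64))
        dense[0, 0] = 1.0  # one lone photon; most window means vanish
        events = events_from_dense(dense)
        qmap = single_ring_qmap(4)
        acc = correlate_multitau(events, qmap, build_lags(64, 1000.0))
        result = normalize(acc, qmap)
        assert not np.isinf(result.g2).any()

    def test_brownian_g2_decays_to_one(self):
        cfg = SimulationConfig(
            ring_spec=[(0.06, 300)], n_frames=20_000, mean_count_rate=0.05,
            seed=29,
        )
        events = __import__("virusxpcs").brownian_speckle_sequence(cfg)
        qmap = single_ring_qmap(300, q=0.06)
        acc = correlate_multitau(events, qmap, build_lags(20_000, cfg.frame_rate))
        result = normalize(acc, qmap)
        tail = np.argsort(result.delays)[-3:]
        se = result.sigma_g2[0, tail] / np.sqrt(result.n_pixels[0])
        assert np.all(np.abs(result.g2[0, tail] - 1.0) < 3 * se)
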