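import numpy as np
import pytest
from helpers_oracles import counting_cumulative_length
from hypothesis import given, settings
from hypothesis import strategies as hst

from calplast import synth
from calplast.spatial import (
    CumulativeCurve,
    DeltaLengthCurve,
    LinescanProfile,
    RegionBands,
    band_metrics,
    cumulative_length,
    default_levels,
    delta_length,
    exclude_global_responders,
    extract_profile,
    normalize_pair,
    resample_polyline,
)


def profile(values, pixel_len=15.0, condition="pre"):
    return LinescanProfile(np.asarray(values, dtype=float), pixel_len, condition)


class TestExtractProfile:
    def test_constant_map(self):
        m = np.full((8, 310), 0.3)
        out = extract_profile(m, frame_rate=31.0, stim_times=[5.0])
        np.testing.assert_allclose(out.values, 0.3)

    def test_monotone_rise_gives_end_of_window_value(self):
        fr = 31.0
        n = 310
        m = np.tile(np.linspace(0, 1, n), (4, 1))
        out = extract_profile(m, frame_rate=fr, stim_times=[5.0], window_len=0.2)
        t = np.arange(n) / fr
        last_in_win = np.where((t >= 5.0) & (t < 5.2))[0][-1]
        np.testing.assert_allclose(out.values, np.linspace(0, 1, n)[last_in_win])

    def test_round_trip_hotspot_map(self):
        """Noise-free linescan movie collapses back to the bump profile."""
        pre, _, _ = synth.generate_linescan_pair(
            30, 15.0, 15, 2.5, synth.RegimeSpec.preset("control"), seed=0
        )
        fr, n = 31.0, 310
        t = np.arange(n) / fr
        kern = synth.event_kernel(t - 5.0)
        m = pre[:, None] * kern[None, :]
        out = extract_profile(m, frame_rate=fr, stim_times=[5.0], window_len=0.4)
        peak_in_win = kern[(t >= 5.0) & (t < 5.4)].max()
        np.testing.assert_allclose(out.values, pre * peak_in_win, rtol=1e-12)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError, match="trial"):
            extract_profile(np.zeros((4, 100)), 31.0, [])


class TestNormalizePair:
    def test_identical_pair_max_one(self):
        pre = profile([0.2, 0.5, 1.0])
        post = profile([0.2, 0.5, 1.0], condition="late_post")
        a, b = normalize_pair(pre, post)
        assert a.values.max() == pytest.approx(1.0)
        assert b.values.max() == pytest.approx(1.0)

    def test_post_may_exceed_one(self):
        pre = profile([0.2, 0.5, 1.0])
        post = profile([0.4, 1.0, 2.0], condition="late_post")
        _, b = normalize_pair(pre, post)
        assert b.values.max() == pytest.approx(2.0)

    def test_idempotent(self):
        pre = profile([0.2, 0.5, 0.8])
        post = profile([0.1, 0.9, 1.3], condition="late_post")
        a1, b1 = normalize_pair(pre, post)
        a2, b2 = normalize_pair(a1, b1)
        np.testing.assert_allclose(a1.values, a2.values)
        np.testing.assert_allclose(b1.values, b2.values)

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_pair(profile([-0.1, 0.0]), profile([0.5, 0.5]))


class TestCumulativeLength:
    def test_uniform_profile(self):
        c = cumulative_length(profile([1.0, 1.0, 1.0], pixel_len=10.0),
                              levels=np.array([0.5]))
        assert c.lengths[0] == pytest.approx(30.0)

    def test_direct_count_example(self):
        c = cumulative_length(profile([0.2, 0.5, 1.0], pixel_len=1.0),
                              levels=np.array([0.3, 0.9, 1.1]))
        np.testing.assert_allclose(c.lengths, [2.0, 1.0, 0.0])

    def test_matches_counting_oracle_random_profiles(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 1.5, size=rng.integers(3, 60))
            p = profile(vals, pixel_len=15.0)
            levels = default_levels(p)
            got = cumulative_length(p, levels)
            want = counting_cumulative_length(vals, 15.0, levels)
            np.testing.assert_array_equal(got.lengths, want)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hst.lists(hst.floats(0, 2), min_size=1, max_size=40))
    def test_monotone_and_conserving(self, vals):
        p = profile(vals, pixel_len=15.0)
        c = cumulative_length(p)
        assert np.all(np.diff(c.lengths) <= 0)
        assert c.lengths[0] == pytest.approx(p.total_length)
        above = default_levels(p)[default_levels(p) > np.max(vals)]
        if above.size:
            assert cumulative_length(p, above).lengths.max() == 0.0


class TestDeltaLength:
    def grid(self):
        return np.arange(0, 1.2, 0.01)

    def test_identical_curves_zero(self):
        p = profile([0.2, 0.7, 1.0])
        c = cumulative_length(p, self.grid())
        d = delta_length(c, c)
        np.testing.assert_allclose(d.delta, 0.0)

    def test_extra_pixel_adds_pixel_len(self):
        lv = self.grid()
        pre = profile([0.2, 0.7, 1.0], pixel_len=15.0)
        post = profile([0.2, 0.7, 1.0, 1.1], pixel_len=15.0, condition="late_post")
        d = delta_length(cumulative_length(pre, lv), cumulative_length(post, lv))
        below = lv <= 1.1
        np.testing.assert_allclose(d.delta[below], 15.0)

    def test_orientation_flag(self):
        lv = self.grid()
        pre = profile([0.5, 1.0])
        post = profile([0.8, 1.0], condition="late_post")
        a = delta_length(cumulative_length(pre, lv), cumulative_length(post, lv))
        b = delta_length(cumulative_length(pre, lv), cumulative_length(post, lv),
                         orientation="pre_minus_post")
        np.testing.assert_allclose(a.delta, -b.delta)

    def test_grid_mismatch_rejected(self):
        pre = cumulative_length(profile([0.5]), np.array([0.1, 0.2]))
        post = cumulative_length(profile([0.5]), np.array([0.1, 0.3]))
        with pytest.raises(ValueError, match="grid"):
            delta_length(pre, post)


class TestBandMetrics:
    def test_zero_curve(self):
        lv = np.arange(0, 1.01, 0.01)
        d = DeltaLengthCurve(levels=lv, delta=np.zeros_like(lv), pixel_len=15.0)
        assert band_metrics(d) == (0.0, 0.0)

    def test_constant_curve(self):
        lv = np.arange(0, 1.01, 0.01)
        d = DeltaLengthCurve(levels=lv, delta=np.full_like(lv, 7.5), pixel_len=15.0)
        hot, off = band_metrics(d)
        assert hot == pytest.approx(7.5)
        assert off == pytest.approx(7.5)

    def test_band_without_levels_rejected(self):
        lv = np.arange(0, 0.5, 0.01)  # no levels above the hotspot threshold
        d = DeltaLengthCurve(levels=lv, delta=np.zeros_like(lv), pixel_len=15.0)
        with pytest.raises(ValueError, match="hotspot"):
            band_metrics(d)

    def test_bands_disjoint_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            RegionBands(hotspot_level=0.5, off_band=(0.3, 0.67))


def regime_band_means(name, n_cells=20, noise_sd=0.0, seed0=0):
    regime = synth.RegimeSpec.preset(name)
    hots, offs = [], []
    for c in range(n_cells):
        pre, post, _ = synth.generate_linescan_pair(
            40, 15.0, 20, 2.5, regime, seed=seed0 + c, noise_sd=noise_sd
        )
        a, b = normalize_pair(profile(pre), profile(post, condition="late_post"))
        lv = default_levels(a, b)
        d = delta_length(cumulative_length(a, lv), cumulative_length(b, lv))
        hot, off = band_metrics(d)
        hots.append(hot)
        offs.append(off)
    return float(np.mean(hots)), float(np.mean(offs))


class TestRegimeSignatures:
    def test_control_no_spurious_expansion(self):
        hot, off = regime_band_means("control", noise_sd=0.0)
        assert hot == 0.0 and off == 0.0

    def test_local_only_expands_hotspot_band_only(self):
        hot, off = regime_band_means("local_only", noise_sd=0.0)
        assert hot > 0.0
        assert off == pytest.approx(0.0, abs=1e-9)

    def test_global_only_expands_off_hotspot_band(self):
        hot, off = regime_band_means("global_only", noise_sd=0.0)
        assert off > 0.0

    def test_noise_free_separation_no_overlap_and_ranked_with_noise(self):
        """Hotspot-vs-off-hotspot pattern separates the regimes."""
        sep = {n: regime_band_means(n) for n in ("local_only", "global_only", "control")}
        assert sep["local_only"][0] > sep["global_only"][0] >= 0
        assert sep["global_only"][1] > sep["local_only"][1] == 0
        noisy = {n: regime_band_means(n, noise_sd=0.02, seed0=50)
                 for n in ("local_only", "global_only", "control")}
        assert noisy["local_only"][0] > noisy["control"][0]
        assert noisy["global_only"][1] > noisy["control"][1]


class TestExcludeGlobalResponders:
    def test_everywhere_above_level_excluded(self):
        profs = [profile(np.full(20, 0.95)), profile(np.linspace(0, 1, 20))]
        assert exclude_global_responders(profs) == [1]

    def test_localized_bump_retained(self):
        vals = np.full(20, 0.2)
        vals[9:11] = 1.0  # 10 % coverage
        assert exclude_global_responders([profile(vals)]) == [0]

    def test_coverage_exactly_at_cutoff_retained(self):
        vals = np.concatenate([np.full(9, 0.95), [0.5]])  # coverage 0.9 exactly
        assert exclude_global_responders([profile(vals)], coverage_cutoff=0.9) == [0]


def test_resample_polyline_spacing():
    pts = np.array([[0.0, 0.0], [0.0, 30.0]])
    out = resample_polyline(pts, 15.0)
    np.testing.assert_allclose(out, [[0, 0], [0, 15], [0, 30]])
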