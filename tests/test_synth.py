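import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from calplast import synth
from calplast.synth import RegimeSpec, SimConfig


def no_evoked(cfg: SimConfig) -> SimConfig:
    return cfg.replace(
        evoked_prob_by_intensity={k: 0.0 for k in cfg.evoked_prob_by_intensity}
    )


class TestSimConfig:
    def test_rejects_stim_outside_trial(self):
        with pytest.raises(ValueError):
            SimConfig(stim_time=12.0, trial_len=10.0)

    @pytest.mark.parametrize("field,value", [
        ("spont_rate", -1.0), ("noise_sd", float("nan")), ("noise_sd", -0.1),
    ])
    def test_rejects_invalid_rates(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_rejects_probability_outside_unit_interval(self):
        with pytest.raises(ValueError):
            SimConfig(evoked_prob_by_intensity={10.0: 1.2},
                      evoked_amp_by_intensity={10.0: 0.5})


class TestRegimeSpec:
    def test_presets_respect_invariants(self):
        control = RegimeSpec.preset("control")
        assert control.hotspot_gain == control.offhotspot_gain == 1.0
        local = RegimeSpec.preset("local_only")
        assert local.offhotspot_gain == 1.0 and local.hotspot_gain > 1.0
        glob = RegimeSpec.preset("global_only")
        assert glob.offhotspot_gain > 1.0 and glob.hotspot_gain < local.hotspot_gain

    def test_invalid_control_rejected(self):
        with pytest.raises(ValueError):
            RegimeSpec(name="control", hotspot_gain=1.5)


class TestGenerateTrialSession:
    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig(n_trials=4, seed=3)
        a, _ = synth.generate_trial_session(cfg)
        b, _ = synth.generate_trial_session(cfg)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.values, tb.values)

    def test_streams_independent(self):
        cfg = SimConfig(n_trials=4, seed=3)
        a, _ = synth.generate_trial_session(cfg, stream=0)
        b, _ = synth.generate_trial_session(cfg, stream=1)
        assert not np.array_equal(a.trials[0].values, b.trials[0].values)

    def test_degenerate_limit_one_event_per_trial(self, clean_config):
        sess, truth = synth.generate_trial_session(clean_config)
        for times, evoked in zip(truth.event_times, truth.evoked):
            assert evoked
            assert len(times) == 1
            assert times[0] == pytest.approx(
                clean_config.stim_time + clean_config.evoked_latency
            )

    def test_spontaneous_counts_are_poisson(self):
        """Mean/variance ratio of per-trial counts is 1 within sampling error."""
        cfg = no_evoked(SimConfig(n_trials=3000, noise_sd=0.0, seed=9))
        _, truth = synth.generate_trial_session(cfg)
        counts = np.array([len(t) for t in truth.event_times])
        lam_hat = counts.mean()
        ratio = counts.var(ddof=1) / lam_hat
        # var of the dispersion index under Poisson is ~2/(n-1)
        se = np.sqrt(2.0 / (len(counts) - 1))
        assert abs(ratio - 1.0) < 3 * se
        assert lam_hat == pytest.approx(cfg.spont_rate * cfg.trial_len, rel=0.05)

    def test_window_probability_matches_closed_form(self):
        """P(≥1 event in a 200 ms pre-stimulus window) = 1−exp(−0.2λ)."""
        lam = 1.1
        cfg = no_evoked(SimConfig(n_trials=500, spont_rate=lam, noise_sd=0.0, seed=4))
        _, truth = synth.generate_trial_session(cfg)
        rng = np.random.default_rng(7)
        n_win = 10_000
        hits = 0
        for _ in range(n_win):
            i = rng.integers(0, cfg.n_trials)
            t0 = cfg.stim_time + rng.uniform(-4.5, -0.7)
            times = truth.event_times[i]
            hits += bool(np.any((times >= t0) & (times < t0 + 0.2)))
        p_true = 1.0 - np.exp(-0.2 * lam)
        se = np.sqrt(p_true * (1.0 - p_true) / n_win)
        assert abs(hits / n_win - p_true) < 3 * se

    def test_events_within_trial_bounds(self):
        cfg = SimConfig(n_trials=50, seed=2)
        _, truth = synth.generate_trial_session(cfg)
        for times in truth.event_times:
            assert np.all((times >= 0) & (times <= cfg.trial_len + 0.1))


class TestGeneratePlasticitySession:
    def test_control_regime_preserves_parameters(self):
        cfg = SimConfig(n_trials=4, seed=5)
        blocks, truth = synth.generate_plasticity_session(
            cfg, RegimeSpec.preset("control")
        )
        assert truth.amp_gain == 1.0 and truth.prob_gain == 1.0
        assert set(blocks) == {"pre", "early_post", "late_post"}

    def test_probability_gain_monte_carlo(self):
        """Empirical post probability within 3 SE of min(1, g_p · p)."""
        base_p = 0.3
        g = 1.5
        cfg = SimConfig(
            n_trials=10_000, spont_rate=0.0, noise_sd=0.0, seed=6,
            evoked_prob_by_intensity={50.0: base_p},
            evoked_amp_by_intensity={50.0: 1.0},
        )
        regime = RegimeSpec(name="both", hotspot_gain=1.0, offhotspot_gain=1.0,
                            probability_gain=g)
        _, truth = synth.generate_plasticity_session(cfg, regime)
        p_post = min(1.0, g * base_p)
        frac = np.mean(truth.sessions["late_post"].evoked)
        se = np.sqrt(p_post * (1 - p_post) / cfg.n_trials)
        assert abs(frac - p_post) < 3 * se
        frac_pre = np.mean(truth.sessions["pre"].evoked)
        se_pre = np.sqrt(base_p * (1 - base_p) / cfg.n_trials)
        assert abs(frac_pre - base_p) < 3 * se_pre


class TestGenerateLinescanPair:
    def test_control_noise_free_identity(self):
        pre, post, _ = synth.generate_linescan_pair(
            40, 15.0, 20, 2.5, RegimeSpec.preset("control"), seed=0
        )
        np.testing.assert_array_equal(pre, post)

    def test_global_only_ratio_off_hotspot(self):
        regime = RegimeSpec.preset("global_only")
        pre, post, truth = synth.generate_linescan_pair(
            40, 15.0, 20, 2.5, regime, seed=0
        )
        off = ~truth.hotspot_mask
        np.testing.assert_allclose(post[off] / pre[off], regime.offhotspot_gain)
        np.testing.assert_allclose(
            post[truth.hotspot_mask] / pre[truth.hotspot_mask], regime.hotspot_gain
        )

    def test_peak_is_profile_max_at_center(self):
        pre, _, _ = synth.generate_linescan_pair(
            41, 15.0, 20, 3.0, RegimeSpec.preset("control"), seed=0
        )
        assert np.argmax(pre) == 20

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_linescan_pair(40, 15.0, 20, -1.0,
                                         RegimeSpec.preset("control"), seed=0)
        with pytest.raises(ValueError):
            synth.generate_linescan_pair(40, 15.0, 80, 2.0,
                                         RegimeSpec.preset("control"), seed=0)


class TestGenerateMovie:
    def test_zero_shifts_zero_noise_identity(self, rng):
        base = rng.random((32, 32))
        movie, _ = synth.generate_movie(base, [(0, 0)] * 3, noise_sd=0.0)
        for frame in movie:
            np.testing.assert_array_equal(frame, base)

    def test_out_of_bounds_shift_rejected(self, rng):
        base = rng.random((32, 32))
        with pytest.raises(ValueError, match="quarter"):
            synth.generate_movie(base, [(20, 0)], noise_sd=0.0)


class TestGenerateCompartmentData:
    def test_perfect_correlation(self):
        data, _ = synth.generate_compartment_data(100, 1.0, seed=0)
        r = np.corrcoef(data["dendrite"], data["soma"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_null_correlation_bounded(self):
        """Independent draws: sample r concentrates at 0 with SD 1/√n.

        A single sample r lands outside ±3/√n about 0.3% of the time, so the
        bound is asserted on the mean over k independent replicates (SE
        1/√(nk)) rather than on one draw.
        """
        n, k = 10_000, 20
        rs = []
        for s in range(k):
            data, _ = synth.generate_compartment_data(n, 0.0, seed=s)
            rs.append(np.corrcoef(data["dendrite"], data["soma"])[0, 1])
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(n * k)
        assert np.std(rs) < 3.0 / np.sqrt(n)

    def test_target_recovered_within_fisher_interval(self):
        n, target = 1000, 0.6
        data, _ = synth.generate_compartment_data(n, target, seed=2)
        r = np.corrcoef(data["dendrite"], data["ais"])[0, 1]
        z, z0 = np.arctanh(r), np.arctanh(target)
        assert abs(z - z0) < 2.576 / np.sqrt(n - 3)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_compartment_data(10, 1.5, seed=0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(hst.integers(0, 2**31 - 1))
def test_any_seed_reproducible(seed):
    cfg = SimConfig(n_trials=2, seed=seed)
    a, _ = synth.generate_trial_session(cfg)
    b, _ = synth.generate_trial_session(cfg)
    np.testing.assert_array_equal(a.trials[0].values, b.trials[0].values)


def test_stimulus_train_span():
    assert synth.stimulus_train_span(8, 100.0) == pytest.approx(0.07)
    assert synth.stimulus_train_span(1, 100.0) == 0.0
    with pytest.raises(ValueError):
        synth.stimulus_train_span(0, 100.0)
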