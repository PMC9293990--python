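"""Filters, envelopes, scoring, bootstrap machinery and TF significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps
from scipy import stats

from optoarousal.sleep import (
    Recording,
    TrialWindow,
    _multiset_resamples,
    arousal_probability,
    bca_interval,
    bootstrap_mean_distribution,
    cwt_power,
    emg_envelope,
    extract_trials,
    filter_eeg,
    filter_emg,
    paired_difference_bootstrap,
    remove_small_clusters,
    score_arousal,
    score_states,
    tf_significance,
    trial_mean_emg,
    trial_mean_power,
)
from optoarousal.synth import SleepSimConfig, simulate_sleep_recording

FS = 500.0


class TestFilters:
    def test_eeg_passband_tone_amplitude_and_phase(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        y = filter_eeg(x, FS)
        mid = slice(2000, -2000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)
        lag = np.argmax(sps.correlate(y[mid], x[mid], mode="full")) - (len(x[mid]) - 1)
        assert lag == 0

    def test_dc_attenuated(self):
        y = filter_eeg(np.ones(10_000), FS)
        assert 20 * np.log10(max(np.abs(y[2000:-2000]).max(), 1e-12)) < -40

    def test_emg_stopband_at_10hz(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        y = filter_emg(x, FS)
        assert 20 * np.log10(np.abs(y[2000:-2000]).max()) < -20

    def test_zero_phase_time_reversal_symmetry(self, rng):
        # forward-backward filtering commutes with time reversal away from
        # the edge transients of the 0.5-Hz corner
        x = rng.standard_normal(30_000)
        fwd_rev = filter_eeg(x, FS)[::-1]
        rev_fwd = filter_eeg(x[::-1], FS)
        mid = slice(10_000, -10_000)
        np.testing.assert_allclose(fwd_rev[mid], rev_fwd[mid], atol=1e-6)


class TestEmgEnvelope:
    def test_constant_amplitude_is_unity(self):
        env = emg_envelope(np.full(10_000, 3.0), FS)
        np.testing.assert_allclose(env, 1.0)

    def test_step_change_scales_envelope(self):
        x = np.r_[np.ones(5000), 3.0 * np.ones(5000)]
        # keep the pre-stimulus window clear of the smoothing ramp at the step
        env = emg_envelope(x, FS, prestim_window=(0.0, 9.0))
        assert env[7000:].mean() == pytest.approx(3.0, rel=0.02)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_prestim_mean_is_one_for_any_input(self, seed):
        x = np.random.default_rng(seed).standard_normal(8000) * 10 + 1
        env = emg_envelope(x, FS, prestim_window=(0.0, 10.0))
        assert env[: int(10 * FS)].mean() == pytest.approx(1.0, rel=1e-12)

    def test_zero_prestim_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            emg_envelope(np.r_[np.zeros(8000), np.ones(2000)], FS, prestim_window=(0.0, 10.0))


class TestScoreStates:
    def test_pure_nrem_recording(self):
        cfg = SleepSimConfig(duration_s=300.0, seed=1)
        rec, truth = simulate_sleep_recording(cfg)
        # build a pure-NREM signal by reusing the generator's band weights
        from optoarousal.synth import _band_noise
        from optoarousal._seeds import rng_for

        rng = rng_for(5, "pure_nrem")
        n = int(300 * FS)
        eeg = 4.0 * _band_noise(n, FS, 0.5, 4.0, rng) + 1.0 * _band_noise(n, FS, 5.0, 9.0, rng)
        emg = 1.0 * rng.standard_normal(n)
        labels = score_states(eeg, emg, FS)
        assert set(labels) == {"NREM"}

    def test_accuracy_against_generator_truth(self, short_sleep):
        cfg, rec, truth = short_sleep
        labels = score_states(rec.eeg, rec.emg, rec.fs, rec.epoch_length)
        assert (labels == truth.state_epochs).mean() >= 0.90

    def test_zero_emg_delta_dominant_never_wake(self):
        from optoarousal.synth import _band_noise
        from optoarousal._seeds import rng_for

        rng = rng_for(6, "delta")
        n = int(120 * FS)
        eeg = 4.0 * _band_noise(n, FS, 0.5, 4.0, rng)
        labels = score_states(eeg, np.zeros(n), FS)
        assert "Wake" not in labels


class TestExtractTrials:
    def test_pre_state_and_exclusions(self, short_sleep):
        cfg, rec, truth = short_sleep
        trials = extract_trials(rec)
        assert len(trials) == len(rec.stim_schedule)
        for trial in trials:
            if not trial.excluded:
                assert trial.pre_state in ("NREM", "REM")
                assert len(trial.eeg) == int(40 * rec.fs)

    def test_mixture_of_states_excluded(self):
        labels = np.array(["NREM"] * 10 + ["Wake"] * 1 + ["NREM"] * 29)
        sched = pd.DataFrame({"onset_s": [60.0], "condition": ["10Hz"], "pulse_width_ms": 5.0, "train_s": 10.0})
        rec = Recording(np.zeros(int(200 * FS)), np.zeros(int(200 * FS)), FS, sched, labels, 5.0)
        (trial,) = extract_trials(rec)
        assert trial.excluded and "mixture" in trial.exclude_reason

    def test_edge_clipped_trial_excluded(self):
        labels = np.array(["NREM"] * 40)
        sched = pd.DataFrame({"onset_s": [5.0], "condition": ["sham"], "pulse_width_ms": 5.0, "train_s": 10.0})
        rec = Recording(np.zeros(int(200 * FS)), np.zeros(int(200 * FS)), FS, sched, labels, 5.0)
        (trial,) = extract_trials(rec)
        assert trial.excluded and "clipped" in trial.exclude_reason


def _synthetic_trial(arousal_at=None, arousal_len=9.0, seed=0):
    """NREM trial; optional wake bout (high EMG, low delta) inside the train."""
    from optoarousal.synth import _band_noise
    from optoarousal._seeds import rng_for

    rng = rng_for(seed, "trial")
    n = int(40 * FS)
    delta_w = np.full(n, 4.0)
    gamma_w = np.full(n, 0.5)
    emg_w = np.full(n, 1.0)
    if arousal_at is not None:
        i0 = int((10 + arousal_at) * FS)
        i1 = min(n, i0 + int(arousal_len * FS))
        delta_w[i0:i1] = 1.0
        gamma_w[i0:i1] = 2.0
        emg_w[i0:i1] = 3.0
    eeg = delta_w * _band_noise(n, FS, 0.5, 4.0, rng) + 1.0 * _band_noise(n, FS, 5.0, 9.0, rng) + gamma_w * _band_noise(n, FS, 30.0, 80.0, rng)
    emg = emg_w * rng.standard_normal(n)
    return TrialWindow("10Hz", 100.0, "NREM", eeg, emg, FS)


class TestScoreArousal:
    def test_no_change_is_negative(self):
        assert score_arousal(_synthetic_trial(None, seed=1)) is False

    def test_sustained_arousal_detected(self):
        assert score_arousal(_synthetic_trial(arousal_at=1.0, arousal_len=9.0, seed=2)) is True

    def test_short_transient_rejected(self):
        # 2-s excursion is below the 3-s minimum
        assert score_arousal(_synthetic_trial(arousal_at=4.0, arousal_len=2.0, seed=3)) is False

    def test_excluded_trial_rejected(self):
        trial = _synthetic_trial(None, seed=4)
        trial.excluded = True
        with pytest.raises(ValueError, match="excluded"):
            score_arousal(trial)


class TestBootstrap:
    def test_exhaustive_count_for_five(self):
        W, p = _multiset_resamples(5)
        assert len(p) == 126  # distinct multisets
        assert p.sum() == pytest.approx(1.0)
        _, _, n_res = bootstrap_mean_distribution(np.arange(5.0))
        assert n_res == 3125  # all ordered with-replacement resamples

    def test_exhaustive_distribution_matches_direct_enumeration(self):
        import itertools

        data = np.array([0.3, 1.7, 2.2, 5.0])
        means, w, n_res = bootstrap_mean_distribution(data)
        assert n_res == 4**4
        direct = [np.mean([data[i] for i in tup]) for tup in itertools.product(range(4), repeat=4)]
        # compare weighted CDFs at several points
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            direct_q = np.quantile(direct, q, method="inverted_cdf")
            ours = means.ravel()
            order = np.argsort(ours)
            cdf = np.cumsum(w[order])
            ours_q = ours[order][np.searchsorted(cdf, q)]
            assert ours_q == pytest.approx(direct_q)

    def test_zero_differences_give_zero_interval(self):
        lo, hi, _ = bca_interval(np.zeros(5))
        assert lo == hi == 0.0

    def test_degenerate_unit_difference(self):
        lo, hi, _ = bca_interval(np.ones(5))
        assert (lo, hi) == (1.0, 1.0)

    def test_bca_matches_scipy_on_continuous_data(self, rng):
        data = rng.normal(0.5, 1.0, 9)
        lo, hi, n_res = bca_interval(data, n_boot=20_000, exhaustive_budget=10**3, seed=4)
        res = stats.bootstrap(
            (data,), np.mean, n_resamples=20_000, confidence_level=0.95,
            method="BCa", random_state=np.random.default_rng(0),
        )
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.08)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.08)


class TestArousalStats:
    def test_probability_table(self):
        df = pd.DataFrame(
            {
                "animal": [0, 0, 0, 0, 1, 1],
                "condition": ["sham", "sham", "10Hz", "10Hz", "sham", "10Hz"],
                "aroused": [0, 1, 1, 1, 0, 1],
                "excluded": [False] * 6,
            }
        )
        table = arousal_probability(df)
        assert table.loc[0, "sham"] == 0.5
        assert table.loc[0, "10Hz"] == 1.0

    def test_zero_difference_ci_contains_zero(self):
        table = pd.DataFrame({"sham": [0.2, 0.3, 0.1, 0.4, 0.25], "10Hz": [0.2, 0.3, 0.1, 0.4, 0.25]})
        stats_ = paired_difference_bootstrap(table)
        s = stats_["10Hz"]
        assert s.mean_difference == 0.0
        assert s.ci_low <= 0.0 <= s.ci_high

    def test_saturated_difference_degenerate_ci(self):
        table = pd.DataFrame({"sham": np.zeros(5), "10Hz": np.ones(5)})
        s = paired_difference_bootstrap(table)["10Hz"]
        assert s.mean_difference == 1.0
        assert (s.ci_low, s.ci_high) == (1.0, 1.0)
        assert s.n_resamples == 3125


class TestCwtPower:
    def test_tone_frequency_localized(self):
        t = np.arange(0, 20, 1 / FS)
        grid = cwt_power(np.sin(2 * np.pi * 4.0 * t), FS)
        mid = slice(int(5 * FS), int(15 * FS))
        argmax_f = grid.freqs[np.argmax(grid.power[:, mid].mean(axis=1))]
        step = grid.freqs[1] / grid.freqs[0]
        assert 4.0 / step <= argmax_f <= 4.0 * step

    def test_zero_signal_zero_power(self):
        grid = cwt_power(np.zeros(2000), FS)
        np.testing.assert_allclose(grid.power, 0.0)

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(3000)
        a = cwt_power(x, FS)
        b = cwt_power(2 * x, FS)
        np.testing.assert_allclose(b.power, 4 * a.power, rtol=1e-9)


class TestTfSignificance:
    def _noise_grids(self, rng, n_trials, F=12, T=800):
        return [rng.standard_normal((F, T)) ** 2 for _ in range(n_trials)]

    def test_identical_trials_empty_mask(self, rng):
        animals = [self._noise_grids(rng, 3) for _ in range(5)]
        times = np.arange(800) / FS
        freqs = np.linspace(1, 12, 12)
        grid = tf_significance(animals, animals, times, freqs, smooth_samples=100, downsample=10)
        assert grid.n_resamples == 3125
        assert not grid.mask.any()
        np.testing.assert_allclose(grid.diff, 0.0, atol=1e-12)

    def test_null_masked_fraction_near_alpha(self):
        fractions = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            real = [self._noise_grids(rng, 3) for _ in range(5)]
            sham = [self._noise_grids(rng, 3) for _ in range(5)]
            times = np.arange(800) / FS
            freqs = np.linspace(1, 12, 12)
            grid = tf_significance(real, sham, times, freqs, smooth_samples=100, downsample=10)
            fractions.append(grid.mask.mean())
        assert 0.0 <= np.mean(fractions) <= 0.12

    def test_planted_effect_detected(self, rng):
        times = np.arange(800) / FS
        freqs = np.linspace(1, 12, 12)
        real, sham = [], []
        for _ in range(5):
            r = self._noise_grids(rng, 3)
            for g in r:
                g[4:7, 300:500] += 10.0
            real.append(r)
            sham.append(self._noise_grids(rng, 3))
        grid = tf_significance(real, sham, times, freqs, smooth_samples=50, downsample=10)
        patch = grid.mask[4:7, 30:50]
        assert patch.mean() >= 0.8

    def test_mismatched_shapes_rejected(self, rng):
        a = [self._noise_grids(rng, 2)]
        b = [self._noise_grids(rng, 2, F=10)]
        with pytest.raises(ValueError, match="shape"):
            tf_significance(a + a, b + b, np.arange(800) / FS, np.linspace(1, 12, 12))

    def test_deterministic_exhaustive_path(self, rng):
        real = [self._noise_grids(rng, 2) for _ in range(4)]
        sham = [self._noise_grids(rng, 2) for _ in range(4)]
        times = np.arange(800) / FS
        freqs = np.linspace(1, 12, 12)
        g1 = tf_significance(real, sham, times, freqs, smooth_samples=100, downsample=10)
        g2 = tf_significance(real, sham, times, freqs, smooth_samples=100, downsample=10)
        np.testing.assert_array_equal(g1.ci_low, g2.ci_low)
        np.testing.assert_array_equal(g1.mask, g2.mask)


class TestClusterRemoval:
    def test_empty_mask_unchanged(self):
        out, removed = remove_small_clusters(np.zeros((5, 5), bool), 4)
        assert not out.any() and removed == 0

    def test_single_pixel_cleared(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        out, removed = remove_small_clusters(mask, 4)
        assert not out.any() and removed == 1

    def test_matches_floodfill_oracle(self, rng):
        mask = rng.random((10, 10)) < 0.4

        def flood_sizes(m):
            seen = np.zeros_like(m, bool)
            sizes = {}
            for i in range(m.shape[0]):
                for j in range(m.shape[1]):
                    if m[i, j] and not seen[i, j]:
                        stack, comp = [(i, j)], []
                        seen[i, j] = True
                        while stack:
                            a, b = stack.pop()
                            comp.append((a, b))
                            for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                                x, y = a + da, b + db
                                if 0 <= x < m.shape[0] and 0 <= y < m.shape[1] and m[x, y] and not seen[x, y]:
                                    seen[x, y] = True
                                    stack.append((x, y))
                        for cell in comp:
                            sizes[cell] = len(comp)
            return sizes

        sizes = flood_sizes(mask)
        for min_pixels in (2, 3, 5):
            out, _ = remove_small_clusters(mask, min_pixels)
            expect = np.zeros_like(mask)
            for (i, j), s in sizes.items():
                expect[i, j] = s >= min_pixels
            np.testing.assert_array_equal(out, expect)


class TestTrialMeans:
    def test_single_trial_identity(self, rng):
        g = rng.random((6, 50))
        out = trial_mean_power([g])
        np.testing.assert_array_equal(out.power, g)

    def test_two_constant_grids(self):
        a, b = np.full((4, 10), 2.0), np.full((4, 10), 6.0)
        out = trial_mean_power([a, b])
        np.testing.assert_allclose(out.power, 4.0)

    def test_constant_envelopes_zero_width_band(self):
        env = np.ones((4, 100))
        mean, lo, hi = trial_mean_emg(env)
        np.testing.assert_allclose(mean, 1.0)
        np.testing.assert_allclose(lo, hi)


def test_default_cluster_floor_spans_half_second_by_one_hz():
    from optoarousal.sleep import default_min_cluster_pixels

    times = np.arange(0, 20, 0.02)  # 50 columns per second
    freqs = 0.5 * 2 ** (np.arange(71) / 12)
    n = default_min_cluster_pixels(times, freqs)
    assert n >= 25  # at least the 0.5-s span in time alone
    assert n == default_min_cluster_pixels(times, freqs)  # deterministic
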