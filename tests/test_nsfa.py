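"""Peak-scaled fluctuation analysis: exact fits, oracles, invariances."""

import numpy as np
import pytest

from optoarousal.nsfa import (
    NsfaConfig,
    align_peaks,
    bin_by_current,
    fit_variance_mean,
    lowpass_sweeps,
    nsfa_pipeline,
    peak_scaled_variance,
    select_sweeps,
)
from optoarousal.psc import EventList, SweepSet
from optoarousal.synth import ChannelModel, simulate_evoked_sweeps

FS = 10_000.0


def _waveform_sweeps(n_sweeps=25, scale=None, noise=0.0, seed=0):
    """Sweeps sharing one two-exponential waveform, optionally rescaled."""
    rng = np.random.default_rng(seed)
    t = np.arange(3000) / FS
    onset = 0.05
    g = np.where(t >= onset, np.exp(-(t - onset) / 0.03) - np.exp(-(t - onset) / 0.0005), 0.0)
    g /= g.max()
    scale = np.ones(n_sweeps) if scale is None else np.asarray(scale)
    sweeps = 60.0 * scale[:, None] * g[None, :] + rng.normal(0, noise, (n_sweeps, len(t)))
    return SweepSet(-sweeps, FS, [int(onset * FS)], polarity="inward")


class TestLowpass:
    def test_dc_preserved(self):
        ss = SweepSet(np.full((3, 2000), 12.5), FS, [100])
        out = lowpass_sweeps(ss, 1000.0)
        np.testing.assert_allclose(out.sweeps, 12.5, rtol=1e-6)

    def test_stopband_attenuation(self):
        t = np.arange(20_000) / 20_000.0
        tone = np.sin(2 * np.pi * 5000 * t)
        ss = SweepSet(tone[None, :], 20_000.0, [0])
        out = lowpass_sweeps(ss, 1000.0)
        mid = out.sweeps[0, 2000:-2000]  # keep clear of filtfilt edge transients
        atten_db = 20 * np.log10(np.abs(mid).max() / 1.0)
        assert atten_db < -20

    def test_white_noise_variance_shrinks(self, rng):
        ss = SweepSet(rng.standard_normal((2, 5000)), FS, [0])
        out = lowpass_sweeps(ss, 1000.0)
        assert out.sweeps.var() < ss.sweeps.var()

    def test_cutoff_above_nyquist_rejected(self):
        ss = SweepSet(np.zeros((1, 100)), FS, [0])
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_sweeps(ss, 6000.0)


class TestSelectSweeps:
    def _sweeps(self, n):
        return SweepSet(np.zeros((n, 1000)), FS, [500])

    def test_no_events_keeps_all(self):
        ss = self._sweeps(25)
        out, valid, excluded = select_sweeps(ss, None)
        assert out.n_sweeps == 25 and valid and excluded == []

    @pytest.mark.parametrize(
        "n,contaminated,expect_valid,expect_kept",
        [(25, 10, False, 15), (40, 5, True, 35)],
    )
    def test_contamination_threshold(self, n, contaminated, expect_valid, expect_kept):
        ss = self._sweeps(n)
        ev = EventList(
            np.arange(contaminated), np.full(contaminated, 0.06), np.ones(contaminated), np.full(contaminated, 0.059)
        )
        out, valid, excluded = select_sweeps(ss, ev)
        assert out.n_sweeps == expect_kept
        assert valid is expect_valid
        assert len(excluded) == contaminated

    def test_events_outside_window_ignored(self):
        ss = self._sweeps(25)
        ev = EventList([0, 1], [0.01, 0.02], [5.0, 5.0], [0.009, 0.019])  # pre-pulse
        out, valid, _ = select_sweeps(ss, ev)
        assert out.n_sweeps == 25 and valid


class TestAlignPeaks:
    def test_identical_sweeps_zero_shift(self):
        ss = _waveform_sweeps(5)
        aligned, mean_wf, excluded = align_peaks(ss)
        np.testing.assert_allclose(aligned.sweeps, ss.rectified(), atol=1e-12)
        assert excluded == []

    def test_known_shifts_recovered(self):
        base = _waveform_sweeps(5)
        shifts = np.array([-30, -10, 0, 10, 30])
        shifted = np.stack([np.roll(base.sweeps[i], s) for i, s in enumerate(shifts)])
        ss = SweepSet(shifted, FS, base.pulse_onsets, polarity="inward")
        aligned, mean_wf, _ = align_peaks(ss)
        # all peaks land on one common sample
        peaks = np.argmax(aligned.sweeps, axis=1)
        assert np.ptp(peaks) == 0

    def test_peakless_sweep_excluded(self):
        ss = _waveform_sweeps(5, noise=1.0, seed=1)
        flat = np.random.default_rng(2).normal(0, 1.0, (1, ss.n_samples))
        both = SweepSet(np.vstack([ss.sweeps, -flat]), FS, ss.pulse_onsets, polarity="inward")
        aligned, _, excluded = align_peaks(both)
        assert excluded == [5]
        assert aligned.n_sweeps == 5

    def test_mean_peak_of_identical_shapes(self):
        scale = np.array([0.5, 1.0, 1.5])
        ss = _waveform_sweeps(3, scale=scale)
        aligned, mean_wf, _ = align_peaks(ss)
        assert mean_wf.max() == pytest.approx(60.0 * scale.mean(), rel=1e-6)


class TestPeakScaledVariance:
    def test_identical_sweeps_zero_variance(self):
        ss = _waveform_sweeps(10)
        aligned, mean_wf, _ = align_peaks(ss)
        I, var, _ = peak_scaled_variance(aligned, mean_wf)
        np.testing.assert_allclose(var, 0.0, atol=1e-18)

    def test_pure_rescaling_zero_variance(self):
        scale = np.linspace(0.6, 1.4, 12)
        ss = _waveform_sweeps(12, scale=scale)
        aligned, mean_wf, _ = align_peaks(ss)
        I, var, _ = peak_scaled_variance(aligned, mean_wf)
        np.testing.assert_allclose(var, 0.0, atol=1e-16)

    def test_peak_scaling_removes_peak_variance(self, evoked_ensemble):
        model, sweeps, truth = evoked_ensemble
        aligned, mean_wf, _ = align_peaks(sweeps)
        I, var, details = peak_scaled_variance(aligned, mean_wf)
        pk = details["peak_index"]
        unscaled = aligned.sweeps.var(axis=0, ddof=1)[pk]
        assert var[0] < unscaled  # var[0] is the peak sample of the decay segment


class TestBinByCurrent:
    def test_linear_decay_equal_occupancy(self):
        I = np.linspace(60.0, 0.2, 300)
        var = np.ones_like(I)
        I_k, v_k, counts, dropped = bin_by_current(I, var, 30)
        assert len(I_k) == 30 and dropped == 0
        assert np.all(counts == 10)

    def test_occupancy_conserved(self, rng):
        I = 60 * np.exp(-np.arange(400) / 120.0) + rng.normal(0, 1.5, 400)
        var = rng.uniform(0, 5, 400)
        I_k, v_k, counts, dropped = bin_by_current(I, var, 30)
        assert counts.sum() == 400

    def test_matches_bruteforce_assignment(self, rng):
        # non-monotone decay: assignment by current value, not time order
        I = np.r_[np.linspace(50, 5, 40), 20 + rng.normal(0, 3, 20)]
        var = rng.uniform(0, 10, len(I))
        n_bins = 8
        I_k, v_k, counts, _ = bin_by_current(I, var, n_bins)
        edges = np.linspace(I.min(), I.max(), n_bins + 1)
        expect = {}
        for x, v in zip(I, var):  # exhaustive per-sample assignment oracle
            k = n_bins - 1 if x >= edges[-2] else int((x - edges[0]) // np.diff(edges)[0])
            k = min(max(k, 0), n_bins - 1)
            expect.setdefault(k, []).append((x, v))
        occupied = sorted(expect)
        assert len(I_k) == len(occupied)
        for out_i, k in enumerate(occupied):
            xs, vs = zip(*expect[k])
            assert I_k[out_i] == pytest.approx(np.mean(xs))
            assert v_k[out_i] == pytest.approx(np.mean(vs))

    def test_constant_current_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            bin_by_current(np.ones(50), np.ones(50))


class TestFitVarianceMean:
    def test_exact_recovery(self):
        I = np.arange(2.0, 62.0, 2.0)
        var = 2.0 * I - I**2 / 50.0 + 1.0
        est = fit_variance_mean(I, var)
        assert est.valid
        assert est.unitary_current_i == pytest.approx(2.0, rel=1e-9)
        assert est.n_channels_N == pytest.approx(50.0, rel=1e-9)
        assert est.baseline_variance_b == pytest.approx(1.0, rel=1e-9)

    def test_exact_recovery_with_fixed_b(self):
        I = np.arange(2.0, 32.0, 2.0)
        var = 1.5 * I - I**2 / 80.0 + 2.5
        est = fit_variance_mean(I, var, fix_b=2.5)
        assert est.unitary_current_i == pytest.approx(1.5, rel=1e-9)
        assert est.n_channels_N == pytest.approx(80.0, rel=1e-9)

    def test_constant_variance_flagged_invalid(self):
        I = np.arange(2.0, 42.0, 2.0)
        est = fit_variance_mean(I, np.full_like(I, 3.0))
        assert not est.valid
        assert abs(est.unitary_current_i) < 1e-9
        assert est.raw_coefficients is not None

    def test_algebraic_identities_on_valid_fit(self):
        I = np.arange(2.0, 62.0, 2.0)
        var = 1.2 * I - I**2 / 120.0 + 4.0
        est = fit_variance_mean(I, var)
        # parabola value at I -> 0 equals b; vertex at I = i*N/2
        assert est.predicted_variance(np.array([0.0]))[0] == pytest.approx(est.baseline_variance_b)
        vertex = est.unitary_current_i * est.n_channels_N / 2
        dI = 1e-4
        slope = (est.predicted_variance(np.array([vertex + dI])) - est.predicted_variance(np.array([vertex - dI]))) / (2 * dI)
        assert slope[0] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_bins_invalid(self):
        est = fit_variance_mean(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert not est.valid and est.flags


class TestPipeline:
    CFG = NsfaConfig(lowpass_hz=None)

    def test_parameter_recovery(self):
        # N = 100, i = 1.0: medians across replicates within the estimator's band
        model = ChannelModel(n_channels=100, unitary_current=1.0, open_prob_peak=0.6, peak_cv=0.1, baseline_noise_sd=2.0)
        Ns, is_ = [], []
        for seed in range(8):
            sweeps, _ = simulate_evoked_sweeps(model, 100, seed=seed)
            est = nsfa_pipeline(sweeps, config=self.CFG)
            assert est.valid
            Ns.append(est.n_channels_N)
            is_.append(est.unitary_current_i)
        assert np.median(Ns) == pytest.approx(100.0, rel=0.15)
        assert np.median(is_) == pytest.approx(1.0, rel=0.10)

    def test_rescaling_invariance(self):
        model = ChannelModel(n_channels=100, unitary_current=1.0, open_prob_peak=0.6, peak_cv=0.1)
        sweeps, _ = simulate_evoked_sweeps(model, 100, seed=3)
        est1 = nsfa_pipeline(sweeps, config=self.CFG)
        c = 2.5
        scaled = SweepSet(c * sweeps.sweeps, sweeps.fs, sweeps.pulse_onsets, polarity=sweeps.polarity)
        est2 = nsfa_pipeline(scaled, config=self.CFG)
        assert est2.unitary_current_i / est1.unitary_current_i == pytest.approx(c, rel=0.02)
        assert est2.n_channels_N == pytest.approx(est1.n_channels_N, rel=0.02)

    def test_too_few_clean_sweeps_invalid(self):
        model = ChannelModel()
        sweeps, _ = simulate_evoked_sweeps(model, 15, seed=5)
        est = nsfa_pipeline(sweeps, config=self.CFG)
        assert not est.valid
        assert any("clean sweeps" in f for f in est.flags)

    def test_bias_shrinks_with_sweep_count(self):
        model = ChannelModel(n_channels=100, unitary_current=1.0, open_prob_peak=0.6, peak_cv=0.1)
        errs = []
        for n_sweeps in (50, 400):
            e = []
            for seed in range(4):
                sweeps, _ = simulate_evoked_sweeps(model, n_sweeps, seed=100 + seed)
                est = nsfa_pipeline(sweeps, config=self.CFG)
                e.append(abs(est.n_channels_N - 100.0))
            errs.append(np.median(e))
        assert errs[1] <= errs[0] * 1.5  # no blow-up; typically a clear decrease

    def test_report_schema(self, evoked_ensemble):
        _, sweeps, _ = evoked_ensemble
        est = nsfa_pipeline(sweeps, config=self.CFG)
        d = est.to_dict()
        for key in ("unitary_current_i_pA", "n_channels_N", "baseline_variance_b_pA2", "valid"):
            assert key in d
        assert len(d["binned_current_I_pA"]) == len(d["binned_variance_pA2"])
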