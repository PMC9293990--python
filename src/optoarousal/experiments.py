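"""Reproducibility experiments: parameter recovery and calibration suites.

Each function runs one self-contained simulation experiment through the
package's public pipeline and returns scalar summaries. They are shared
by the test suite and by ``scripts/acceptance.py`` so that both always
report the same computation.

Problem sizes are chosen to resolve each question on a single CPU in
seconds to a few minutes: 100-sweep ensembles over 20 replicate seeds for
fluctuation-analysis recovery, 200 cells for the connectivity null, 20
seeds of five-animal sessions for the sleep statistics, and 20-second EEG
segments for the time-frequency calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import derive_seed, rng_for
from .nsfa import NsfaConfig, align_peaks, fit_variance_mean, nsfa_pipeline, peak_scaled_variance
from .psc import classify_connectivity, detect_events, peristimulus_probability, DetectionParams, EventList, SweepSet
from .sleep import (
    arousal_probability,
    cwt_power,
    default_freqs,
    extract_trials,
    paired_difference_bootstrap,
    score_arousal,
    tf_significance,
)
from .synth import (
    ChannelModel,
    SleepSimConfig,
    SpontaneousModel,
    _band_noise,
    render_trace,
    simulate_evoked_sweeps,
    simulate_spontaneous_events,
    simulate_sleep_recording,
    _kernel_peak_offset,
    _kernel_rise5_offset,
)

# the generator's defaults double as the study conditions
NSFA_MODEL = dict(unitary_current=1.0, open_prob_peak=0.6, peak_cv=0.1, baseline_noise_sd=2.0)
NSFA_CFG = NsfaConfig(lowpass_hz=None)  # generator noise is white up to Nyquist


def exhaustive_resample_count(n_animals: int = 5, seed: int = 0) -> dict:
    """Resample count of the exhaustive paired bootstrap over n animals."""
    rng = rng_for(seed, "exhaustive-count")
    grids = [[rng.standard_normal((6, 40)) ** 2] for _ in range(n_animals)]
    sham = [[rng.standard_normal((6, 40)) ** 2] for _ in range(n_animals)]
    out = tf_significance(grids, sham, np.arange(40) / 10.0, np.linspace(1, 6, 6), smooth_samples=5, downsample=2)
    return {"n_resamples": int(out.n_resamples)}


def nsfa_exact_fit() -> dict:
    """Recovery of (i, N, b) from exact parabola points."""
    I = np.arange(2.0, 62.0, 2.0)
    var = 2.0 * I - I**2 / 50.0 + 1.0
    est = fit_variance_mean(I, var)
    rel = max(
        abs(est.unitary_current_i - 2.0) / 2.0,
        abs(est.n_channels_N - 50.0) / 50.0,
        abs(est.baseline_variance_b - 1.0),
    )
    return {"i": est.unitary_current_i, "N": est.n_channels_N, "b": est.baseline_variance_b, "max_rel_error": rel}


def nsfa_recovery(seed: int = 0, n_channels: int = 100, n_sweeps: int = 100, n_seeds: int = 20) -> dict:
    """Median recovered (N, i) across replicate simulated ensembles."""
    model = ChannelModel(n_channels=n_channels, **NSFA_MODEL)
    Ns, is_ = [], []
    for k in range(n_seeds):
        sweeps, _ = simulate_evoked_sweeps(model, n_sweeps, seed=derive_seed(seed, f"nsfa-rec-{k}"))
        est = nsfa_pipeline(sweeps, config=NSFA_CFG)
        Ns.append(est.n_channels_N)
        is_.append(est.unitary_current_i)
    return {
        "median_N": float(np.median(Ns)),
        "median_i": float(np.median(is_)),
        "true_N": n_channels,
        "true_i": 1.0,
    }


def nsfa_drug_effect(seed: int = 0, n_seeds: int = 20) -> dict:
    """Doubling N with i fixed: paired recovery across replicates."""
    ctrl = ChannelModel(n_channels=100, **NSFA_MODEL)
    drug = ChannelModel(n_channels=200, **NSFA_MODEL)
    rows = []
    for k in range(n_seeds):
        s_c, _ = simulate_evoked_sweeps(ctrl, 100, seed=derive_seed(seed, f"drug-c-{k}"))
        s_d, _ = simulate_evoked_sweeps(drug, 100, seed=derive_seed(seed, f"drug-d-{k}"))
        e_c = nsfa_pipeline(s_c, config=NSFA_CFG)
        e_d = nsfa_pipeline(s_d, config=NSFA_CFG)
        rows.append((e_c.n_channels_N, e_d.n_channels_N, e_c.unitary_current_i, e_d.unitary_current_i))
    arr = np.asarray(rows)
    return {
        "median_N_ctrl": float(np.median(arr[:, 0])),
        "median_N_drug": float(np.median(arr[:, 1])),
        "N_ratio": float(np.median(arr[:, 1]) / np.median(arr[:, 0])),
        "median_i_ctrl": float(np.median(arr[:, 2])),
        "median_i_drug": float(np.median(arr[:, 3])),
        "fraction_N_increased": float(np.mean(arr[:, 1] > arr[:, 0])),
    }


def peak_scaled_degenerate(seed: int = 0) -> dict:
    """Peak-scaled variance of identical and purely rescaled sweeps."""
    rng = rng_for(seed, "degenerate")
    t = np.arange(3000) / 10_000.0
    g = np.where(t >= 0.05, np.exp(-(t - 0.05) / 0.03) - np.exp(-(t - 0.05) / 0.0005), 0.0)
    g /= g.max()
    identical = SweepSet(-60.0 * np.tile(g, (10, 1)), 10_000.0, [500], polarity="inward")
    scales = rng.uniform(0.5, 1.5, 12)
    rescaled = SweepSet(-60.0 * scales[:, None] * g[None, :], 10_000.0, [500], polarity="inward")
    out = {}
    for name, ss in (("identical", identical), ("rescaled", rescaled)):
        aligned, mean_wf, _ = align_peaks(ss)
        _, var, _ = peak_scaled_variance(aligned, mean_wf)
        out[f"max_var_{name}"] = float(np.abs(var).max())
    return out


def connectivity_criterion(seed: int = 0, n_cells: int = 200, n_pulses: int = 90) -> dict:
    """Threshold arithmetic on the population baseline, plus a null simulation.

    Null cells carry Poisson background matched to the population baseline
    probability (0.2243 per 50-ms bin) and are classified against the
    across-cell threshold; 90 pulses per cell (15 min at 0.1 Hz).
    """

    class _Profile:
        def __init__(self, evoked):
            self.first_post_bin = evoked

        def baseline_bins(self):
            return np.array([])

    res_hi = classify_connectivity(_Profile(0.93), 0.2243, 0.0184)
    res_lo = classify_connectivity(_Profile(0.30), 0.2243, 0.0184)

    rate = -np.log(1 - 0.2243) / 0.05
    fp = 0
    for k in range(n_cells):
        ev = simulate_spontaneous_events(
            SpontaneousModel(rate=rate), n_pulses * 10.0 + 1.0, seed=derive_seed(seed, f"null-cell-{k}")
        )
        pulses = [(0, t) for t in np.arange(1.0, n_pulses * 10.0, 10.0)]
        prof = peristimulus_probability(ev, pulses)
        fp += classify_connectivity(prof, 0.2243, 0.0184).is_connected
    return {
        "threshold": res_hi.threshold,
        "connected_at_093": bool(res_hi.is_connected),
        "connected_at_030": bool(res_lo.is_connected),
        "null_false_positive_rate": fp / n_cells,
    }


def latency_recovery(seed: int = 0, delay_ms: float = 4.0, n_sweeps: int = 30) -> dict:
    """Evoked events at a fixed 4-ms latency, detected and timed at 10 kHz."""
    fs, onset = 10_000.0, 0.1
    r5 = _kernel_rise5_offset(0.5, 10.0)
    t_onset = onset + delay_ms / 1000.0 - r5
    t_peak = t_onset + _kernel_peak_offset(0.5, 10.0)
    truth = EventList([0], [t_peak], [80.0], [t_onset + r5])
    sweeps = np.stack(
        [
            render_trace(truth, (0.5, 10.0), 2.0, fs, 0.3, polarity="inward", seed=derive_seed(seed, f"lat-{i}"))
            for i in range(n_sweeps)
        ]
    )
    ss = SweepSet(sweeps, fs, [int(onset * fs)], polarity="inward")
    events = EventList.concatenate(
        [
            detect_events(ss.sweeps[i], fs, "inward", DetectionParams(amplitude_threshold_pA=20.0), sweep_index=i)
            for i in range(n_sweeps)
        ]
    )
    from .psc import opsc_latency

    _, mean = opsc_latency(ss, events)
    return {"mean_latency_ms": mean, "abs_error_ms": abs(mean - delay_ms)}


def filter_calibration() -> dict:
    """Zero-phase and attenuation figures of the EEG/EMG filters."""
    from scipy import signal as sps

    from .sleep import filter_eeg, filter_emg

    fs = 500.0
    t = np.arange(0, 30, 1 / fs)
    tone = np.sin(2 * np.pi * 10 * t)
    mid = slice(2000, -2000)

    y = filter_eeg(tone, fs)
    lag = int(np.argmax(sps.correlate(y[mid], tone[mid], mode="full")) - (len(tone[mid]) - 1))
    gain = float(np.abs(y[mid]).max())

    dc = filter_eeg(np.ones(15_000), fs)
    dc_db = float(20 * np.log10(max(np.abs(dc[2000:-2000]).max(), 1e-12)))

    e = filter_emg(tone, fs)
    emg_db = float(20 * np.log10(np.abs(e[mid]).max()))
    return {"eeg_tone_gain": gain, "eeg_tone_lag_samples": lag, "dc_attenuation_db": dc_db, "emg_10hz_attenuation_db": emg_db}


def emg_envelope_normalization(seed: int = 0, n_inputs: int = 20) -> dict:
    """Pre-stimulus mean of the normalized envelope over arbitrary inputs."""
    from .sleep import emg_envelope

    fs = 500.0
    worst = 0.0
    for k in range(n_inputs):
        rng = rng_for(seed, f"env-{k}")
        x = rng.standard_normal(int(40 * fs)) * rng.uniform(0.5, 20) + rng.uniform(-5, 5)
        env = emg_envelope(x, fs, prestim_window=(0.0, 10.0))
        worst = max(worst, abs(env[: int(10 * fs)].mean() - 1.0))
    return {"max_abs_deviation": worst}


# ---------------------------------------------------------------------------
# time-frequency calibration


def _nrem_segment(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    return (
        4.0 * _band_noise(n, fs, 0.5, 4.0, rng)
        + 1.0 * _band_noise(n, fs, 5.0, 9.0, rng)
        + 0.5 * _band_noise(n, fs, 30.0, 80.0, rng)
        + 0.3 * rng.standard_normal(n)
    )


def tf_null_calibration(seed: int = 0, n_seeds: int = 20, n_animals: int = 5, trials_per_group: int = 3, segment_s: float = 20.0) -> dict:
    """Sham-vs-sham masked-pixel fraction of the TF significance map."""
    fs = 500.0
    n = int(segment_s * fs)
    freqs = default_freqs()
    times = np.arange(n) / fs
    fractions = []
    for s in range(n_seeds):
        real, sham = [], []
        for a in range(n_animals):
            rng = rng_for(seed, f"tfnull-{s}-{a}")
            r = [cwt_power(_nrem_segment(rng, n, fs), fs, freqs).power for _ in range(trials_per_group)]
            sh = [cwt_power(_nrem_segment(rng, n, fs), fs, freqs).power for _ in range(trials_per_group)]
            real.append([np.mean(r, axis=0)])
            sham.append([np.mean(sh, axis=0)])
        grid = tf_significance(real, sham, times, freqs)
        fractions.append(float(grid.mask.mean()))
    return {"mask_fraction_mean": float(np.mean(fractions)), "mask_fractions": fractions}


def tf_planted_effect(seed: int = 0, n_seeds: int = 5, n_animals: int = 5, trials_per_group: int = 3, segment_s: float = 20.0) -> dict:
    """Detection of a 2 s x 4 Hz power increase planted in the real trials.

    A strong 4-8 Hz oscillatory transient is added to every real trial of
    every animal during a 2-s window; detection is the masked fraction of
    the patch (4-8 Hz x the 2-s window) in the significance map, and the
    false fraction is measured outside the patch with a 1.5-s temporal and
    one-octave spectral guard band around it: the 1-s smoothing window and
    the Morlet bandwidth (sigma_f = f/6) necessarily spread the planted
    power into that margin, so it belongs to the signal, not to the
    false-positive budget.
    """
    fs = 500.0
    n = int(segment_s * fs)
    freqs = default_freqs()
    times = np.arange(n) / fs
    t0, t1 = segment_s / 2 - 1.0, segment_s / 2 + 1.0
    f_lo, f_hi = 4.0, 8.0

    inside_frac, outside_frac = [], []
    for s in range(n_seeds):
        real, sham = [], []
        for a in range(n_animals):
            rng = rng_for(seed, f"tfplant-{s}-{a}")
            r_trials = []
            for _ in range(trials_per_group):
                x = _nrem_segment(rng, n, fs)
                burst = 8.0 * _band_noise(n, fs, f_lo, f_hi, rng)
                win = (times >= t0) & (times < t1)
                x = x + burst * win
                r_trials.append(cwt_power(x, fs, freqs).power)
            sh = [cwt_power(_nrem_segment(rng, n, fs), fs, freqs).power for _ in range(trials_per_group)]
            real.append([np.mean(r_trials, axis=0)])
            sham.append([np.mean(sh, axis=0)])
        grid = tf_significance(real, sham, times, freqs)
        in_f = (grid.freqs >= f_lo) & (grid.freqs <= f_hi)
        in_t = (grid.times >= t0) & (grid.times < t1)
        patch = grid.mask[np.ix_(in_f, in_t)]
        guard_f = (grid.freqs >= f_lo / 2) & (grid.freqs <= f_hi * 2)
        guard_t = (grid.times >= t0 - 1.5) & (grid.times < t1 + 1.5)
        guard = guard_f[:, None] & guard_t[None, :]
        outside = grid.mask[~guard]
        inside_frac.append(float(patch.mean()))
        outside_frac.append(float(outside.mean()))
    return {
        "patch_detection_fraction": float(np.mean(inside_frac)),
        "outside_masked_fraction": float(np.mean(outside_frac)),
    }


# ---------------------------------------------------------------------------
# end-to-end sleep pipeline


def sleep_pipeline_coverage(
    seed: int = 0,
    n_seeds: int = 20,
    n_animals: int = 5,
    trials_per_animal: int = 40,
    true_probs: dict | None = None,
) -> dict:
    """End-to-end arousal-probability difference and its BCa CI coverage.

    Each replicate simulates five animals' closed-loop sessions (sham and
    10-Hz trains, arousal probabilities 0.1 and 0.9), scores arousals
    automatically, and checks whether the BCa 95% CI of the mean paired
    difference covers the generative difference of 0.8.
    """
    probs = true_probs or {"sham": 0.1, "10Hz": 0.9}
    true_diff = probs["10Hz"] - probs["sham"]
    covered, estimates = [], []
    for s in range(n_seeds):
        rows = []
        for a in range(n_animals):
            cfg = SleepSimConfig(
                duration_s=9000.0,
                stim_conditions=("sham", "10Hz"),
                arousal_prob=probs,
                seed=derive_seed(seed, f"cov-{s}-{a}"),
            )
            rec, _ = simulate_sleep_recording(cfg)
            n_used = 0
            for trial in extract_trials(rec):
                if trial.excluded:
                    continue
                rows.append({"animal": a, "condition": trial.condition, "aroused": score_arousal(trial)})
                n_used += 1
                if n_used >= trials_per_animal:
                    break
        table = arousal_probability(pd.DataFrame(rows))
        stats = paired_difference_bootstrap(table, seed=derive_seed(seed, f"cov-boot-{s}"))["10Hz"]
        covered.append(stats.ci_low <= true_diff <= stats.ci_high)
        estimates.append(stats.mean_difference)
    return {
        "coverage": float(np.mean(covered)),
        "mean_estimated_difference": float(np.mean(estimates)),
        "true_difference": true_diff,
    }
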