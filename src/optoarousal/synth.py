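"""Synthetic data with known ground truth for the whole analysis chain.

Three generators are provided:

* quantal opto-evoked postsynaptic currents — a binomial channel model
  (``N`` channels of unitary current ``i``, two-exponential open-probability
  time course, lognormal trial-to-trial peak scaling, Gaussian baseline
  noise), the generative counterpart of the variance–mean relation
  ``sigma^2 = i*I - I^2/N + b`` that peak-scaled fluctuation analysis fits;
* spontaneous synaptic event trains — homogeneous Poisson times with
  lognormal amplitudes, rendered into current traces as sums of
  difference-of-exponential kernels;
* state-structured EEG/EMG polysomnography — a semi-Markov wake/NREM/REM
  process, per-state band-limited EEG spectra and EMG tone, a closed-loop
  stimulation schedule (trains triggered only after >= 20 s of stable
  NREM/REM, >= 3 min refractory, capped at 200 stimulations) and
  probabilistic, latency-distributed arousal responses.

Every generator is deterministic given its configuration and seed; each
draws from a substream derived from the seed and a stage name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, signal

from ._seeds import rng_for
from .psc import EventList, SweepSet, polarity_sign
from .sleep import Recording

__all__ = [
    "ChannelModel",
    "SpontaneousModel",
    "SleepSimConfig",
    "GroundTruth",
    "dexp_kernel",
    "simulate_evoked_sweeps",
    "simulate_spontaneous_events",
    "render_trace",
    "generate_stim_schedule",
    "simulate_sleep_recording",
]

STATES = ("Wake", "NREM", "REM")
CONDITIONS = ("sham", "1Hz", "5Hz", "10Hz", "20Hz")


@dataclass
class ChannelModel:
    """Binomial model of an opto-evoked synaptic current.

    ``n_channels`` channels each pass ``unitary_current`` pA when open;
    the open probability follows a difference-of-exponentials time course
    peaking at ``open_prob_peak``, scaled sweep-to-sweep by a lognormal
    factor with coefficient of variation ``peak_cv``.
    """

    n_channels: int = 100
    unitary_current: float = 1.0  # pA, magnitude
    open_prob_peak: float = 0.6
    rise_tau: float = 0.5  # ms
    decay_tau: float = 30.0  # ms
    peak_cv: float = 0.1
    baseline_noise_sd: float = 2.0  # pA
    polarity: Literal["inward", "outward"] = "inward"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("kinetics require decay_tau > rise_tau > 0")
        if not (0 <= self.open_prob_peak <= 1):
            raise ValueError("open_prob_peak must lie in [0, 1]")
        if self.peak_cv < 0:
            raise ValueError("peak_cv must be >= 0")
        if self.open_prob_peak * (1 + 3 * self.peak_cv) > 1 + 1e-12:
            raise ValueError("open_prob_peak * (1 + 3*peak_cv) must not exceed 1")
        polarity_sign(self.polarity)


@dataclass
class SpontaneousModel:
    """Poisson spontaneous PSC train with lognormal amplitudes."""

    rate: float = 2.0  # events / s
    amplitude_mean: float = 50.0  # pA
    amplitude_cv: float = 0.3
    rise_tau: float = 0.5  # ms
    decay_tau: float = 10.0  # ms

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.amplitude_mean <= 0:
            raise ValueError("amplitude_mean must be positive")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("kinetics require decay_tau > rise_tau > 0")


def _default_band_powers() -> dict:
    # relative delta/theta/gamma amplitude weights per state
    return {"Wake": (1.0, 1.5, 2.0), "NREM": (4.0, 1.0, 0.5), "REM": (1.0, 4.0, 1.0)}


@dataclass
class SleepSimConfig:
    """Study conditions for the simulated closed-loop sleep experiment.

    Protocol constants (500 Hz digitization, 10-s trains at 1/5/10/20 Hz
    plus interleaved sham, 5-ms pulses, >= 20 s state persistence to
    trigger, >= 3 min refractory, <= 200 stimulations per session) match
    the in-vivo recording protocol; dwell times, spectra and arousal
    probabilities are the generator's nominal conditions.
    """

    fs: float = 500.0
    epoch_length: float = 5.0  # s
    duration_s: float = 7200.0
    state_dwell_means: dict = field(default_factory=lambda: {"Wake": 60.0, "NREM": 120.0, "REM": 60.0})
    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 1.0, 0.0], [0.65, 0.0, 0.35], [0.9, 0.1, 0.0]])
    )
    band_powers: dict = field(default_factory=_default_band_powers)
    broadband_level: float = 0.3
    eeg_amp_uV: float = 20.0
    emg_base_uV: float = 10.0
    emg_tone: dict = field(default_factory=lambda: {"Wake": 3.0, "NREM": 1.0, "REM": 0.5})
    arousal_prob: dict = field(
        default_factory=lambda: {"sham": 0.1, "1Hz": 0.25, "5Hz": 0.5, "10Hz": 0.9, "20Hz": 0.9}
    )
    arousal_latency_mean: float = 2.0  # s
    stim_conditions: tuple = CONDITIONS
    pulse_width_ms: float = 5.0
    train_duration: float = 10.0  # s
    refractory: float = 180.0  # s
    max_stims: int = 200
    min_state_s: float = 20.0  # state persistence required to trigger
    wake_bout_min_s: float = 5.0  # minimum wake bout after an arousal
    hold_state_during_train: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (3, 3):
            raise ValueError("transition_matrix must be 3x3 (Wake, NREM, REM)")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0):
            raise ValueError("transition_matrix rows must sum to 1")
        offdiag = self.transition_matrix * (1 - np.eye(3))
        if np.any(offdiag.sum(axis=1) <= 0):
            raise ValueError("degenerate transition matrix: a state has no exit probability")
        for p in self.arousal_prob.values():
            if not (0 <= p <= 1):
                raise ValueError("arousal probabilities must lie in [0, 1]")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        for s in STATES:
            if self.state_dwell_means.get(s, 0) <= 0:
                raise ValueError(f"dwell mean for {s} must be positive")


@dataclass
class GroundTruth:
    """Generator-side truth used as the oracle in tests.

    Only the fields relevant to the generated artifact are populated.
    """

    open_counts: np.ndarray | None = None  # (n_sweeps, n_samples), evoked sweeps
    peak_scales: np.ndarray | None = None  # lognormal per-sweep factors
    events: EventList | None = None  # true spontaneous events
    state_epochs: np.ndarray | None = None  # per-epoch labels after arousals
    base_state_epochs: np.ndarray | None = None  # labels before arousal overrides
    state_samples: np.ndarray | None = None  # per-sample state codes (0/1/2)
    arousals: pd.DataFrame | None = None  # one row per stimulation trial
    dwell_s: dict | None = None  # realized dwell times per state


def dexp_kernel(fs: float, rise_tau_ms: float, decay_tau_ms: float) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials kernel sampled at ``fs``, unit peak.

    Returns the kernel and the index of its peak sample. The kernel is
    truncated where the decay falls below 1e-4 of the peak.
    """
    tr, td = rise_tau_ms / 1000.0, decay_tau_ms / 1000.0
    if not (td > tr > 0):
        raise ValueError("kinetics require decay_tau > rise_tau > 0")
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    t_end = t_peak + td * np.log(1e4)
    t = np.arange(0, t_end, 1.0 / fs)
    k = np.exp(-t / td) - np.exp(-t / tr)
    k /= k.max()
    return k, int(np.argmax(k))


def _kernel_rise5_offset(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Time (s) from kernel onset to its 5% rise point (continuous form)."""
    tr, td = rise_tau_ms / 1000.0, decay_tau_ms / 1000.0
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)

    def f(t: float) -> float:
        return (np.exp(-t / td) - np.exp(-t / tr)) - 0.05 * peak

    return float(optimize.brentq(f, 1e-12, t_peak))


def _kernel_peak_offset(rise_tau_ms: float, decay_tau_ms: float) -> float:
    tr, td = rise_tau_ms / 1000.0, decay_tau_ms / 1000.0
    return tr * td / (td - tr) * np.log(td / tr)


def simulate_evoked_sweeps(
    model: ChannelModel,
    n_sweeps: int,
    fs: float = 10_000.0,
    pulse_onset: float = 0.05,
    sweep_len: float = 0.3,
    seed: int = 0,
) -> tuple[SweepSet, GroundTruth]:
    """Simulate an ensemble of opto-evoked PSC sweeps.

    Each sweep is ``unitary_current`` times a per-sample binomial count of
    open channels (size ``n_channels``, probability following the
    two-exponential time course, scaled per sweep by a lognormal factor of
    CV ``peak_cv``), signed by polarity, plus Gaussian baseline noise.
    Binomial draws are independent across samples, which realizes the
    variance–mean parabola the downstream estimator assumes.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = rng_for(seed, "evoked_sweeps")
    n_samples = int(round(sweep_len * fs))
    onset_idx = int(round(pulse_onset * fs))
    if not (0 <= onset_idx < n_samples):
        raise ValueError("pulse_onset must lie inside the sweep")

    k, _ = dexp_kernel(fs, model.rise_tau, model.decay_tau)
    g = np.zeros(n_samples)
    seg = min(len(k), n_samples - onset_idx)
    g[onset_idx : onset_idx + seg] = k[:seg]

    if model.peak_cv > 0:
        sig = np.sqrt(np.log(1 + model.peak_cv**2))
        scales = rng.lognormal(-0.5 * sig**2, sig, n_sweeps)
    else:
        scales = np.ones(n_sweeps)
    p = np.clip(model.open_prob_peak * scales[:, None] * g[None, :], 0.0, 1.0)
    counts = rng.binomial(model.n_channels, p)
    noise = rng.normal(0.0, model.baseline_noise_sd, (n_sweeps, n_samples))
    sign = polarity_sign(model.polarity)
    sweeps = sign * (model.unitary_current * counts) + noise

    sweepset = SweepSet(
        sweeps=sweeps,
        fs=fs,
        pulse_onsets=np.array([onset_idx]),
        pulse_width_ms=10.0,
        polarity=model.polarity,
    )
    return sweepset, GroundTruth(open_counts=counts, peak_scales=scales)


def simulate_spontaneous_events(model: SpontaneousModel, duration: float, seed: int = 0) -> EventList:
    """Homogeneous-Poisson spontaneous events with lognormal amplitudes.

    Event ``time`` is the (future) kernel peak time and ``rise5_time`` the
    kernel's 5% rise point, so detector output is directly comparable.
    Amplitudes are magnitudes (pA); polarity is applied at render time.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng_for(seed, "spontaneous_events")
    n = rng.poisson(model.rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, n))
    if model.amplitude_cv > 0:
        sig = np.sqrt(np.log(1 + model.amplitude_cv**2))
        amps = rng.lognormal(np.log(model.amplitude_mean) - 0.5 * sig**2, sig, n)
    else:
        amps = np.full(n, model.amplitude_mean)
    t_peak = _kernel_peak_offset(model.rise_tau, model.decay_tau)
    t_r5 = _kernel_rise5_offset(model.rise_tau, model.decay_tau)
    return EventList(np.zeros(n, dtype=int), onsets + t_peak, amps, onsets + t_r5)


def render_trace(
    events: EventList,
    kinetics: tuple[float, float],
    noise_sd: float,
    fs: float,
    duration: float,
    polarity: Literal["inward", "outward"] = "inward",
    seed: int = 0,
) -> np.ndarray:
    """Render an event list into a current trace.

    The trace is a sum of unit-peak difference-of-exponentials kernels
    placed so each kernel's peak lands at the event's ``time``, scaled by
    the event amplitude magnitudes, signed by polarity, plus Gaussian
    noise. Events outside ``[0, duration)`` are rejected.
    """
    if fs < 1000:
        raise ValueError("fs must be >= 1 kHz to resolve PSC kinetics")
    rise_tau, decay_tau = kinetics
    n = int(round(duration * fs))
    if len(events) and (np.any(events.time < 0) or np.any(events.time >= duration)):
        raise ValueError("event times must lie in [0, duration)")
    k, kp = dexp_kernel(fs, rise_tau, decay_tau)
    sign = polarity_sign(polarity)
    x = np.zeros(n)
    for t, a in zip(events.time, np.abs(events.amplitude)):
        start = int(round(t * fs)) - kp
        k0, k1 = max(0, -start), min(len(k), n - start)
        if k1 > k0:
            x[start + k0 : start + k1] += a * k[k0:k1]
    x *= sign
    if noise_sd > 0:
        x = x + rng_for(seed, "render_noise").normal(0.0, noise_sd, n)
    return x


def _simulate_state_epochs(config: SleepSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov state sequence at epoch resolution (codes 0/1/2)."""
    n_epochs = int(round(config.duration_s / config.epoch_length))
    P = config.transition_matrix * (1 - np.eye(3))
    P = P / P.sum(axis=1, keepdims=True)
    out = np.empty(n_epochs, dtype=np.int8)
    state = 0  # sessions start awake
    pos = 0
    while pos < n_epochs:
        dwell = rng.exponential(config.state_dwell_means[STATES[state]])
        n = max(1, int(round(dwell / config.epoch_length)))
        out[pos : pos + n] = state
        pos += n
        state = rng.choice(3, p=P[state])
    return out


def generate_stim_schedule(
    states: np.ndarray,
    config: SleepSimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Closed-loop stimulation schedule from an epoch-resolution hypnogram.

    A train may start at an epoch boundary only when the preceding
    ``min_state_s`` were one uninterrupted NREM or REM state; consecutive
    onsets are at least ``refractory`` apart, conditions (sham interleaved
    with the stimulation frequencies) are drawn uniformly at random, and
    the total count never exceeds ``max_stims``.

    Returns a DataFrame with columns ``onset_s, condition, pulse_width_ms,
    train_s``.
    """
    states = np.asarray(states)
    if states.dtype.kind in "UO":
        states = np.array([STATES.index(s) for s in states], dtype=np.int8)
    rng = rng_for(config.seed if seed is None else seed, "stim_schedule")
    ep = config.epoch_length
    need = int(np.ceil(config.min_state_s / ep))
    duration = len(states) * ep

    onsets: list[float] = []
    conditions: list[str] = []
    last = -np.inf
    for e in range(need, len(states)):
        t = e * ep
        if t + config.train_duration > duration:
            break
        if t - last < config.refractory:
            continue
        window = states[e - need : e]
        if window[0] in (1, 2) and np.all(window == window[0]):
            onsets.append(t)
            conditions.append(str(rng.choice(config.stim_conditions)))
            last = t
            if len(onsets) >= config.max_stims:
                break

    return pd.DataFrame(
        {
            "onset_s": onsets,
            "condition": conditions,
            "pulse_width_ms": config.pulse_width_ms,
            "train_s": config.train_duration,
        }
    )


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    b, a = signal.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    x = signal.filtfilt(b, a, rng.standard_normal(n))
    return x / x.std()


def simulate_sleep_recording(config: SleepSimConfig) -> tuple[Recording, GroundTruth]:
    """Simulate a closed-loop optogenetic sleep session.

    The base hypnogram is semi-Markov with exponential dwells (minimum one
    epoch). The stimulation schedule is produced by
    :func:`generate_stim_schedule` on the base hypnogram; each scheduled
    trial whose preceding ``min_state_s`` remain a clean NREM/REM period in
    the arousal-modified sequence flips to Wake with probability
    ``arousal_prob[condition]`` after an exponential latency, for at least
    ``wake_bout_min_s``. ``arousal_prob`` is the total per-trial arousal
    probability: by default (``hold_state_during_train``) a trial drawn as
    "no arousal" keeps its sleep state through the train window, so
    spontaneous transitions do not add to the nominal rate; with the hold
    disabled the base dynamics run untouched and stimulation only ever
    adds wake bouts. EEG is a per-state mixture of band-limited noise
    (delta 0.5-4, theta 5-9, gamma 30-80 Hz) plus a broadband floor; EMG is
    Gaussian noise with a state-dependent envelope.
    """
    rng_states = rng_for(config.seed, "sleep_states")
    rng_arousal = rng_for(config.seed, "arousal")
    rng_eeg = rng_for(config.seed, "eeg_noise")
    rng_emg = rng_for(config.seed, "emg_noise")

    base_epochs = _simulate_state_epochs(config, rng_states)
    schedule = generate_stim_schedule(base_epochs, config, config.seed)

    spe = int(round(config.epoch_length * config.fs))
    state_samples = np.repeat(base_epochs, spe)
    n = len(state_samples)

    need = int(round(config.min_state_s * config.fs))
    rows = []
    for _, stim in schedule.iterrows():
        onset = int(round(stim.onset_s * config.fs))
        pre = state_samples[onset - need : onset]
        clean = len(pre) == need and pre[0] in (1, 2) and np.all(pre == pre[0])
        pre_state = STATES[int(state_samples[onset - 1])] if onset > 0 else "Wake"
        if not clean:
            rows.append((stim.onset_s, stim.condition, pre_state, False, np.nan, False))
            continue
        p = config.arousal_prob.get(stim.condition, 0.0)
        aroused = bool(rng_arousal.random() < p)
        latency = np.nan
        train_end = min(n, onset + int(round(config.train_duration * config.fs)))
        pre_code = int(pre[-1])
        if aroused:
            hi = max(0.5, config.train_duration - 3.5)
            latency = float(np.clip(rng_arousal.exponential(config.arousal_latency_mean), 0.5, hi))
            wake_dur = max(config.wake_bout_min_s, rng_arousal.exponential(config.state_dwell_means["Wake"]))
            a0 = onset + int(round(latency * config.fs))
            a1 = min(n, a0 + int(round(wake_dur * config.fs)))
            if config.hold_state_during_train:
                state_samples[onset:a0] = pre_code  # asleep until the evoked arousal
            state_samples[a0:a1] = 0
        elif config.hold_state_during_train:
            # arousal_prob is the total per-trial arousal probability, so a
            # "no arousal" draw holds the sleep state through the train
            state_samples[onset:train_end] = pre_code
        rows.append((stim.onset_s, stim.condition, pre_state, aroused, latency, True))
    arousals = pd.DataFrame(
        rows, columns=["onset_s", "condition", "pre_state", "aroused", "latency_s", "valid_pre"]
    )

    # EEG: per-state weighted sum of band-limited components
    bands = {"delta": (0.5, 4.0), "theta": (5.0, 9.0), "gamma": (30.0, 80.0)}
    comps = {name: _band_noise(n, config.fs, lo, hi, rng_eeg) for name, (lo, hi) in bands.items()}
    weights = np.array([config.band_powers[s] for s in STATES])  # (3, 3) state x band
    eeg = np.zeros(n)
    for bi, name in enumerate(bands):
        eeg += weights[state_samples, bi] * comps[name]
    eeg += config.broadband_level * rng_eeg.standard_normal(n)
    eeg *= config.eeg_amp_uV / np.abs(weights).max()

    tone = np.array([config.emg_tone[s] for s in STATES])
    emg = config.emg_base_uV * tone[state_samples] * rng_emg.standard_normal(n)

    # per-epoch labels = majority state within each epoch
    n_epochs = n // spe
    reshaped = state_samples[: n_epochs * spe].reshape(n_epochs, spe)
    labels = np.array([STATES[np.bincount(row, minlength=3).argmax()] for row in reshaped])

    recording = Recording(
        eeg=eeg,
        emg=emg,
        fs=config.fs,
        stim_schedule=schedule,
        state_labels=labels,
        epoch_length=config.epoch_length,
    )
    truth = GroundTruth(
        state_epochs=labels.copy(),
        base_state_epochs=np.array([STATES[s] for s in base_epochs]),
        state_samples=state_samples,
        arousals=arousals,
    )
    return recording, truth
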