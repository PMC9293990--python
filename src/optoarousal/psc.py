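"""Postsynaptic-current event detection and optogenetic connectivity statistics.

This module holds the containers for voltage-clamp sweep ensembles and
detected synaptic events, an automatic threshold-plus-derivative event
detector, drug-epoch comparisons of spontaneous event trains, and the
photostimulation (CRACM) statistics: peristimulus event-probability
profiles in 50-ms bins, the connectivity criterion (evoked probability in
the first post-pulse bin exceeding baseline probability plus ``k`` standard
errors, ``k = 5`` by default), opto-evoked response latencies measured at
the 5% rise point of the first event after each pulse, and per-pulse
response amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "SweepSet",
    "EventList",
    "ProbabilityProfile",
    "ConnectivityResult",
    "EpochComparison",
    "DetectionParams",
    "detect_events",
    "epoch_stats",
    "compare_epochs",
    "peristimulus_probability",
    "classify_connectivity",
    "opsc_latency",
    "opsc_amplitudes",
]

Polarity = Literal["inward", "outward"]


def polarity_sign(polarity: str) -> float:
    if polarity == "inward":
        return -1.0
    if polarity == "outward":
        return 1.0
    raise ValueError(f"polarity must be 'inward' or 'outward', got {polarity!r}")


@dataclass
class SweepSet:
    """Aligned voltage-clamp current sweeps with light-pulse onsets.

    Parameters
    ----------
    sweeps
        ``(n_sweeps, n_samples)`` current in pA, signed (inward negative).
    fs
        Sampling rate in Hz.
    pulse_onsets
        Light-pulse onset sample indices, shared by every sweep (sweeps are
        acquired time-locked to the stimulus).
    pulse_width_ms
        Light pulse duration.
    polarity
        Expected response polarity; ``inward`` currents are negative.
    holding_mV
        Holding potential (metadata only).
    labels
        Optional per-sweep condition tags (e.g. control/drug/wash).
    """

    sweeps: np.ndarray
    fs: float
    pulse_onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pulse_width_ms: float = 10.0
    polarity: Polarity = "inward"
    holding_mV: float | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=int).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        polarity_sign(self.polarity)
        if self.sweeps.size and (
            (self.pulse_onsets < 0).any() or (self.pulse_onsets >= self.sweeps.shape[1]).any()
        ):
            raise ValueError("pulse_onsets must lie within sweep bounds")
        if self.labels is not None and len(self.labels) != self.sweeps.shape[0]:
            raise ValueError("labels must have one entry per sweep")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1] if self.sweeps.ndim == 2 else 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def rectified(self) -> np.ndarray:
        """Polarity-rectified magnitudes (responses positive-going)."""
        return polarity_sign(self.polarity) * self.sweeps

    def subset(self, idx: np.ndarray | Sequence[int]) -> "SweepSet":
        idx = np.asarray(idx)
        labels = None if self.labels is None else [self.labels[i] for i in np.atleast_1d(idx)]
        return replace(self, sweeps=self.sweeps[idx], labels=labels)


@dataclass
class EventList:
    """Detected or simulated synaptic events.

    ``time`` is the peak time, ``rise5_time`` the 5% rise point, both in
    seconds on the sweep's time base. ``amplitude`` is the signed amplitude
    in pA (negative for inward events).
    """

    sweep_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    time: np.ndarray = field(default_factory=lambda: np.array([]))
    amplitude: np.ndarray = field(default_factory=lambda: np.array([]))
    rise5_time: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.sweep_index = np.asarray(self.sweep_index, dtype=int).ravel()
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.amplitude = np.asarray(self.amplitude, dtype=float).ravel()
        self.rise5_time = np.asarray(self.rise5_time, dtype=float).ravel()
        n = len(self.time)
        if not (len(self.sweep_index) == len(self.amplitude) == len(self.rise5_time) == n):
            raise ValueError("event fields must have equal length")
        if np.any(self.rise5_time > self.time + 1e-12):
            raise ValueError("rise5_time must not exceed peak time")

    def __len__(self) -> int:
        return len(self.time)

    def in_window(self, t0: float, t1: float) -> "EventList":
        """Events with peak time in the half-open window ``[t0, t1)``."""
        sel = (self.time >= t0) & (self.time < t1)
        return EventList(self.sweep_index[sel], self.time[sel], self.amplitude[sel], self.rise5_time[sel])

    def for_sweep(self, i: int) -> "EventList":
        sel = self.sweep_index == i
        return EventList(self.sweep_index[sel], self.time[sel], self.amplitude[sel], self.rise5_time[sel])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sweep": self.sweep_index,
                "time_s": self.time,
                "amplitude_pA": self.amplitude,
                "rise5_s": self.rise5_time,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        return cls(
            df["sweep"].to_numpy(int),
            df["time_s"].to_numpy(float),
            df["amplitude_pA"].to_numpy(float),
            df["rise5_s"].to_numpy(float),
        )

    @classmethod
    def concatenate(cls, parts: Sequence["EventList"]) -> "EventList":
        if not parts:
            return cls()
        return cls(
            np.concatenate([p.sweep_index for p in parts]),
            np.concatenate([p.time for p in parts]),
            np.concatenate([p.amplitude for p in parts]),
            np.concatenate([p.rise5_time for p in parts]),
        )


@dataclass
class ProbabilityProfile:
    """Peristimulus event probability in fixed-width bins around pulse onset."""

    bin_edges: np.ndarray  # seconds relative to pulse onset, len = n_bins + 1
    probability: np.ndarray  # fraction of pulses with >= 1 event per bin
    n_pulses: int
    bin_s: float = 0.05

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def first_post_bin(self) -> float:
        """Probability in the first bin at/after pulse onset."""
        k = int(np.searchsorted(self.bin_edges, -1e-12))
        return float(self.probability[k])

    def baseline_bins(self) -> np.ndarray:
        """Probabilities of all fully pre-onset bins."""
        pre = self.bin_edges[1:] <= 1e-12
        return self.probability[pre]


@dataclass
class ConnectivityResult:
    """Outcome of the evoked-vs-baseline probability criterion."""

    evoked_probability: float
    baseline_probability: float
    baseline_sem: float
    k_sigma: float
    threshold: float
    is_connected: bool
    mean_latency_ms: float | None = None
    mean_amplitude_pA: float | None = None

    def to_dict(self) -> dict:
        return {
            "evoked_probability": self.evoked_probability,
            "baseline_probability": self.baseline_probability,
            "baseline_sem": self.baseline_sem,
            "k_sigma": self.k_sigma,
            "threshold": self.threshold,
            "is_connected": bool(self.is_connected),
            "mean_latency_ms": self.mean_latency_ms,
            "mean_amplitude_pA": self.mean_amplitude_pA,
        }


@dataclass
class EpochComparison:
    """Control/drug/wash comparison of a spontaneous event train."""

    frequency_hz: dict
    mean_amplitude_pA: dict
    pct_change_frequency: float
    pct_change_amplitude: float
    ks_statistic: float | None
    ks_pvalue: float | None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "mean_amplitude_pA": self.mean_amplitude_pA,
            "pct_change_frequency": self.pct_change_frequency,
            "pct_change_amplitude": self.pct_change_amplitude,
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "flags": self.flags,
        }


@dataclass
class DetectionParams:
    """Tunables of the threshold-plus-derivative event detector."""

    amplitude_threshold_pA: float = 15.0
    derivative_threshold_pA_ms: float = 10.0
    refractory_ms: float = 5.0
    smooth_ms: float = 0.5  # pre-smoothing for peak finding / rise timing
    baseline_ms: float = 5.0  # local baseline window length
    baseline_gap_ms: float = 2.0  # gap between baseline window and peak

    def __post_init__(self) -> None:
        if self.amplitude_threshold_pA <= 0 or self.derivative_threshold_pA_ms <= 0:
            raise ValueError("thresholds must be positive")


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float, copy=True)
    pad = np.pad(x, (w // 2, w - w // 2 - 1), mode="reflect")
    return np.convolve(pad, np.ones(w) / w, mode="valid")


def detect_events(
    trace: np.ndarray,
    fs: float,
    polarity: Polarity = "inward",
    params: DetectionParams | None = None,
    sweep_index: int = 0,
) -> EventList:
    """Detect synaptic events on a single current trace.

    Candidate peaks are found on a lightly smoothed, polarity-rectified
    copy; each candidate is accepted when its amplitude over the local
    baseline (median of the ``baseline_ms`` preceding the onset) exceeds
    the amplitude threshold and the rising-phase slope exceeds the
    derivative threshold. Events closer than the refractory period are
    merged (tallest wins, earliest sample on ties).
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    if np.isnan(trace).any():
        raise ValueError("trace contains NaNs")
    if fs < 1000:
        warnings.warn("sampling rate below 1 kHz may not resolve PSC kinetics", stacklevel=2)

    sign = polarity_sign(polarity)
    x = sign * trace
    w = max(1, int(round(params.smooth_ms * fs / 1000)))
    xs = _moving_average(x, w)
    refr = max(1, int(round(params.refractory_ms * fs / 1000)))
    nb = max(1, int(round(params.baseline_ms * fs / 1000)))

    global_base = float(np.median(xs))
    peaks, _ = signal.find_peaks(xs, height=global_base + params.amplitude_threshold_pA, distance=refr)

    d = np.gradient(xs) * fs / 1000.0  # pA/ms
    gap = max(1, int(round(params.baseline_gap_ms * fs / 1000)))
    times, amps, rises = [], [], []
    for p in peaks:
        # local baseline: median of baseline_ms ending baseline_gap_ms before the peak
        b1 = max(1, p - gap)
        b0 = max(0, b1 - nb)
        base = float(np.median(x[b0:b1]))
        # raw peak within a half-smoothing-window of the smoothed peak
        lo, hi = max(0, p - w), min(len(x), p + w + 1)
        praw = lo + int(np.argmax(x[lo:hi]))
        amp = x[praw] - base
        if amp < params.amplitude_threshold_pA:
            continue
        if np.max(d[b1 : p + 1]) < params.derivative_threshold_pA_ms:
            continue
        # 5% rise point: first sample after the last sub-5% sample before the peak
        seg = xs[b0 : praw + 1]
        below = np.nonzero(seg < base + 0.05 * amp)[0]
        r5 = b0 + (int(below[-1]) + 1 if below.size else 0)
        r5 = min(r5, praw)
        times.append(praw / fs)
        amps.append(sign * amp)
        rises.append(r5 / fs)

    order = np.argsort(times) if times else []
    return EventList(
        np.full(len(times), sweep_index, dtype=int)[order] if len(times) else [],
        np.asarray(times)[order] if len(times) else [],
        np.asarray(amps)[order] if len(times) else [],
        np.asarray(rises)[order] if len(times) else [],
    )


def detect_events_sweepset(sweeps: SweepSet, params: DetectionParams | None = None) -> EventList:
    """Run :func:`detect_events` over every sweep of a :class:`SweepSet`."""
    parts = [
        detect_events(sweeps.sweeps[i], sweeps.fs, sweeps.polarity, params, sweep_index=i)
        for i in range(sweeps.n_sweeps)
    ]
    return EventList.concatenate(parts)


def epoch_stats(events: EventList, window: tuple[float, float]) -> tuple[float, float]:
    """Event frequency (Hz) and mean absolute amplitude (pA) in ``[t0, t1)``.

    An empty window yields frequency 0 and amplitude ``nan``.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed start")
    ev = events.in_window(t0, t1)
    freq = len(ev) / (t1 - t0)
    amp = float(np.mean(np.abs(ev.amplitude))) if len(ev) else float("nan")
    return freq, amp


def _intervals(events: EventList, window: tuple[float, float]) -> np.ndarray:
    ev = events.in_window(*window)
    return np.diff(np.sort(ev.time))


def compare_epochs(
    events: EventList,
    control: tuple[float, float],
    drug: tuple[float, float],
    wash: tuple[float, float] | None = None,
) -> EpochComparison:
    """Compare spontaneous-event statistics between drug-application epochs.

    Windows must be disjoint. Percent changes are
    ``100 * (drug - control) / control``; inter-event-interval distributions
    of the control and drug epochs are compared with a two-sample
    Kolmogorov–Smirnov test (skipped, with a flag, when either epoch has
    fewer than two intervals).
    """
    wins = {"control": control, "drug": drug}
    if wash is not None:
        wins["wash"] = wash
    spans = sorted(wins.values())
    for a, b in zip(spans, spans[1:]):
        if b[0] < a[1]:
            raise ValueError("epoch windows must be disjoint")

    freq, amp = {}, {}
    for name, win in wins.items():
        f, a = epoch_stats(events, win)
        freq[name], amp[name] = f, a

    flags: list[str] = []
    pcf = 100.0 * (freq["drug"] - freq["control"]) / freq["control"] if freq["control"] > 0 else float("nan")
    if freq["control"] == 0:
        flags.append("control epoch empty; percent change undefined")
    pca = 100.0 * (amp["drug"] - amp["control"]) / amp["control"] if np.isfinite(amp.get("control", np.nan)) else float("nan")

    iic, iid = _intervals(events, control), _intervals(events, drug)
    if len(iic) >= 2 and len(iid) >= 2:
        ks = stats.ks_2samp(iic, iid)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat = ks_p = None
        flags.append("too few events for K-S test")

    return EpochComparison(freq, amp, pcf, pca, ks_stat, ks_p, flags)


def peristimulus_probability(
    events: EventList,
    pulse_onsets: Sequence[tuple[int, float]],
    window: tuple[float, float] = (-0.5, 0.5),
    bin_s: float = 0.05,
) -> ProbabilityProfile:
    """Fraction of pulses followed (or preceded) by at least one event per bin.

    ``pulse_onsets`` is a sequence of ``(sweep_index, onset_seconds)``
    pairs. Bin edges are aligned to the pulse onset; the window bounds must
    be integer multiples of the bin width, otherwise the request is
    rejected.
    """
    if len(pulse_onsets) < 1:
        raise ValueError("at least one pulse required")
    lo, hi = window
    n_lo, n_hi = lo / bin_s, hi / bin_s
    if abs(n_lo - round(n_lo)) > 1e-9 or abs(n_hi - round(n_hi)) > 1e-9:
        raise ValueError("window bounds must be integer multiples of the bin width (bins aligned to pulse onset)")
    edges = np.arange(round(n_lo), round(n_hi) + 1) * bin_s
    n_bins = len(edges) - 1

    hits = np.zeros(n_bins, dtype=int)
    for sweep, onset in pulse_onsets:
        ev = events.for_sweep(int(sweep))
        rel = ev.time - onset
        idx = np.floor(rel / bin_s - round(n_lo)).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        hits[np.unique(idx)] += 1

    return ProbabilityProfile(edges, hits / len(pulse_onsets), len(pulse_onsets), bin_s)


def classify_connectivity(
    profile: ProbabilityProfile,
    baseline_probability: float | None = None,
    baseline_sem: float | None = None,
    k_sigma: float = 5.0,
) -> ConnectivityResult:
    """Apply the evoked-probability connectivity criterion.

    A cell is classified as connected when the event probability in the
    first 50-ms bin after the light pulse exceeds
    ``baseline_probability + k_sigma * baseline_sem``. When no external
    baseline is supplied (the default), the baseline probability and its
    SEM are computed across the profile's pre-pulse bins; externally
    supplied values allow using across-cell population baselines instead.
    """
    if (baseline_probability is None) != (baseline_sem is None):
        raise ValueError("supply both baseline_probability and baseline_sem, or neither")
    if baseline_probability is None:
        base_bins = profile.baseline_bins()
        if base_bins.size == 0:
            raise ValueError("profile has no pre-pulse bins and no external baseline was given")
        baseline_probability = float(np.mean(base_bins))
        baseline_sem = float(np.std(base_bins, ddof=1) / np.sqrt(base_bins.size)) if base_bins.size > 1 else 0.0
    if not (0 <= baseline_probability <= 1):
        raise ValueError("baseline probability must lie in [0, 1]")

    evoked = profile.first_post_bin
    threshold = baseline_probability + k_sigma * baseline_sem
    return ConnectivityResult(
        evoked_probability=evoked,
        baseline_probability=baseline_probability,
        baseline_sem=baseline_sem,
        k_sigma=k_sigma,
        threshold=threshold,
        is_connected=bool(evoked > threshold),
    )


def opsc_latency(
    sweeps: SweepSet,
    events: EventList,
    response_window_s: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Opto-evoked response latency per pulse, and the mean over responders.

    Latency is the time from the light-pulse onset to the 5% rise point of
    the first event after the pulse. Pulses with no event inside the
    response window are excluded (``nan`` in the per-pulse vector); the
    mean over an empty responder set is ``nan``.
    """
    lat = np.full((sweeps.n_sweeps, len(sweeps.pulse_onsets)), np.nan)
    for i in range(sweeps.n_sweeps):
        ev = events.for_sweep(i)
        for k, onset_idx in enumerate(sweeps.pulse_onsets):
            t_on = onset_idx / sweeps.fs
            sel = (ev.rise5_time >= t_on) & (ev.rise5_time < t_on + response_window_s)
            if sel.any():
                lat[i, k] = 1000.0 * (np.min(ev.rise5_time[sel]) - t_on)
    flat = lat.ravel()
    mean = float(np.nanmean(flat)) if np.isfinite(flat).any() else float("nan")
    return flat, mean


def opsc_amplitudes(
    sweeps: SweepSet,
    response_window_s: float = 0.05,
    baseline_ms: float = 5.0,
    smooth_ms: float = 2.0,
) -> tuple[np.ndarray, float, float]:
    """Per-pulse peak response amplitude (pA magnitude), with mean and SEM.

    For each sweep and pulse, the local baseline is the median of the
    ``baseline_ms`` preceding the pulse onset on the polarity-rectified
    trace; the amplitude is the rectified peak within the response window
    minus that baseline. Peaks are read on a lightly smoothed copy
    (``smooth_ms`` moving average) so wide-band noise does not bias the
    windowed maximum upward.
    """
    x = sweeps.rectified()
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms * sweeps.fs / 1000)))
        xs = np.apply_along_axis(_moving_average, 1, x, w)
    else:
        xs = x
    nb = max(1, int(round(baseline_ms * sweeps.fs / 1000)))
    nw = int(round(response_window_s * sweeps.fs))
    amps = []
    for i in range(sweeps.n_sweeps):
        for onset in sweeps.pulse_onsets:
            base = float(np.median(x[i, max(0, onset - nb) : onset])) if onset > 0 else 0.0
            # peak located on the smoothed copy, amplitude read from the raw trace
            pk = onset + int(np.argmax(xs[i, onset : onset + nw]))
            amps.append(float(x[i, pk]) - base)
    amps_arr = np.asarray(amps)
    mean = float(amps_arr.mean()) if amps_arr.size else float("nan")
    sem = float(amps_arr.std(ddof=1) / np.sqrt(amps_arr.size)) if amps_arr.size > 1 else float("nan")
    return amps_arr, mean, sem
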