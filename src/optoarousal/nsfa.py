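"""Peak-scaled non-stationary fluctuation analysis (NSFA).

Estimates the unitary channel current ``i`` and the number of activated
channels ``N`` from an ensemble of opto-evoked postsynaptic currents by
least-squares fitting the peak-scaled variance against the mean current:

    sigma^2(I) = i * I - I^2 / N + b

where ``b`` is the baseline variance. The procedure: optionally low-pass
filter the sweeps, exclude sweeps contaminated by spontaneous events
(requiring at least 20 clean sweeps), align response peaks, scale the mean
waveform to each sweep's peak amplitude and average the squared
differences, sample that variance time course in 30 bins of equal current
decrement from peak to baseline, and fit the parabola above.

Per-sweep peak amplitudes used for alignment and scaling are measured on a
lightly smoothed copy of each sweep (the variance itself is computed on
the unsmoothed data): a single-sample peak estimate carries the full
baseline-plus-channel fluctuation of that sample, and because that error
enters every scaled sample of the sweep it otherwise inflates the
quadratic term of the fit and biases N upward by roughly a factor of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .psc import EventList, SweepSet

__all__ = [
    "NsfaConfig",
    "NsfaEstimate",
    "lowpass_sweeps",
    "select_sweeps",
    "align_peaks",
    "peak_scaled_variance",
    "bin_by_current",
    "fit_variance_mean",
    "nsfa_pipeline",
]


@dataclass
class NsfaConfig:
    """Tunables of the NSFA pipeline.

    ``lowpass_hz`` applies a zero-phase Butterworth low-pass before
    analysis (set ``None`` to skip — appropriate when the recording noise
    is white up to Nyquist, as filtering then removes fluctuation signal
    along with noise). ``peak_smooth_ms`` is the moving-average width used
    only for measuring per-sweep peak amplitudes.
    """

    lowpass_hz: float | None = 1000.0
    lowpass_order: int = 4
    min_sweeps: int = 20
    n_bins: int = 30
    min_bins: int = 5
    peak_smooth_ms: float = 2.0
    peak_noise_sigma: float = 5.0  # exclude peakless sweeps below this x baseline SD
    max_align_shift_ms: float = 5.0
    decay_end_sigma: float = 2.0  # decay segment ends where mean < this x baseline SD
    fix_b: float | None = None


@dataclass
class NsfaEstimate:
    """Fitted (i, N, b) with binned data and diagnostics.

    Currents are analyzed as magnitudes, so a valid estimate has
    ``i > 0`` and ``N > 0``; the response sign is carried in ``polarity``.
    """

    unitary_current_i: float = np.nan  # pA
    n_channels_N: float = np.nan
    baseline_variance_b: float = np.nan  # pA^2
    binned_current_I: np.ndarray = field(default_factory=lambda: np.array([]))
    binned_variance: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_sweeps_used: int = 0
    n_bins_dropped: int = 0
    fit_residual_rms: float = np.nan  # pA^2
    valid: bool = False
    flags: list[str] = field(default_factory=list)
    polarity: str = "inward"
    raw_coefficients: tuple | None = None
    mean_waveform: np.ndarray | None = None
    variance_trace: np.ndarray | None = None

    def predicted_variance(self, current: np.ndarray) -> np.ndarray:
        """Fitted parabola evaluated at current magnitudes."""
        current = np.asarray(current, dtype=float)
        return (
            self.unitary_current_i * current
            - current**2 / self.n_channels_N
            + self.baseline_variance_b
        )

    def to_dict(self) -> dict:
        return {
            "unitary_current_i_pA": float(self.unitary_current_i),
            "n_channels_N": float(self.n_channels_N),
            "baseline_variance_b_pA2": float(self.baseline_variance_b),
            "binned_current_I_pA": list(map(float, self.binned_current_I)),
            "binned_variance_pA2": list(map(float, self.binned_variance)),
            "bin_counts": list(map(int, self.bin_counts)),
            "n_sweeps_used": self.n_sweeps_used,
            "n_bins_dropped": self.n_bins_dropped,
            "fit_residual_rms_pA2": float(self.fit_residual_rms),
            "valid": bool(self.valid),
            "flags": self.flags,
            "polarity": self.polarity,
        }


def lowpass_sweeps(sweeps: SweepSet, cutoff: float, order: int = 4) -> SweepSet:
    """Zero-phase Butterworth low-pass applied identically to every sweep."""
    if cutoff >= sweeps.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({sweeps.fs / 2} Hz)")
    b, a = signal.butter(order, cutoff / (sweeps.fs / 2), btype="low")
    filtered = signal.filtfilt(b, a, sweeps.sweeps, axis=1)
    out = sweeps.subset(np.arange(sweeps.n_sweeps))
    out.sweeps = filtered
    return out


def select_sweeps(
    sweeps: SweepSet,
    events: EventList | None,
    min_sweeps: int = 20,
    window: tuple[float, float] | None = None,
) -> tuple[SweepSet, bool, list[int]]:
    """Drop sweeps contaminated by spontaneous events in the analysis window.

    ``events`` are spontaneous events detected on the same sweeps; a sweep
    with any event inside ``window`` (default: pulse onset to sweep end)
    is excluded. Returns the retained subset, a validity flag (False when
    fewer than ``min_sweeps`` survive), and the excluded sweep indices.
    """
    if events is None or len(events) == 0:
        return sweeps, sweeps.n_sweeps >= min_sweeps, []
    if window is None:
        onset = sweeps.pulse_onsets[0] / sweeps.fs if len(sweeps.pulse_onsets) else 0.0
        window = (onset, sweeps.n_samples / sweeps.fs)
    contaminated = sorted(
        set(int(s) for s, t in zip(events.sweep_index, events.time) if window[0] <= t < window[1])
    )
    keep = [i for i in range(sweeps.n_sweeps) if i not in contaminated]
    subset = sweeps.subset(np.array(keep, dtype=int))
    return subset, len(keep) >= min_sweeps, contaminated


def _smooth(x: np.ndarray, fs: float, ms: float) -> np.ndarray:
    w = max(1, int(round(ms * fs / 1000)))
    return ndimage.uniform_filter1d(x, size=w, axis=-1, mode="reflect")


def align_peaks(
    sweeps: SweepSet,
    peak_smooth_ms: float = 2.0,
    peak_noise_sigma: float = 5.0,
    max_shift_ms: float = 5.0,
) -> tuple[SweepSet, np.ndarray, list[int]]:
    """Align response peaks across sweeps and compute the mean waveform.

    Each polarity-rectified sweep is circularly shifted by the lag (within
    ``max_shift_ms``) that maximizes its cross-correlation with the
    provisional ensemble mean — aligning the whole response rather than a
    single noisy maximum, which would couple each sweep's largest noise
    excursion to the alignment point. Sweeps whose smoothed peak fails the
    noise criterion (``peak_noise_sigma`` x pre-pulse SD above baseline)
    are excluded. Returns the aligned set, the rectified mean waveform,
    and the excluded sweep indices.
    """
    if sweeps.n_sweeps < 1:
        raise ValueError("empty sweep set")
    onset = int(sweeps.pulse_onsets[0]) if len(sweeps.pulse_onsets) else 0
    x = sweeps.rectified()
    xs = _smooth(x, sweeps.fs, peak_smooth_ms)

    base_mean = xs[:, :onset].mean(axis=1) if onset > 0 else np.zeros(sweeps.n_sweeps)
    base_sd = xs[:, :onset].std(axis=1) if onset > 0 else np.zeros(sweeps.n_sweeps)
    peak_amp = xs[:, onset:].max(axis=1) - base_mean

    ok = peak_amp > peak_noise_sigma * base_sd
    excluded = [int(i) for i in np.nonzero(~ok)[0]]
    kept = np.nonzero(ok)[0]
    if kept.size == 0:
        raise ValueError("no sweep has a detectable response peak")

    template = xs[kept].mean(axis=0)
    max_shift = max(1, int(round(max_shift_ms * sweeps.fs / 1000)))
    n = sweeps.n_samples
    aligned = np.empty((kept.size, n))
    for row, i in enumerate(kept):
        corr = signal.correlate(template, xs[i], mode="full")
        lags = np.arange(-(n - 1), n)
        window = np.abs(lags) <= max_shift
        shift = int(lags[window][np.argmax(corr[window])])
        aligned[row] = np.roll(x[i], shift)
    out = sweeps.subset(kept)
    out.sweeps = aligned  # rectified magnitudes from here on
    out.polarity = "outward"
    mean_waveform = aligned.mean(axis=0)
    return out, mean_waveform, excluded


def peak_scaled_variance(
    aligned: SweepSet,
    mean_waveform: np.ndarray,
    peak_smooth_ms: float = 2.0,
    decay_end_sigma: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Peak-scaled ensemble variance over the decay segment.

    The mean waveform is scaled to each sweep's peak amplitude (measured
    on a smoothed copy; see module docstring) and the squared differences
    are averaged across sweeps (divisor ``n - 1``). Returns the mean
    current ``I(t)`` and variance ``sigma^2(t)`` restricted to the decay
    segment — from the peak to the first sample where the mean returns to
    within ``decay_end_sigma`` pre-pulse SDs of baseline — plus details
    (peak index, segment bounds, per-sweep scale factors).
    """
    if aligned.n_sweeps < 2:
        raise ValueError("need at least two sweeps")
    x = aligned.sweeps  # rectified magnitudes after align_peaks
    m = np.asarray(mean_waveform, dtype=float)
    onset = int(aligned.pulse_onsets[0]) if len(aligned.pulse_onsets) else 0

    xs = _smooth(x, aligned.fs, peak_smooth_ms)
    ms = _smooth(m, aligned.fs, peak_smooth_ms)
    pk = onset + int(np.argmax(ms[onset:])) if onset < len(m) else int(np.argmax(ms))
    if ms[pk] == 0:
        raise ValueError("mean waveform peak is zero; cannot scale")
    scales = xs[:, pk] / ms[pk]

    resid = x - scales[:, None] * m[None, :]
    var = (resid**2).sum(axis=0) / (aligned.n_sweeps - 1)

    base_mean = m[:onset].mean() if onset > 0 else 0.0
    base_sd = m[:onset].std() if onset > 0 else 0.0
    below = np.nonzero(m[pk:] < base_mean + decay_end_sigma * base_sd)[0]
    end = pk + int(below[0]) if below.size else len(m)

    I_seg = m[pk:end] - base_mean
    var_seg = var[pk:end]
    details = {"peak_index": pk, "segment": (pk, end), "scales": scales, "baseline_mean": base_mean, "baseline_sd": base_sd}
    return I_seg, var_seg, details


def bin_by_current(
    current: np.ndarray,
    variance: np.ndarray,
    n_bins: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Bin the variance time course by current level.

    Bin edges are equally spaced in current magnitude between the peak and
    the baseline end of the decay; samples are assigned by current value
    (not time order) and averaged per bin. Empty bins are dropped.
    Returns ``(I_k, var_k, counts, n_dropped)``.
    """
    current = np.asarray(current, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if current.size != variance.size or current.size == 0:
        raise ValueError("current and variance must be equal-length and non-empty")
    if np.ptp(current) == 0:
        raise ValueError("current spans zero range; cannot bin")
    hi, lo = current.max(), current.min()
    edges = np.linspace(lo, hi, n_bins + 1)
    # assign by value; right-closed top bin so the peak sample is kept
    idx = np.clip(np.digitize(current, edges[1:-1]), 0, n_bins - 1)
    I_k, v_k, counts = [], [], []
    for k in range(n_bins):
        sel = idx == k
        if sel.any():
            I_k.append(current[sel].mean())
            v_k.append(variance[sel].mean())
            counts.append(int(sel.sum()))
    n_dropped = n_bins - len(I_k)
    return np.asarray(I_k), np.asarray(v_k), np.asarray(counts, dtype=int), n_dropped


def fit_variance_mean(
    binned_current: np.ndarray,
    binned_variance: np.ndarray,
    fix_b: float | None = None,
    min_bins: int = 5,
) -> NsfaEstimate:
    """Ordinary least squares of the variance-mean parabola.

    Fits ``sigma^2 = i*I - I^2/N + b`` on the basis ``{I, I^2, 1}`` (or
    ``{I, I^2}`` with ``b`` fixed). The estimate is valid only when
    ``i > 0`` and ``N > 0``; degenerate designs and negative curvature are
    flagged, with raw coefficients still reported.
    """
    I = np.asarray(binned_current, dtype=float)
    V = np.asarray(binned_variance, dtype=float)
    est = NsfaEstimate(binned_current_I=I, binned_variance=V, bin_counts=np.ones(len(I), dtype=int))
    need = min_bins if fix_b is None else max(3, min_bins - 2)
    if len(I) < need:
        est.flags.append(f"only {len(I)} bins; need >= {need}")
        return est
    if np.ptp(I) == 0:
        est.flags.append("constant current; singular design")
        return est

    if fix_b is None:
        A = np.column_stack([I, I**2, np.ones_like(I)])
    else:
        A = np.column_stack([I, I**2])
        V = V - fix_b
    coef, _, rank, _ = np.linalg.lstsq(A, V, rcond=None)
    if rank < A.shape[1]:
        est.flags.append("rank-deficient design")
        return est
    c1, c2 = float(coef[0]), float(coef[1])
    b = float(coef[2]) if fix_b is None else float(fix_b)
    est.raw_coefficients = (c1, c2, b)

    est.unitary_current_i = c1
    est.baseline_variance_b = b
    if c2 < 0:
        est.n_channels_N = -1.0 / c2
    else:
        est.n_channels_N = np.nan
        est.flags.append("non-negative quadratic coefficient; N undefined")
    pred = A @ coef + (0.0 if fix_b is None else 0.0)
    est.fit_residual_rms = float(np.sqrt(np.mean((V - pred) ** 2)))
    est.valid = bool(c1 > 0 and c2 < 0)
    if not est.valid and c1 <= 0:
        est.flags.append("non-positive unitary current")
    return est


def nsfa_pipeline(
    sweeps: SweepSet,
    spontaneous_events: EventList | None = None,
    config: NsfaConfig | None = None,
) -> NsfaEstimate:
    """Full peak-scaled NSFA: filter, select, align, scale, bin, fit.

    Validity flags propagate: too few clean sweeps or too few occupied
    bins yield an invalid estimate (never an exception), with all
    intermediates retained on the result for inspection.
    """
    cfg = config or NsfaConfig()

    work = sweeps
    if cfg.lowpass_hz is not None:
        work = lowpass_sweeps(work, cfg.lowpass_hz, cfg.lowpass_order)

    work, enough, excluded = select_sweeps(work, spontaneous_events, cfg.min_sweeps)
    if not enough:
        est = NsfaEstimate(n_sweeps_used=work.n_sweeps, polarity=sweeps.polarity)
        est.flags.append(
            f"only {work.n_sweeps} clean sweeps (excluded {len(excluded)}); minimum {cfg.min_sweeps}"
        )
        return est

    aligned, mean_waveform, peakless = align_peaks(work, cfg.peak_smooth_ms, cfg.peak_noise_sigma, cfg.max_align_shift_ms)
    if aligned.n_sweeps < cfg.min_sweeps:
        est = NsfaEstimate(n_sweeps_used=aligned.n_sweeps, polarity=sweeps.polarity)
        est.flags.append(f"only {aligned.n_sweeps} sweeps with detectable peaks; minimum {cfg.min_sweeps}")
        return est

    I_seg, var_seg, details = peak_scaled_variance(aligned, mean_waveform, cfg.peak_smooth_ms, cfg.decay_end_sigma)
    try:
        I_k, v_k, counts, n_dropped = bin_by_current(I_seg, var_seg, cfg.n_bins)
    except ValueError as exc:
        est = NsfaEstimate(n_sweeps_used=aligned.n_sweeps, polarity=sweeps.polarity)
        est.flags.append(str(exc))
        return est
    if len(I_k) < cfg.min_bins:
        est = NsfaEstimate(
            binned_current_I=I_k, binned_variance=v_k, bin_counts=counts,
            n_sweeps_used=aligned.n_sweeps, n_bins_dropped=n_dropped, polarity=sweeps.polarity,
        )
        est.flags.append(f"only {len(I_k)} occupied bins; minimum {cfg.min_bins}")
        return est

    est = fit_variance_mean(I_k, v_k, cfg.fix_b, cfg.min_bins)
    est.bin_counts = counts
    est.n_sweeps_used = aligned.n_sweeps
    est.n_bins_dropped = n_dropped
    est.polarity = sweeps.polarity
    est.mean_waveform = mean_waveform
    est.variance_trace = var_seg
    if peakless:
        est.flags.append(f"excluded {len(peakless)} peakless sweeps")
    return est
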