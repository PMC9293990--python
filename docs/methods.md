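# Methods

This note documents the models implemented in `optoarousal`, the
parameters that matter, the design choices made where the procedure left
room, and what the synthetic-data validation does and does not establish.

## Peak-scaled non-stationary fluctuation analysis

### Model

A postsynaptic current is modeled as `N` identical, independent channels
of unitary current `i` (pA). If `I(t)` is the mean current and the number
of open channels is binomial, the ensemble variance obeys the parabola

    sigma^2(I) = i*I - I^2/N + b,

with `b` the baseline variance (pA^2). Trial-to-trial variation of the
peak amplitude (release probability, pool size) violates the plain
ensemble-variance reading; the peak-scaled variant removes it by scaling
the mean waveform to each sweep's peak before squaring differences.

### Pipeline and defaults

1. *Low-pass* (`lowpass_hz`, default 1 kHz, zero-phase Butterworth order
   4). The cutoff is a convention for recorded data, whose channel noise
   is band-limited. **On the synthetic generator the pipeline is run with
   `lowpass_hz=None`**: the generator draws channel states independently
   per sample, so its fluctuation spectrum is white up to Nyquist and a
   1 kHz cutoff at 10 kHz sampling removes ~80% of the fluctuation power
   itself, deflating the fitted `i` about five-fold. This is a property
   of the synthetic noise model, not of the estimator.
2. *Sweep selection* (`min_sweeps`, default 20): sweeps with any
   spontaneous event inside the analysis window are excluded; fewer than
   20 survivors invalidate the estimate (a flag, not an exception).
3. *Alignment*: each rectified sweep is shifted (≤ 5 ms) to maximize its
   cross-correlation with the provisional ensemble mean. Aligning on
   per-sweep argmax peaks instead couples each sweep's largest noise
   excursion to the alignment point and distorts the near-peak variance.
   Sweeps whose smoothed peak is below 5 pre-pulse SDs are dropped as
   peakless (a smoothed-trace maximum over thousands of samples reaches
   ~3 SD by chance alone).
4. *Peak scaling* (`peak_smooth_ms`, default 2 ms): per-sweep scale
   factors are peak amplitudes read on a lightly smoothed copy; the
   variance is computed on unsmoothed sweeps with divisor `n - 1`. A
   single-sample peak estimate carries that sample's full noise, and
   because the error multiplies the whole scaled template it adds
   `g(t)^2 * (i*Ip - Ip^2/N + b)` to the variance — enough to bias `N`
   upward by roughly a factor of two. Averaging ~20 samples shrinks the
   term by that factor and is negligible against the kernel's 30-ms decay.
5. *Decay segment*: from the mean-waveform peak to the first sample
   within 2 pre-pulse SDs of baseline (the procedure specifies "peak to
   baseline" but not the endpoint).
6. *Binning* (`n_bins`, default 30): edges equally spaced in current
   magnitude; samples assigned by value, not time order; empty bins are
   dropped and counted, never interpolated; fewer than 5 occupied bins
   invalidate the fit.
7. *Fit*: unweighted OLS on the basis {I, I^2, 1}; `i` is the linear
   coefficient, `N = -1/c2`, `b` the intercept (optionally fixed to a
   measured pre-pulse variance, in which case the basis is {I, I^2}).
   Validity requires `i > 0` and `N > 0`; raw coefficients are always
   reported. Bin occupancy weighting is not applied (the source procedure
   is silent; the unweighted fit is the simplest defensible choice and is
   what the exact-recovery tests pin down).

Algebraic identities asserted on every valid fit: the parabola equals `b`
at `I = 0` and has its vertex at `I = i*N/2`.

### Recovery under the generator

With `N=100, i=1 pA, p_peak=0.6, peak_cv=0.1, b=4 pA^2`, 100 sweeps and 20
replicate seeds, the pipeline recovers median `N` within ~6% and median
`i` within ~5%; doubling `N` with `i` fixed doubles the estimate in every
replicate while `i` stays within 5%. These figures validate the estimator
against its own generative assumptions (independent binomial channels);
they do not certify accuracy under correlated channel gating, multiple
conductance states, or electrotonic filtering.

## Synthetic data

*Evoked sweeps*: per-sample open counts `Binomial(N, p(t))` with a
difference-of-exponentials open-probability course (rise 0.5 ms, decay
30 ms), lognormal per-sweep scaling of the peak probability (CV =
`peak_cv`, mean 1), Gaussian baseline noise, polarity applied as sign.
Draws are independent across samples — sufficient to realize the
variance-mean parabola the estimator assumes, deliberately not a Markov
gating scheme.

*Spontaneous trains*: homogeneous Poisson times, lognormal amplitude
magnitudes; event `time` is the rendered kernel's peak time and
`rise5_time` its 5% point, so detector output is directly comparable.
Rendering sums unit-peak kernels scaled by amplitudes plus Gaussian noise.

*Sleep sessions*: a semi-Markov wake/NREM/REM process (exponential dwells,
minimum one 5-s epoch; default means 60/120/60 s and transitions
Wake→NREM, NREM→{Wake .65, REM .35}, REM→{Wake .9, NREM .1} — typical
mouse bout structure at lights-on). EEG is a per-state mixture of
band-limited Gaussian noise (delta 0.5–4, theta 5–9, gamma 30–80 Hz;
weights 1/1.5/2 Wake, 4/1/0.5 NREM, 1/4/1 REM) over a broadband floor;
EMG is white noise with tone 3/1/0.5. The closed-loop schedule triggers
10-s trains (5-ms pulses; sham and 1/5/10/20 Hz drawn uniformly) only
after ≥ 20 s of uninterrupted NREM/REM, with ≥ 3-min refractory and at
most 200 stimulations per session — the recording-protocol constants.

`arousal_prob` maps condition to the **total per-trial arousal
probability** (defaults sham 0.1, 1 Hz 0.25, 5 Hz 0.5, 10/20 Hz 0.9).
By default a trial drawn "no arousal" holds its sleep state through the
train window, so spontaneous exits do not stack on top of the nominal
rate; this makes the parameter mean exactly what the per-condition
probability measures (the sham rate already stands in for spontaneous
arousals). `hold_state_during_train=False` leaves the base dynamics
untouched and stimulation only ever adds wake bouts. Evoked arousals
start after an exponential latency (mean 2 s, clipped to [0.5 s,
train − 3.5 s] so a scored arousal is geometrically possible) and last at
least 5 s.

Not emulated: circadian structure, real hypnogram statistics,
micro-arousals, movement/ECG artifacts, respiration, electrode drift.
Tests passing on this generator demonstrate the *analysis* chain; they
say nothing about scorer agreement with human raters on real data.

All generators are bit-reproducible: every stochastic stage draws from a
substream derived by SHA-256 from `(seed, stage_name)`, so adding a
generator never perturbs another's draws.

## Event detection

Threshold-plus-derivative detector, chosen for determinism: candidate
peaks on a 0.5-ms-smoothed rectified trace (`find_peaks`, refractory
5 ms); local baseline = median of 5 ms ending 2 ms before the peak;
amplitude = raw peak minus baseline, accepted above `amplitude_threshold`
(default 15 pA) with rising slope above `derivative_threshold` (10
pA/ms); the 5% rise point is the first sample after the last sub-5%
sample before the peak; ties break to the earliest sample. At SNR 10 the
detector achieves ≥ 95% recall and precision against generator truth, and
times 5%-rise latencies to ≤ 0.5 ms at 10 kHz.

## Connectivity statistics

Peristimulus profiles use 50-ms bins aligned to pulse onset over
[−0.5, +0.5] s. The criterion: connected iff the first post-pulse bin
exceeds baseline + 5×SEM. Two baseline modes are implemented: per-cell
(mean and SEM across the profile's own pre-pulse bins, the default) and
an externally supplied across-cell population baseline, e.g. the
published 22.43% ± 1.84 (n = 61 cells) for excitatory events. The modes
differ sharply in false-positive behavior: with k pre-pulse bins the
per-cell rule is a one-sided z of 5/√k ≈ 1.58 (k = 10), i.e. ~6–8% false
positives regardless of pulse count, while the population rule's rate
falls with trials per cell (exact binomial ~2% at 90 pulses). The null
calibration therefore uses the population mode with background rate
matched to the population baseline and 90 pulses per cell (15 min at
0.1 Hz).

## Sleep-EEG analysis

*Filters*: zero-phase (forward-backward) 2nd-order Butterworth band-pass,
EEG 0.5–225 Hz and EMG 100–225 Hz. At 500 Hz sampling the 225-Hz corner
sits at 0.9 Nyquist; this matches the recording configuration and is
permitted with a warning.

*EMG envelope*: rectify → 500-sample moving average (reflective edges) →
divide by the pre-stimulus mean; the normalized envelope averages to 1
over that window by construction.

*State scoring* (automated surrogate for visual scoring): per 5-s epoch,
Wake iff EMG RMS > 2× the sleep floor (10th percentile across epochs);
otherwise REM iff theta/delta RMS ratio > 1.5, else NREM. Thresholds are
validated only against the generator (≥ 90% epoch accuracy, typically
≥ 99%) and are configurable; no claim is made about human-scorer
agreement.

*Trials*: −10 s to +20 s around the 10-s train (40 s total, t = 0 at
train onset, half-open windows). Trials are excluded when clipped by the
recording edges or when the 10-s pre-stimulus period is not one
uninterrupted NREM or REM state. REM trials use the same window as NREM.

*Arousal scoring*: within the 0–10 s train window, a wake-like feature
state — EMG envelope > 2× pre-stimulus mean, or delta fraction (1-s
windows) < 0.5× its pre-stimulus mean — sustained ≥ 3 s. Against
generator truth the scorer misses ~0% of evoked arousals with < 1% false
alarms.

*Arousal statistics*: per-animal, per-condition probabilities over valid
trials; group effect = mean per-animal (condition − sham) difference;
BCa 95% CI by resampling animals with replacement — exhaustively over all
`n^n` ordered resamples when `n^n` fits the budget (3,125 at n = 5,
collapsed to the 126 distinct multisets with multiplicity weights, which
is numerically identical), else 5000 Monte-Carlo resamples. Animals
missing either member of a pair are dropped pairwise and reported.
**Known limitation**: any BCa interval for a mean over five animals
under-covers — measured ~85% at a nominal 95% for this implementation and
for `scipy.stats.bootstrap` alike — so coverage-style checks at n = 5
should expect ~85%, not 95%.

*Spectrograms*: complex Morlet with center frequency omega0 = 6
(`pywt` `cmor2.0-0.9549`), 12 voices per octave over 0.5–30 Hz, power =
squared modulus; per-frequency cone-of-influence half-widths
(√2/(1.033 f)) are carried on the grid and edge regions can be masked.

*Paired time-frequency significance*: per animal, mean real-trial power
minus mean sham-trial power (trials are averaged per animal first); the
difference grid is smoothed along time with a 500-sample moving average
on the raw 500-Hz timebase and then downsampled by 10, in that order.
At each coordinate the across-animal mean is bootstrapped as above and
the mask marks coordinates whose CI excludes zero. The CI uses
**expanded percentile** levels, `alpha'/2 = Phi(-t_{n-1,1-alpha/2} *
sqrt(n/(n-1)))`: the plain percentile interval of a 5-animal mean has a
measured two-sided false-positive rate of ~16% at a nominal 5%
(equivalent to thresholding |t_4| at 1.75), while the expanded levels
restore ~8%; plain percentile remains available (`expand=False`).
Sham-vs-sham calibration on the generator gives a masked-pixel fraction
of ~0.08 at alpha = 0.05, and a planted 2 s × 4–8 Hz power increase is
recovered in ~100% of its pixels. Small-cluster removal (4-connected)
defaults to off in the library; the CLI applies a floor of the pixels
spanning 0.5 s × 1 Hz.

## Problem sizes of the reproducibility suite

Chosen to resolve each question on one CPU in seconds to minutes:
20-sweep-minimum NSFA ensembles of 100 sweeps × 20 seeds; 200 cells × 90
pulses for the connectivity null; 20 master seeds × 5 animals × 40 trials
(2.5-h sessions) for the arousal statistics; 20-s EEG segments × 3 trials
per group × 5 animals × 20 seeds for the time-frequency calibration.

## On-disk conventions

Times in seconds, 0-based sample indexing, half-open intervals. Sweeps in
HDF5; polysomnography in classic 16-bit EDF (1-s records, zero-padded to
whole seconds; signals round-trip within one quantization step of the
physical range) with CSV sidecars; events in CSV; results and run
manifests (config hash, seed, versions) in JSON.
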