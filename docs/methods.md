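# Methods

This note documents the models and procedures implemented in `swdkit`,
the defaults and why they were chosen, the numerical details, and what
the synthetic benchmark does and does not establish.

## 1. Signal model and detection pipeline

### Acquisition assumptions

The pipeline assumes chronic rodent cortical EEG sampled at 2 kHz with
an acquisition bandwidth of roughly 0.1 Hz – 1 kHz, in microvolts.
Multi-channel recordings are processed per channel; there is no
cross-channel consensus step (cortical screw electrodes at different
sites can express discharges independently).

### Preprocessing

Each channel is divided into consecutive 10-minute segments
(`segment_length = 600 s`). A final partial segment shorter than one
analysis epoch (0.5 s) is dropped and logged; longer remainders are
processed. Each segment is filtered with a 3rd-order Butterworth
bandpass, cutoffs 0.5 and 400 Hz, designed in second-order sections —
at a 0.5 Hz corner and 2 kHz rate the polynomial transfer-function
coefficients are ill-conditioned, while SOS evaluation is stable.

Filtering is zero-phase by default (`sosfiltfilt`): the filter is
applied forward and backward, which doubles the stop-band attenuation in
dB, squares the passband magnitude, and cancels group delay, so
candidate timestamps are not skewed by the filter. A single-pass causal
mode (`FilterSpec.zero_phase = False`) is provided for a strictly causal
reading; with the default cutoffs the passband is wide enough that the
choice does not measurably change detection on the benchmark.

### Epoch features

The filtered segment is divided into 500-ms non-overlapping epochs
(trailing partial epoch discarded). Per epoch:

* **Amplitude correlation** — the lag-0 Pearson correlation between the
  epoch and its successor. "Correlation between successive epochs" is
  inherently a pair property; we assign the pair value to the earlier
  epoch, and the final epoch of a segment copies the previous value
  (flagged `amp_corr_copied`). A zero-variance epoch yields 0 with a
  `amp_corr_degenerate` flag rather than NaN. A sliding-lag maximum
  (`amp_corr_max_lag > 0`) is available for rhythms whose period does
  not divide the epoch length; with a 6 Hz discharge and 500-ms epochs
  (exactly three cycles) lag 0 is already aligned, which is why lag-0 is
  the default.
* **RMS** — √mean(x²), in µV.
* **Spike density** — local maxima of |x| above
  `threshold_multiplier × robust SD` of the parent segment, with a 30 ms
  refractory period resolved in favour of the larger extremum, divided
  by the epoch length (spikes/s). The robust SD is 1.4826 × MAD of the
  whole filtered segment, so the amplitude criterion is not inflated by
  the discharges being detected. The multiplier (default 5) and
  refractory (30 ms, about one-fifth of a 6 Hz cycle) are package
  choices: the criterion must sit far above Gaussian background
  (P(|x| > 5σ) ≈ 6 × 10⁻⁷ per sample) yet below the spike amplitude of
  any discharge large enough to matter.
* **Band-power ratio** — power in 20–50 Hz divided by power in
  0.5–20 Hz, from a Hann-windowed periodogram of the epoch, integrating
  bins whose centers fall in each half-open band [low, high) so the
  20 Hz bin is counted once. The division is guarded by
  ε = 10⁻¹² × total power. A 500-ms epoch gives 2 Hz resolution, so the
  lower band effectively starts at 2 Hz; `band_context` (e.g. 2.0 s)
  computes the spectrum over a longer window centered on each epoch when
  strict band fidelity matters. `band_mode = "difference"` replaces the
  ratio by P_high − P_low.

Scale behaviour: `rms` is scale-equivariant; `amp_corr`, `band_ratio`
and (because its amplitude criterion scales with the segment's robust
SD) `spike_density` are scale-invariant. With robust-z thresholds the
entire candidate set is therefore invariant under a pure gain change of
the recording — verified as a test.

### Thresholding and candidate formation

An epoch is flagged iff it **strictly exceeds the threshold for all
four features** (logical AND). Raising any single threshold can only
shrink the flagged set (monotonicity), and the conjunction is at most as
permissive as any single feature — both tested properties.

Thresholds are resolved per recording and per channel:

* `robust_z` (default for `rms`, `spike_density`, `band_ratio`, z = 3):
  median + z × scale over all epochs of the channel, with
  scale = max(1.4826 × MAD, 10⁻⁹ × |median|). The floor guards features
  whose MAD is exactly zero (e.g. spike density on a quiet channel,
  where the median and MAD are both 0 — the threshold then degenerates
  to "any spike at all", which is the intended reading under the
  four-feature conjunction). Robust mode requires ≥ 100 epochs
  (50 s of signal); shorter recordings must use absolute thresholds.
* `absolute` (default for `amp_corr`, 0.5): correlation is already on a
  fixed [−1, 1] scale, and its null distribution is tight around 0, so
  a fixed threshold is more interpretable than a z-score.

Whether thresholds should be per-animal or global is a genuinely open
design question; per-recording robust estimation was chosen because
baseline amplitude differs across animals and electrode placements, and
it makes the detector self-calibrating.

Flagged epochs are merged into candidates: maximal runs, bridging
unflagged gaps of ≤ 1 epoch (`max_gap_epochs`), minimum duration 1.0 s
(`min_duration`, i.e. two epochs). The merge rule acknowledges that a
multi-second discharge is scored on a 0.5-s grid: single-epoch dropouts
(e.g. the epoch straddling a brief amplitude dip) should not split one
episode into two. Candidates carry per-feature peak values and the
spanned epoch count for audit. The pipeline deliberately stops at ranked
candidates — the final confirmation of an electrographic seizure is a
human judgement on the signal and the simultaneous video, which is out
of scope.

### Episode statistics and accuracy

`episode_statistics` reports n, episodes/hour (n / recorded hours, with
pooled multi-channel results normalized by channel-hours), and mean ±
SEM duration (SEM = sample SD/√n for n ≥ 2, undefined otherwise).

`evaluate_detection` matches candidates to ground-truth intervals
one-to-one and maximally per channel; a candidate is eligible for a
truth interval when its midpoint falls within `match_tolerance` (2 s
default) of the interval. Maximum-cardinality bipartite matching is used
so the score does not depend on enumeration order. Sensitivity =
matched truth / all truth; FDR = unmatched candidates / all candidates
(undefined when there are no candidates); onset and duration errors are
mean absolute differences over matched pairs.

## 2. Synthetic benchmark

### What it emulates

The generator reproduces the *statistical conditions* reported for
chronic rodent EEG with sparse absence-like discharges: 2 kHz sampling,
episodes at 3.3/hour, durations 4.1 ± 0.4 s, 6 Hz spike-wave repetition.

* **Background**: Gaussian noise with the standard aperiodic EEG
  spectrum S(f) = 1/(1 + (f/f_knee)^α), default α = 2 and
  f_knee = 1 Hz, scaled to exactly 50 µV RMS per channel. The steep,
  delta-dominated spectrum matches rodent cortical EEG, in which
  relative power above 20 Hz is small — this is what gives the
  band-ratio feature its discriminative power. A pure power law
  (knee = 0) and flatter exponents remain configurable; note that at
  α ≈ 1 the background carries so much relative 20–50 Hz power that no
  6-Hz-dominant discharge can separate on the band ratio alone.
  Optional mains interference is a fixed-amplitude sinusoid.
* **Arrivals**: homogeneous Poisson at `rate` episodes/hour, thinned to
  enforce a ≥ 1 s silent gap between events and containment within the
  recording; at 3.3/h the thinning loss is well under 1%. A fixed event
  count (`n_events`) replaces the Poisson draw for benchmark designs.
  Durations are normal(4.1, 0.4²) truncated below at 2 s.
* **Waveform**: sin(2πf₀t) plus one biphasic spike per cycle, phase
  locked to the wave crest. The spike is a Ricker (second derivative of
  a Gaussian) transient with spectral peak at f₀ × n_harmonics
  (6 × 5 = 30 Hz by default, the center of the upper band) and peak
  amplitude 4× the wave amplitude. A monophasic pulse train would put
  its largest harmonics at 6–18 Hz — below the upper band — whereas
  real SWD spikes are sharp and biphasic/polyphasic; the Ricker shape
  captures that while keeping the largest single periodogram peak at
  the fundamental. The waveform is amplitude-tapered (raised cosine,
  0.25 s per end), mean-removed, normalized to unit RMS, and injected
  additively at `spike_amplitude_ratio` × recording RMS (default 4 —
  a calibration choice, since discharge amplitude relative to baseline
  is not a reported quantity; discernible-by-eye discharges in cortical
  screws are several-fold baseline).
* **Reproducibility**: all randomness flows from one root seed through
  named `SeedSequence` substreams (background per channel, schedule,
  waveform per event), so each component is independently reproducible
  and a fixed (config, seed) yields bit-identical output. Injected
  events appear synchronously on all channels, emulating generalized
  cortical discharges; per-site asynchrony and hippocampal depth
  signals are not modeled.

### What passing the benchmark does and does not show

Parameter recovery on this benchmark (sensitivity ≥ 0.85, FDR ≤ 0.15,
mean |duration error| ≤ 1 s at amplitude ratio 4 across 10 seeds, and
zero candidates on ≥ 9 of 10 background-only hours) demonstrates that
the pipeline is internally consistent: the features separate discharges
from the stationary background they were designed against, thresholds
self-calibrate, and timing is recovered to epoch resolution. It does
*not* demonstrate performance on real recordings, which contain
artifacts (movement, chewing, electrode noise), non-stationary state
changes (sleep spindles, theta), and discharge morphologies beyond the
stereotyped template. The deliberate omission of artifacts is why the
benchmark FDR is near zero; on real data the visual-review step remains
essential.

A systematic ~0.4 s under-estimate of episode duration is expected and
observed: the detected interval is built from fully-expressed epochs, so
tapered discharge edges and the pair convention for `amp_corr` (the
last discharge epoch pairs with background) each shave off up to one
epoch. This bias is within one epoch per edge and is reported, not
corrected.

## 3. Behavioral and metabolic metrics

All are pure functions with literal definitions:

* **PPI** (% per prepulse level, startle 120 dB; prepulses 74/78/82 dB):
  (1 − mean prepulse response / mean startle response) × 100. Values may
  be negative (facilitation); a zero mean startle response is an error.
* **RMR** (kcal/h): mean of the two smallest energy-expenditure samples
  whose timestamps fall in the half-open window [4, 8) h after fast
  onset; ties broken arbitrarily (both tied values used). Fewer than two
  samples in the window is an error, not a NaN.
* **Hole-board repetition**: number of maximal runs (length ≥ 2) of
  identical consecutive hole IDs. A run of three counts once; two
  separated runs on the same hole count twice. Because the assay is also
  summarized as "number of holes with ≥ 2 sequential pokes", a
  distinct-hole variant (`repetitive_holes`) is provided; the run count
  is the default as the more literal reading of "continuously poking".
* **Footslips per distance**: slips / distance (m).
* **Charge transfer** (pC): trapezoidal integral of |current − baseline|
  over 120 s of a uniform-rate voltage-clamp trace. Absolute deviation
  is the default so inward/outward current conventions do not flip the
  sign; `signed=True` preserves direction.

## 4. Numerical choices and conventions

* Times are seconds from recording start; sample indexing is 0-based;
  intervals are half-open [start, end). Band edges are half-open.
* "Exceeds the threshold" means strictly greater than, for all four
  features.
* EDF output uses a symmetric digital range (−32767..32767) so 0 µV is
  an exact code, and a symmetric physical range covering the observed
  extrema rounded to 6 significant digits so the ASCII header is exact;
  round-trip error is bounded by half a digitization step. The EDF
  record size is the largest divisor of the sample count not exceeding
  one second. Classic EDF only — no EDF+ annotations, no per-channel
  rates.
* Problem sizes in the shipped tests and the acceptance script (2-h
  benchmark recordings, 1-h null recordings, 10 seeds each, 260
  schedule-only draws for rate calibration) were chosen so the standard
  errors of the estimated rates sit well inside the asserted margins.

## 5. Known limitations

* Single-rate EDF only; no artifact rejection or notch filtering.
* The detector is offline and batch; no streaming mode.
* No seizure-type classification; candidates are one undifferentiated
  class.
* The amplitude-correlation feature assumes the discharge period
  approximately divides the epoch length (true for 6 Hz / 500 ms); for
  other fundamentals enable the sliding-lag option.
* Thresholds assume the discharge burden is a small fraction of the
  recording (robust statistics tolerate contamination up to tens of
  percent, not a signal dominated by seizures).
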