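# Methods

This note documents the models, conventions, and numerical choices
behind `volecall`, and what its synthetic benchmarks do and do not show
about real recordings.

## Signal model and detection

Recordings are assumed to be single- or dual-channel PCM WAV at a
sample rate whose Nyquist frequency clears the 125-kHz upper band edge
(300 kHz nominal). The analysis chain is:

**Band-pass.** Order-8 Butterworth, 15–125 kHz, applied
forward-backward (`sosfiltfilt`), giving zero phase shift, preserved
length, and > 40 dB stop-band rejection.

**Spectrogram.** 512-sample Hann window (≈1.7 ms at 300 kHz, ≈0.59-kHz
bins), hop chosen to realize a 0.5-ms frame step exactly (150 samples at
300 kHz). Frame times are window centers; a frame is taken to represent
the signal on `[t − 0.25 ms, t + 0.25 ms)`, which makes onset/offset
estimates symmetric and gives an *n*-frame segment a duration of
exactly *n* × 0.5 ms. The window length trades time against frequency
resolution: ≈0.6-kHz bins comfortably resolve the 8-kHz jump rule and
the harmonic ratio windows, while ≈1.7 ms of smearing keeps boundary
errors well under 1 ms after the symmetric convention.

**Noise-floor flattening.** For each frequency bin, the median
magnitude over all frames is subtracted and the result floored at zero.
A stationary broadband floor cancels exactly; tonal components retain a
positive excess. This assumes calls occupy **less than half the frames
at any given frequency bin** — true for isolation recordings (duty
cycles well under 50%), but the operator will eat into signal on
near-continuous sound. The per-bin robust spread over time
(1.4826 × MAD) is retained as that bin's noise scale.

**Peak picking.** A bin is accepted as a tonal peak if it is a local
spectral maximum and exceeds both (a) the frame's residual floor plus
`threshold_z` noise scales for that bin, and (b) a relative floor of
−25 dB re the frame's loudest bin. The second criterion rejects the
Hann window's −31-dB sidelobes, which otherwise register as spurious
tones whenever a strong call dominates a frame; its cost is that a
genuinely independent simultaneous sound more than ~18× quieter than
the dominant tone in the same frame is not recorded. Peak frequencies
are refined by three-point parabolic interpolation (≤ ±½ bin). Peaks
are capped at the 7 largest per frame (amplitude ties keep the lower
frequency, protecting the fundamental) and stored ascending in
frequency, so the first entry is the candidate fundamental.

`threshold_z` defaults to **5.0**. With the flattening above, a z of 3
flags over half of pure-noise frames (the magnitude noise is
Rayleigh-tailed, not Gaussian); z = 5 yields a per-frame false-alarm
rate of ~0.7%, which the 6-frame minimum-duration rule then suppresses
essentially completely, consistent with the > 97% segment-level
precision the manual-threshold workflow this replaces was tuned to.
Both thresholds are config-exposed (`threshold_z`,
`peak_relative_floor_db`).

## Segmentation rules

Runs of sounding frames separated by ≤ 4 ms of silence form raw
segments (the silent frames are simply absent from the contour).
Segments are then cut wherever the fundamental jumps by **strictly more
than 8 kHz** between successive sounding frames or the internal silence
**strictly exceeds 4 ms**, and survivors are dropped if they have fewer
than **6 frames** (3 ms of sound) or a median fundamental **below
22 kHz** (noise in this band is overwhelmingly non-vocal). Jumps are
evaluated on the fundamental trace only; higher traces follow their
segment. Splitting runs before the exclusion filters.

## Consolidation threshold

The inter-segment interval histogram uses **10-ms bins from zero**
(configurable). Smoothing is a 5-point running median with edge
replication. The threshold is the **right edge of the first interior
local minimum** of the smoothed counts, where a local minimum is a run
of equal values whose neighboring distinct values are both greater — a
pause in a decline does not count, and a plateau resolves to its first
bin. Returning the right edge makes the "gap ≤ threshold" merge rule
inclusive of the trough bin. Design notes:

- 5-ms bins were tried first; with realistic library sizes (~5 × 10³
  gaps) Poisson noise in the flat valley between the two gap modes makes
  trough localization with 5-ms bins unreliable, while 10-ms bins
  recover the true mixture-density trough within ±1 bin across seeds.
  With a short-gap mode near 10 ms and a between-call mode near 150 ms
  this lands the threshold at 40 ms.
- The threshold is estimated once over the whole extracted segment
  library, not per animal; a fixed override
  (`consolidation_threshold_ms`) and a fallback for trough-less
  histograms (`fallback_threshold_ms`) are provided.
- A monotone (unimodal-gap) histogram raises a no-trough error rather
  than silently inventing a threshold.

Merging is a greedy left-to-right pass; a property test confirms it
equals connected components of the gap-adjacency graph, and contours
are never altered by consolidation.

## Features

All features are computed on the fundamental contour. Slope is the
mean of Δf/Δt over consecutive sounding frames **within** segments —
the derivative is undefined over silence, so cross-segment gaps
contribute nothing; a config flag switches between signed (default) and
absolute averaging. The median frequency is taken over frames; frames
are uniformly spaced, so this equals the time-weighted median. A higher
trace counts as harmonic *k* (*k* ≥ 2) when its ratio to the same
frame's fundamental lies in [*k* − 0.2, *k* + 0.2] (the printed 1.8–2.2×
and 2.8–3.2× windows generalized to all integers); per-*k* runs shorter
than 3 ms are discarded; the per-frame harmonic count is reduced to its
mode over all frames, ties resolved toward the lower count
(conservative harmonicity). Per-minute counts assign each vocalization
to the half-open minute bin containing its onset. Per-animal summaries
use the arithmetic mean across that animal's vocalizations and the
sample variance with the *n* − 1 denominator; an animal with zero calls
keeps count 0 with its feature means flagged missing.

## Two-microphone attribution

Cross-channel segments are matched when their time intervals overlap by
at least 2 ms (no matching tolerance is inherent to the method; 2 ms is
this package's default), greedily by decreasing overlap, each segment
at most once. A matched pair is attributed to the channel with the
greater mean per-frame fundamental peak amplitude over the overlap
window; exact ties go to the pup channel (conservative for pup-count
analyses, configurable). Singletons are attributed to their own
channel. Accuracy on synthetic stereo sessions is monotone
non-decreasing in the cross-chamber attenuation and reaches 100% at
10 dB.

## Cohort statistics

Responses are per-animal summaries, so animals — not calls — are the
unit of analysis. The battery:

- **Two-way age × sex ANOVA** via OLS with **Type-II sums of squares**
  by default (the group sizes in developmental cohorts are typically
  unequal and no convention is universal; Types I/III are selectable).
- **Sex-collapse rule:** if the sex main effect has *p* ≥ 0.05 the
  sexes are pooled and a one-way age ANOVA with Tukey HSD post-hocs is
  run; the decision is returned as an explicit record.
- **Mixed factorial ANOVA** (age between, context within, subject as
  the repeated-measures unit). With a two-level within factor
  sphericity holds trivially, so no correction is applied. Subjects
  missing a context level are an error for feature analyses; silent
  animals enter count analyses with count 0.
- **Paired *t*-tests** across contexts within each age group, with
  Benjamini–Hochberg step-up correction over the family of age groups.
- **z-tests** of difference distributions against zero
  (z = mean / (SD/√n)); zero spread is an error rather than ±∞.
- **One-tailed one-sample *t*-tests** (lower tail) for distributions
  expected to fall below zero, e.g. temperature change under isolation.

Implementations delegate to statsmodels, pingouin, and scipy; the test
suite verifies every statistic against independently coded textbook
formulas (balanced two-way and mixed-design sums of squares, the
two-group Tukey/|t| identity, brute-force BH) to 1 × 10⁻⁸.

## Synthetic data: what it emulates, and what it does not

`synthesize_usv` renders tone stacks by phase integration of an
explicit instantaneous-frequency contour (constant, linear chirp, or
one-cycle sinusoidal FM between the stated extremes), with harmonic *k*
scaled by `decay^k` (default 0.5), 1-ms raised-cosine ramps (so truth
durations are well-defined without spectral splatter), additive white
Gaussian noise, and 16-bit PCM output at 300 kHz. SNR is defined as
peak call amplitude over noise RMS in dB — the recordings this emulates
carry no amplitude calibration, so the scale is this package's own
convention. Dual-channel sessions place each call at full amplitude on
its source channel and attenuated on the far channel with independent
noise. `random_session_truth` produces sessions with realistic
structure: 1–3 segments per vocalization, within-call gaps of 6–25 ms,
between-call gaps ~N(150, 30) ms — the bimodal interval structure the
threshold derivation relies on.

The cohort generator draws per-animal counts from a linear age trend
(default: 1800 calls per 10 min at P6, −120/day) with Gaussian
dispersion (SD 700, matching the scale of reported group SDs), a −1.5
kHz male offset on median frequency (SD 2 kHz between animals), and an
age-specific additive context offset that crosses over from suppression
at P8 (−670) to facilitation at P12–P16 (+350…450), mirroring the
qualitative developmental pattern. Counts are left continuous and
unclipped so every injected cell mean is exact; clipping at zero would
bias low-mean, high-dispersion cells. Within-subject correlation comes
from a shared per-animal level plus half-SD context noise.

Not emulated: room acoustics and reverberation, pup movement (amplitude
nonstationarity), colored or impulsive noise, overlapping same-channel
calls, and physiological call-production constraints. Passing the
synthetic benchmarks therefore demonstrates correctness of the
*rules and estimators* under the stated signal model, not detector
performance on arbitrary real-world recordings.

## Problem sizes used by the benchmarks

The acceptance script and test suite use sessions of 20–40
vocalizations (~10–20 s of audio), gap samples of n = 5000, 100 random
tables for oracle equivalence, 500–1000 Monte-Carlo replicates at
reduced cell sizes (n = 4/cell, 3 ages) for type-I calibration, and
60–100 replicates at realistic cohort sizes (8/cell isolation, 6/cell
× 5 ages × 2 contexts) for power — sizes chosen so the whole battery
runs in about a minute on one CPU while keeping Monte-Carlo standard
errors a few times smaller than the margins being checked.

## Known limitations

- The flattening operator fills the functional role of the original
  workflow's multitaper spectral flattening but is not bit-compatible
  with it; thresholds tuned for one will not transfer numerically.
- Fundamental identification is "lowest detected peak": a call whose
  true fundamental falls below the band edge or detection threshold
  while a harmonic survives will be logged at the harmonic's frequency.
- The −25-dB per-frame relative floor hides simultaneous independent
  sounds much quieter than the dominant tone in the same frame.
- The derived consolidation threshold assumes a genuinely bimodal gap
  distribution; for unimodal libraries the finder deliberately fails
  over to the configured fallback rather than guessing.
- Degrees-of-freedom bookkeeping in unbalanced two-way designs depends
  on the sums-of-squares convention; results are reported with their df
  so the convention is always explicit.
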