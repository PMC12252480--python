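# Methods

## Problem and signal model

Two chest-surface signals describe one cardiac cycle from complementary
sides. The electrocardiogram (ECG) records the electrical activity: the QRS
complex marks ventricular depolarisation, with the Q trough immediately
before the dominant R peak and the S trough immediately after. The
phonocardiogram (PCG) records the mechanical consequence: the first heart
sound S1 (closure of the mitral/tricuspid valves, oscillatory content
roughly 10–200 Hz, the loudest feature) and the weaker, higher-frequency
second sound S2 (aortic/pulmonary closure) that follows S1 by one systole,
physiologically 125–500 ms.

From one beat's fiducials the systolic time intervals are

```
EMAT = t(S1 onset) − t(Q)          electromechanical activation time
PEP  = t(S1 peak)  − t(Q)          pre-ejection period (operational def.)
LVET = t(S2 peak)  − t(S1 peak)    left-ventricular ejection time
LVST = t(S2 peak)  − t(S1 onset)   left-ventricular systolic time
S1R  = t(S1 onset) − t(R)
```

in milliseconds. By construction `LVST − LVET = PEP − EMAT` exactly for any
complete beat — the pipeline asserts this identity rather than assuming it.
Each interval can be normalised by the beat's RR interval (stored as a
dimensionless fraction) and the PEP/LVET ratio is reported as a
contractility index.

## Segmentation algorithm

Recordings are processed in consecutive non-overlapping 10 s windows (the
trailing remainder is dropped). Per window:

**Conditioning.** The ECG is linearly detrended and high-passed at 2 Hz
(4th-order Butterworth, half-power convention, forward–backward so the net
phase is zero and fiducial times are not shifted). The PCG is mean-subtracted
and detrended only; a separate 40 Hz zero-phase low-pass copy is kept for
the onset search. Forward–backward filtering uses odd-reflection padding
(the `sosfiltfilt` default), which makes results bit-reproducible on a
platform.

**S1 peaks.** The squared PCG is thresholded at `0.1·max(pcg²)`; each
contiguous above-threshold run contributes its centre index as a candidate.
Candidates are gated on the signed PCG amplitude against
`0.5·mean(pcg at candidates)` — this is what rejects negative-phase carrier
extrema — and finally a 425 ms refractory rule is applied. The refractory
rule is greedy by default (a candidate is kept only if it is ≥ 425 ms after
the last *kept* candidate); the alternative single-pass variant, which
compares each candidate with its immediate predecessor even when that
predecessor was itself discarded, is available as
`S1DetectorParams(refractory_mode="vectorized")`.

**Amplitude consistency.** A detection is accepted iff its amplitude is
within 40 % (closed bound) of a running mean of the last 5 accepted S1
amplitudes; the reference for the first beat is the median candidate
amplitude of the window. The history length and seeding rule are exposed in
`S1DetectorParams` because no canonical values exist.

**S2 peaks.** For beat *j* the squared PCG is searched in
`(s1[j], s1[j+1]]` (last beat: to the window end) for local maxima whose
delay after S1 lies strictly inside 125–500 ms. The reported S2 time is the
mean of the surviving candidate times (`S2Params(mode="max")` instead takes
the largest candidate). Candidate maxima below `0.1×` the search range's
squared maximum are ignored: on broadband-noise-bearing signals *every*
noise wiggle is a local maximum and the unweighted mean of their positions
collapses to the centre of the search window regardless of where S2 is;
the adaptive gate (same style as the S1 threshold) restores the selection
behaviour that smooth recordings exhibit naturally. `min_height_frac=0`
disables the gate.

**S1 onsets.** On the 40 Hz low-passed PCG, prominent troughs (inverted
peaks ≥ `0.2·max(−pcg)`, at least 200 ms apart) seed a backward walk that
steps left while the signal is strictly decreasing forward in time; the
stopping sample — the crest preceding the trough — is the candidate onset.
A candidate survives only if it lies within 50 ms of a detected S1 peak and
not after it; each beat keeps its earliest surviving candidate.

**QRS.** R peaks are local maxima ≥ `0.5·max(ecg)`. Q (S) is searched in
the 250 ms window before (after) each R among local maxima of the negated
ECG above the adaptive threshold `0.2·max(−ecg)`; Q takes the candidate
closest to R (the Q trough immediately precedes R), S takes the earliest
candidate after R, with a minimum candidate spacing of
`min(0.05 s, 0.9·window span)`. An alternative fixed Q height (0.1) exists
for compatibility but breaks amplitude-scale invariance, so the adaptive
rule is the default. An optional minimum R–R separation (0.3 s) can guard
against notched or noise-split R peaks; it is **off** by default for
fidelity to the plain threshold rule.

All thresholds are relative to the window's own signal, so every fiducial
time is invariant to positive rescaling of either channel (property-tested).

**Pairing and statistics.** Each Q is paired with the earliest unused PCG
beat whose S1 anchor (onset if present, else peak) follows it within 250 ms;
unpaired fiducials are dropped, and ECG beats that resolve to the same Q
(noise-split R detections) are collapsed to the median-R row first. RR comes
from consecutive paired R peaks. Beats whose S1 lies within 100 ms of a
window edge are flagged and excluded from summary statistics. Summaries
report mean, sample SD (n−1), median and IQR (linear-interpolation
quantiles), missing values excluded per interval. Screening flags are
evaluated on window means: EMAT% > 12.1 %, EMAT ≥ 104 ms, %EMAT > 13.8 %,
EMAT/LVST ≥ 0.40 — thresholds associated in the clinical literature with
reduced ejection fraction and left-ventricular dysfunction. Flags are
tri-state (`None` when the required means are missing).

**Agreement.** For two paired interval series the Bland–Altman statistics
are `mean(d)` and `mean(d) ± 1.96·sd(d)` with `d = a − b` and sample SD; a
t-based multiplier is available for small n but 1.96 is the default.
Relative errors divide by the reference series `b`; because published
comparisons are ambiguous about aggregation, both the mean of per-pair
relative errors and the aggregate `mae/mean(|b|)` are exposed.

## Synthetic generator

`BeatTrainSpec` encodes the study conditions; the defaults are the
resting-adult profile the package validates against: 28 beats over ~20 s
(RR 714 ± 20 ms), EMAT 74 ms, PEP 89 ms, LVET 244 ms (hence LVST 259 ms),
per-beat interval jitter ±2 ms, white noise at 20 dB SNR per channel,
0.05-amplitude baseline wander at 0.3 Hz, sampling 2 kHz. One seeded
`default_rng` stream drives all randomness, so a spec is bit-reproducible.

The ECG is a per-beat sum of Gaussian P/Q/R/S/T deflections. Widths and
amplitudes are a *generator contract*, not a claim about real ECG: they are
chosen so the adaptive thresholds resolve each wave crisply at the default
noise level. Two choices matter and are deliberate: the Q wave is narrow
(σ = 3 ms) and the S wave deep (−1.0), which keeps the adaptive Q/S
threshold (0.2·max(−ecg) = 0.2) well above the noise floor; with a wide,
shallow Q the "closest to R" tie-break would systematically latch onto
noise maxima on the Q–R shoulder and bias Q late by ~10 ms — a genuine
sensitivity of the threshold rule that the front-end band-limiting of real
acquisition chains masks.

S1 is built as two superimposed parts, each aimed at the operational
definition of the detector that must find it:

* a **low-frequency skeleton** (content ≲ 33 Hz, essentially untouched by
  the 40 Hz onset low-pass): a small crest (amplitude 0.1) peaking exactly
  at the programmed onset `q + EMAT`, a half-cosine descent to −0.5 over
  16 ms, and a 20 ms recovery. The backward-slope onset search terminates at
  the crest preceding the deepest low-passed trough; making that crest *be*
  the programmed onset is the only construction that survives the filter:
  any sharper attack is smeared backward by the zero-phase kernel
  (half-width ~12 ms), which otherwise biases the walk a half-ring-period
  early no matter the attack time.
* a **high-frequency hump and ringdown** (4 ms rise to the burst maximum
  exactly at `q + PEP`, then a 90 Hz cosine decaying with τ = 20 ms). The
  squared-threshold cascade reports the centre of the run around this
  maximum; at 90 Hz the component is ~80 dB down after the 40 Hz
  forward–backward low-pass, so it cannot disturb the onset search.

S2 is a 120 Hz cosine under a symmetric raised-cosine envelope of 100 ms
width (inside the published 100–140 ms S2 duration band) centred at
`s1_peak + LVET`; symmetry matters because the S2 estimator *averages*
candidate maxima, and an asymmetric (decay-only) envelope would bias that
mean late by ~10 ms.

Interval combinations are validated up front: PEP > EMAT, LVET within
130–400 ms (so S2 falls strictly inside the 125–500 ms search window and
inside the 425 ms S1 refractory period), and S2 clear of the next beat's
S1. Infeasible specs raise with an explanation.

`emulate_front_end` optionally applies the causal acquisition chain of a
low-cost two-channel recorder — 2nd-order 100 Hz low-pass plus mid-sample
averaging (half-sample delay) on the PCG, 2nd-order 15 Hz low-pass on the
ECG — for robustness experiments; it is not part of the default pipeline.

### What the generator does and does not emulate

It emulates: synchronous two-channel timing with programmable ground truth,
S1/S2 band placement and relative loudness (S2 weaker than S1), beat-to-beat
RR and interval jitter, additive broadband noise, baseline wander. It does
not emulate: heart-rate-variability spectra, respiratory modulation,
murmurs or extra sounds (S3/S4), pathological QRS morphologies, motion
artifacts, or electrode/contact noise. Consequently, passing the recovery
tests shows the pipeline implements its rules correctly and is unbiased on
signals satisfying its assumptions — it does not certify accuracy on
pathological or artifact-laden recordings.

## Numerical choices

* Run centres use integer midpoint `(start + stop) // 2`; candidate times
  are `t0 + index/fs` (0-based indexing).
* The S2 window bounds are strict (`125 ms < Δ < 500 ms`); the consistency
  tolerance is a closed bound (≤ 40 %); EMAT ≥ 104 ms and EMAT/LVST ≥ 0.40
  are closed, the two EMAT% thresholds open.
* CSV sampling rate is `1/median(Δt)` so single skipped or duplicated
  timestamps cannot corrupt it; decreasing timestamps are rejected, ties
  tolerated.
* Missing fiducials are `NaN` throughout and propagate to missing intervals;
  summaries exclude them per column.
* Degenerate inputs (flat signals, windows shorter than the filter warm-up)
  raise `ValueError` per window; the pipeline logs and skips such windows.
* Output CSV floats are formatted to 6 decimals, so identical input and
  configuration give byte-identical files.

## Problem sizes

The default validation profile is 28 beats (~20 s at 2 kHz); the parameter
recovery study uses 60-beat trains at 2 kHz over ten seeds, chosen as the
smallest design in which the beat-mean estimator's standard error (< 0.5 ms)
is negligible against the ±5 ms recovery criterion. Detector-versus-oracle
equivalence uses 4000-sample white-noise signals over 100 seeds, which
exercises every branch (runs, gates, refractory and distance pruning,
missing fiducials) far more densely than physiological signals do.

## Known limitations

* The onset estimator is defined on the 40 Hz low-passed signal; its result
  on real data depends on the acquisition chain's phase response. The ~2 ms
  residual early bias measurable on the generator's own contract is inherent
  to the crest-stopping rule under noise.
* The Q "closest to R" tie-break is noise-sensitive when the adaptive
  threshold approaches the noise floor (see above); real front-ends
  band-limit the ECG, which mitigates this.
* The S2 averaging rule can only be unbiased for bursts that are
  symmetric within the gate; `mode="max"` is more robust for asymmetric S2.
* Window means, not per-beat values, drive the clinical flags; per-beat
  flagging would need a different false-positive analysis.
* The package segments; it does not diagnose. Threshold crossings are
  screening signals quoted from the literature, not a classifier.
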