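# Methods

This note records the modeling choices behind `spikefbn`: what each stage
assumes, which parameters matter, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## Signal model and preprocessing

Recordings are multichannel scalp EEG in µV at ≥ 250 Hz (1 kHz
throughout the defaults, matching clinical BECT acquisition).  Amplitude
conventions: sample indices are 0-based, frames are half-open spans,
spikes are injected surface-negative but every matching step is
polarity-agnostic.

Preprocessing is a 0.017–70 Hz band-pass of Butterworth character,
order 4 per corner.  It is applied as the *squared magnitude response in
the frequency domain*, which is exactly what zero-phase forward–backward
time-domain filtering realizes, for two reasons: (a) zero phase keeps
spike apices at their recorded latencies, which the apex-matching stages
rely on; (b) the 0.017 Hz drift corner puts a pole with a ~10 s time
constant next to the unit circle, and recursive zero-phase filtering
(`filtfilt`) then produces edge transients that span entire
minutes-long records — measured leakage of an out-of-band 200 Hz probe
tone exceeded 100% with the recursive route and is < 1% with the
spectral route.  The channel mean is removed first; edges are treated as
periodic.  Consequence worth knowing: applying the filter twice halves
components *at* the corners (roll-off squared), so idempotence holds
only for content well inside the band.

Montages: the average reference (AV) subtracts the mean of the 16
standard electrodes (A1/A2 excluded), in fixed order FP1 … O2; the
bipolar (BP) montage is the longitudinal double banana (16 derivations,
anterior minus posterior).  Every AV electrode maps to the derivation
ending at it and the one starting at it within its chain; chain
endpoints (FP1/FP2/O1/O2) map to their single parasagittal derivation
twice, so each candidate always yields exactly 3 feature channels and
the 35-feature layout never varies.

EDF files are read through mne.  Writing uses a minimal built-in 16-bit
EDF writer (1 s records, symmetric physical range per channel); the
round trip against mne's independent reader is exercised in the tests.

## Synthetic EEG generator

The generator defines the study conditions for every downstream claim.
Defaults: 16 channels, 1 kHz, 20 min, 240 double-channel spike events on
C3+P3, spike amplitude 300 µV (uniformly jittered ×1.0–1.2) and duration
60 ms within the clinical 20–70 ms range, background standard deviation
20 µV, synchrony strength 0.8.

Background = 1/f-power ("pink") noise per channel, plus an
amplitude-modulated 10 Hz rhythm whose variance share is largest
occipitally (40%) and small frontally (8%), plus sparse non-epileptiform
sharp transients (Poisson rate 0.3/s over the whole montage, single
random channel, amplitude 2–5× the background SD, duration 40–120 ms).
The transients are part of the background model on purpose: their slopes
and curvatures straddle the morphology gates, so the candidate stage
over-generates the way it does on real recordings and the classifier has
genuine hard negatives to reject.  The rate and ranges were fixed from
that gate arithmetic, not fitted to data.

Spikes are symmetric triangles injected on the raw channels (so the AV
view carries 15/16 of the nominal amplitude) with apices separated by
more than 600 ms, which guarantees a 300 ms analysis frame never spans
two events.  During each spike epoch (apex ± 50 ms, matching the 100 ms
PLV window) all channels receive a Hann-windowed sine at a random
frequency in 14.5–70 Hz with a *common phase* but per-channel random
gain (uniform 0.5–1.5), scaled by `sync_strength` × 3 × background SD.
The common phase is what elevates spike-epoch PLV; the gain spread is
what lets the component survive average-referencing.  The burst's phase
is anchored to cross zero at the apex sample so it never erodes the apex
amplitude that the annotations guarantee.

What the generator does **not** emulate: blink/EMG artifacts, spike-wave
complexes, inter-subject variability, electrode drift or line noise.
Passing tests therefore show the pipeline's internal consistency and its
behavior under controlled morphology/synchrony contrasts — not clinical
performance.

## Template matching

The screening statistic is the normalized cross-correlation of a frame
with a template of equal length; it is symmetric and scale-invariant,
an all-zero frame scores 0 by convention, an all-zero template is an
error.  The universal template is the 300 µV / 60 ms triangle centered
in a 300 ms frame.  Scanning evaluates frames every 10 ms (stride
configurable), takes each frame's apex as the extremum of the detrended
amplitude, re-aligns the window so the template apex coincides with it
(which makes the statistic stride-insensitive), and applies both gates:

* correlation |C| ≥ 0.60 (universal) or 0.75 (specific);
* morphology: the frame's rising slope, |falling slope| and apex
  curvature must each reach 30% (universal) / 40% (specific) of the
  template's own values.

Curvature is the amplitude-normalized central second difference at the
apex over a **5 ms stencil**.  The one-sample second difference is the
obvious definition but measures the wrong thing at 1 kHz: the 70 Hz
acquisition low-pass rounds the apex and pushes a true spike's
one-sample curvature *below* the gate, while broadband noise roughness
pushes false frames *above* it.  The 5 ms stencil measures the spike's
own sharpness, is stable under the low-pass, and leaves the canonical
triangle's slope values (±10 µV/ms) untouched.

Specific templates: accepted frames are apex-aligned, oriented positive,
normalized to unit peak and clustered with K-means (k-means++, fixed
seed, n_init 10).  k grows from 1 and stops the first time some cluster
falls below 5% of the candidates; undersized clusters are discarded and
the remaining centroids — rescaled to their members' mean apex
amplitude — are re-matched at the stricter thresholds (a "prune and
continue" stop rule is available as a config flag).  Finally, per
channel, detections closer than 100 ms collapse to the best-correlated
one; the merge is idempotent.

Unstated constants fixed here: scan stride 10 ms, specific thresholds
0.75/0.40, merge interval 100 ms — all configurable.

## Morphology features

Frames reduce to three landmarks on the detrended, apex-oriented signal:
the apex (extremum of |amplitude|, nearest the hint when one is given)
and the nearest local minima on each side (frame edges as fallback;
monotone frames have no landmarks).  The ten per-channel features are
the left/right/total durations (ms), half-wave amplitudes and their
maximum (µV), signed slopes and the total-excursion slope (µV/ms), and
the area (µV·ms) between the signal and the trough-to-trough chord —
the chord baseline makes the area DC-invariant.  `Amp_peaks` is the
*maximum* of the two half-wave amplitudes (the sum was the other
reading).  A bipolar frame with no resolvable landmarks (e.g. perfectly
cancelling in-phase discharge on C3-P3) contributes a zero block and is
logged, keeping the 30-vector layout fixed.

## PLV networks

Phases come from the analytic signal of the band-passed (14.5–70 Hz,
order-4 Butterworth, 50 ms reflect padding trimmed after the transform)
channel — the quadrant-aware arctangent form, defined also where the
signal crosses zero.  Narrowband filtering before the Hilbert transform
is required for the phase to be interpretable; the band is the spike
band implied by 20–70 ms transients.  The pairwise statistic uses
locking ratio p = q = 1.  A candidate's network is the element-wise mean
of the pairwise PLV matrices over the three non-overlapping 100 ms
windows tiling its 300 ms frame, with unit diagonal; weights are clipped
to [0, 1] against float round-off.  The matrix construction is the Gram
matrix of unit phasors, verified against a naive double loop at 1e-12.

## Graph metrics

All five metrics treat the PLV matrix as a weighted complete graph
(PLV > 0 almost surely; no thresholding by default):

* **AD** — mean node strength (sum of incident weights).
* **ACC** — triangle-intensity (geometric-mean) clustering, weights on
  the natural PLV scale where the maximum possible weight is 1; this
  reduces to the binary formula on 0/1 graphs and gives ACC = w on a
  uniformly weighted complete graph.  A `binarized` mode thresholds the
  weights and applies the binary formula instead; which variant the
  published analyses used is not decidable, so both exist.
* **CPL / GE** — shortest paths under edge length 1/weight.  The default
  divisor is N(N−1) (ordered pairs), under which the complete unit graph
  has CPL = GE = 1; the nonstandard printed divisor N(N+1) is exposed as
  `as_printed` (the two differ exactly by (N−1)/(N+1)).  CPL raises on
  disconnected graphs; GE handles them (unreachable pairs contribute 0).
* **MD** — modularity Σᵤ[eᵤᵤ − (Σᵥ eᵤᵥ)²] evaluated exactly with eᵤᵥ =
  fraction of total edge weight between modules (full inter-module
  weight in each row), on a partition from deterministic greedy (CNM)
  weighted modularity maximization.  One module scores exactly 0; two
  disconnected unit triangles score 0.5.

## Classifier

35→64→32→1, ReLU hidden, sigmoid output, binary cross-entropy, Adam in
its standard bias-corrected form (β₁ 0.9, β₂ 0.999, ε 1e-8, η 1e-3),
100 epochs, batch 32, inverted dropout 0.5 after the first hidden layer
(placement configurable — the source description of the dropout layer is
singular).  Implemented in plain numpy with hand-derived backprop:
no deep-learning framework is needed at this scale, training is
bit-deterministic under a seed, and the analytic gradients stay
accessible for the finite-difference check (agreement to 1e-5 relative
on the full parameter vector).

Features are min-max normalized with training-split statistics only
(test features may leave [0, 1]); the parameters travel with the model,
which persists as a portable `.npz`.  Balancing keeps the minority class
and undersamples the majority (in practice: all spikes, thinned false
positives).  Cross-validation (stratified 5-fold) records the per-epoch
loss/accuracy curves used for round selection; the deployed model is
retrained on the full training split.

## Evaluation and experiment design

Candidates are labeled against ground truth per channel with a 60 ms
tolerance (about one spike duration), one-to-one and nearest-first, so
one annotation validates at most one candidate.  AC/SE/SP are computed
from the confusion matrix, with zero-denominator cases reported as NaN.
The repeated experiment performs detection and feature extraction once,
then repeats balance → split → train → score with fresh seeds and pools
the confusion matrices before applying the rate formulas; per-run tables
are also returned.

Problem sizes: the acceptance-level experiment uses one 5-minute
recording with 60 double-channel spike events and 20 repeated splits,
and the shared test recording is 60 s with 12 events — sizes chosen so
the full suite exercises every stage at desk scale.  The repeat default
in `RunConfig` is 100.

## Known limitations

* The generator's spike is a clean triangle; real BECT spikes have
  after-going slow waves and variable asymmetry, so real-data thresholds
  likely need retuning.
* Near-ceiling synthetic classification means the FBN vs FBN-PLV
  comparison on synthetic data tests a direction (network features do
  not hurt sensitivity), not an effect size.
* The spectral band-pass assumes offline, whole-record processing; it is
  not suitable for streaming use.
* CPL on a thresholded (possibly disconnected) network is undefined by
  design — use GE.
* Detection within 150 ms of the record edges is not attempted (a full
  analysis frame must fit).
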