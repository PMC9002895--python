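# Methods

## Problem and approach

`ecgfusion` detects heart anomalies in two-lead ambulatory ECG in two stages.
Stage 1 slides a 3-second window (step 1 s) over the record and classifies
each window as normal or abnormal *rhythm*.  Stage 2 then inspects every
heartbeat inside normal-rhythm regions and classifies its morphology as a
normal or abnormal *beat* — some beats (e.g. a lone premature ventricular
contraction) hide inside otherwise normal rhythm.  Both stages use the same
model family: a CNN over the window's STFT spectrogram whose pooled features,
squashed to [0, 1] by an elementwise sigmoid, are concatenated with a
fixed-schema handcrafted feature vector (min–max scaled to [0, 1] on training
data), followed by dropout and a single sigmoid unit.  The two recording
leads get one model each and the per-lead scores are fused.

## Preprocessing

* Records at 360 Hz are brought to 250 Hz by rational 25/36 polyphase
  resampling with a Kaiser-window FIR anti-aliasing low-pass
  (`scipy.signal.resample_poly`); 250 Hz records pass through unchanged.
  Output length is `ceil(N * 25/36)`; annotation indices are rescaled by the
  same factor.
* Each lead is min–max normalized to [0, 1] per record, before windowing —
  the only reading under which the normalization is well defined for
  streaming excerpts.
* Rhythm windows are `3*fs` samples every `fs` samples; a trailing partial
  window is dropped.  A window is labeled abnormal if its span overlaps *any*
  abnormal rhythm interval (any-overlap maximizes sensitivity; a
  majority-overlap rule would be the natural alternative and the label map is
  injectable).
* A heartbeat excerpt spans `[R(i-1), R(i+1))` — previous R peak to next R
  peak, half-open so consecutive excerpts never share a sample.  First and
  last annotated beats have no bounding neighbour and are skipped.
* Class balancing down-samples the majority class uniformly at random
  (seeded) to the minority count; the test split takes `floor(0.1 * total)`
  items drawn per class so both splits stay 50–50 within one item.

## Handcrafted features

Rhythm (9 entries, fixed order): R-peak counts from the two detectors,
skewness, kurtosis, variance of the raw window, and average RR / QRS / PR /
QT interval lengths over the delineated beats.  Heartbeat (11 entries):
normalized R amplitude, left/right RR, the three moments, QRS / PR / QT
lengths, and normalized P and T amplitudes.  The schema order is part of the
model contract — trained weights depend on it.

Moment conventions are deliberately mixed and each formula is honored
literally: skewness `mu3/sigma^3` and kurtosis `mu4/sigma^4` use population
(1/N) central moments and kurtosis is non-excess (Gaussian → 3; an `excess`
flag subtracts 3), while variance uses the `N-1` sample denominator.  Inside
feature assembly a constant window yields 0 for skewness/kurtosis so vectors
stay total; the direct functions raise instead.

Undetected waves follow a zero-sentinel rule: a MISSING fiducial forces its
interval lengths and peak amplitude to 0, and interval *averages include*
those zeros rather than skipping the beats.

## R-peak detection

Two detectors run independently, and both counts are carried as features —
they degrade differently on distorted beats, which is itself discriminative.

* **Pan–Tompkins**: band-pass 5–15 Hz (2nd-order Butterworth, zero-phase),
  derivative, squaring, 150 ms moving-window integration, adaptive dual
  thresholds (signal/noise running estimates with 0.125/0.875 updates),
  search-back above half threshold when an RR gap exceeds 1.66 x the running
  average, 200 ms refractory.
* **SEEHT**: band-pass 5–25 Hz, first difference, amplitude normalization,
  Shannon energy `-d^2 ln d^2`, 150 ms zero-phase smoothing, Hilbert
  transform of the mean-removed envelope; R peaks sit at zero crossings of
  the odd component (negative-to-positive under scipy's `x + iH[x]`
  convention).

Both chains are implemented with centred/zero-phase filters so envelope peaks
stay aligned with the R apex, which is finally refined to the local raw-signal
maximum within +/-50 ms.  All constants (band edges, window lengths, update
coefficients, refractory, envelope floor) live in `DetectorConfig`; the
defaults follow the classical descriptions of the two algorithms.  Both
chains normalize internally, so detection is invariant to global amplitude
scaling.

## Delineation

Around each R apex the delineator finds QRS onset/offset by walking outward
until the lightly smoothed first derivative (5-sample moving average) stays
below a noise floor — 5% of the beat's peak derivative magnitude — for a
sustained run; a single sub-floor sample can be a wave apex inside the
complex, not a boundary.  Q and S are the signal minima flanking R inside the
boundaries.  P is searched in a 200 ms window ending 40 ms before QRS onset;
T in a window starting 80 ms after QRS offset, capped at `min(400 ms,
0.6 * RR)`.  Within a window the wave peak is the derivative zero-crossing
between the derivative's extremes (a wave apex is exactly a sign change of
the first derivative; a raw-signal zero crossing need not exist in a [0, 1]
normalized trace).  Flat or degenerate windows yield MISSING, never an
exception.  PR is measured P-peak→R-peak and QT is Q→T-peak, because the
delineator works on peaks rather than wave onsets; clinical PR/QT use
onsets/offsets, a documented deviation.

## Spectrograms

Hann window; L = 167 samples (0.668 s) for rhythm windows and L = 28
(0.112 s) for heartbeats; hop defaults to `floor(L/2)` (50% overlap) and the
DFT length to L (no padding), so a 750-sample rhythm window yields 8 columns.
Power maps to dB with a floor at -100 dB (empty bins stay finite), rescales
linearly to 8 bits, is oriented frequency-up/time-right, and is bilinearly
resized to 875 x 656 (width x height) by default.  Grayscale writes intensity
directly; RGB applies a fixed 256-entry jet-like lookup table materialized
from matplotlib at import.  Models consume a configurable smaller rendering
(default 32 x 32) of the same mapping.

## Network and training

Backbones: `tiny-test` (two 3x3 conv blocks, 16 features — the desk-scale
workhorse), VGG-16/19 (standard 3x3 stacks), and ResNet-18/34 (basic blocks
with batch normalization); all end in global average pooling (512 features
for the standard backbones), and the final classification layer is replaced
by the merging head.  No pretrained weights.  The layer stack (convolution
via im2col, pooling, batch norm, residual blocks, dense, dropout) is
implemented in-package on numpy with full backpropagation, verified against
numerical differentiation.

Loss is binary cross-entropy — the scalar sigmoid output implies it.  SGD
with initial learning rate 0.1 halved every 10 epochs (both configurable);
gradients are globally norm-clipped at 5.0 for stability at that high initial
rate.  An inner 80/20 train/validation split (seeded) drives early stopping:
training stops once validation accuracy strictly decreases in two consecutive
epochs.  Dropout (rate 0.5 by default) sits after the feature merge.  Epoch
training accuracy is recorded in evaluation mode (dropout off).

Decision rules: a single-model score `x` is abnormal iff `x > 0.5` (the
boundary is normal); the fused two-lead score `y = y1 + y2 - 0.5` is abnormal
iff `y >= 0.5` (the boundary is abnormal).  The two conventions disagree at
their boundaries and both are kept exactly as defined, not harmonized.  When
the per-lead labels agree away from the boundary, the fused label provably
equals them.

## Synthetic data

The generator emulates the structure of the target databases: two leads
(lead 2 is lead 1 scaled by 0.6 with independent noise), 250 or 360 Hz,
per-beat R annotations and onset-style rhythm annotations.  Each beat is a
sum of Gaussian bumps, one per P/Q/R/S/T wave, around equally spaced R times;
defaults are physiologic-ish (P: 0.10 units, 80 ms, -160 ms from R;
T: 0.30 units, 120 ms, +250 ms; QRS triplet around R).  Wave "width" is the
approximate full duration; the Gaussian sigma is width/4.  Anomalies:
`premature` shortens the preceding RR by 0.6 and removes the P wave (symbol
PVC); `wide_qrs` doubles the Q/R/S widths *and* the Q/S offsets so the whole
complex dilates (PVC); `absent_p` removes P (J); `tall_t` triples T (Q).
Per-record seeds derive from the master seed by the fixed affine hash
`(seed * 100003 + 7919 * i) mod 2^31`.

What passing on this data does and does not show: the morphology is smooth,
unimodal and noise-controlled, so perfect detector recall and +/-20 ms
delineation here demonstrate correctness of the chains, not clinical
performance; real records have baseline wander, muscle artifact, biphasic
waves and rhythm transitions the generator does not model.  The end-to-end
accuracy criterion is run on a deliberately separable synthetic contrast
(tachycardic wide-QRS rhythm vs normal sinus rhythm) and validates the
pipeline plumbing and trainability, not the published large-scale accuracy.

## Problem sizes

The shipped experiment and acceptance configurations use 16 records of 27 s
(400 balanced rhythm windows, 90/10 split), 32 x 32 model inputs and the
`tiny-test` backbone — sizes chosen so a full run completes in well under a
minute on one CPU core while exercising every stage.  The study-scale
balancing arithmetic (26,532 + 1,199,065 → 53,064 → 47,758/5,306) is
reproduced exactly on index arrays.

## Known limitations

* The WFDB layer covers headers, format 16 (read/write) and 212 (read), and
  MIT `.atr` annotations — enough to round-trip this package's records and
  read the target databases' signal/annotation layout; multi-file signal
  groups and other formats are out of scope.
* Paced and right-bundle-branch-block beats are excluded from heartbeat
  datasets by default, but the exclusion list is configuration
  (`LabelMap.beat_excluded`), because the source guidance on paced beats is
  self-contradictory.
* VGG/ResNet backbones are functional but impractically slow to *train* on
  large images in pure numpy; they exist for architectural fidelity and
  forward-pass use, and `tiny-test` is the tested training path.
* Kurtosis "should be zero for a Gaussian" only in its excess form; the
  implemented default is non-excess per the defining formula, with an
  `excess=True` escape hatch.
* RR semantics: heartbeat features use left/right RR about the central R;
  there is no single "the RR" of an excerpt.
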