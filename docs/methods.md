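# Methods

This note documents the models, numerical choices and design decisions
behind `uhdfinger`, and what the synthetic validation does and does not
establish about real recordings.

## Montage geometry

The recording array is a patch of diamond-shaped 4×4 electrode grids
(16 contacts, 8.6 mm centre-to-centre pitch), tiled contiguously and worn
over the sensorimotor cortex of one hemisphere. We model the scalp as a
**parametric hemisphere** (radius 90 mm, configurable) rather than an
anatomical head: every quantity the analysis consumes is a function of
inter-electrode distance, which a parametric surface preserves.

The planar grid lattice is rotated 45° (the grids sit as diamonds on the
head) and mapped onto the sphere with the **inverse Lambert azimuthal
equal-area projection**, anchored at the vertex. The choice of projection
matters: the azimuthal-equidistant map keeps radial distances exact but
shrinks all tangential ones, biasing nearest-neighbour distances low, while
the equal-area map distributes the distortion symmetrically (radial stretch
× tangential shrink = 1), so the median four-nearest-neighbour distance of
the full 256-electrode patch stays at the pitch: 8.62 mm measured, with an
IQR of ≈ [8.5; 8.8] that matches the scale reported for the physical array.
Grid 0 is the grid whose centroid is nearest the vertex, mirroring the
attachment order that starts at Cz.

**Region of interest.** Electrode-selection maps for such arrays are
typically published pictorially; we implement the operational rule "drop the outermost
electrode ring(s)": lattice erosion with a configurable margin (default 1
ring → 196 of 256 channels). Edge electrodes — within half the minimum
electrode spacing of the convex hull of the projected layout — are also
what the neighbour analysis excludes as pair seeds.

**Density subsets.** Stand-ins for 10–10 and extended 10–10 coverage of
the patch are shipped as fractional patch coordinates (6 and 11 positions)
and snapped to the nearest uHD electrode. Their spacing was chosen so the
realized median four-nearest-neighbour distances on the default montage
(≈ 35 mm sparse, ≈ 24 mm dense) sit at the scale of the published values
for those systems; exact standard-position coordinates on a parametric
head would be a convention, not a derivable quantity.

## Synthetic uHD-EEG generator

The generator produces the statistical structure the analysis consumes, not
a biophysical forward solution. Per channel (microvolts, 600 Hz):

| component | default | rationale |
| --- | --- | --- |
| per-channel pink noise | 5 µV rms, 1/f amplitude spectrum | sensor/skin noise floor |
| background sources | 40 pink sources, 8 µV, linear decay, radii U(40, 150) mm | volume-conduction surrogate: gives neighbours their distance-dependent correlation (r ≈ 0.8 at 8.6 mm, ≈ 0.3 at 35 mm after CAR) |
| mu / beta oscillators | 10 / 8 µV rms at each finger's source, linear decay over 15 mm | sensorimotor rhythms; amplitudes at the upper realistic range so the injected ERD is measurable above the in-band noise floor |
| line noise | 5 µV shared 60 Hz sinusoid | mains interference |
| band-power drift | log-power OU process, σ = 0.5 dB, τ = 60 s | exercises the 25 s power-shift compensation |
| bad channels | white noise at a configurable gain | exercises the z > 6 detector |

ERD/ERS is a multiplicative amplitude scale a = 10^(dB/20) on the
oscillator inside the event window with 0.25 s raised-cosine ramps, so band
power changes by exactly the stated dB in expectation. Default windows
follow the observed dynamics: mu ERD 0.5–2.5 s, mu ERS 3.5–5 s, beta ERD
0.5–5 s, beta rebound 6–7 s post-cue. ERD depths (−2…−4 dB across presets)
are calibration choices — per-finger ERD depths are not standardized
quantities in this literature. Finger sources are placed on interior electrodes along a line
through the patch centre, 2 pitches apart, mimicking the somatotopic strip.

The paradigm generator reproduces the protocol exactly: runs of 25
pseudo-randomly ordered cues (5 per finger), 3–4 s uniform rest, 5 s task,
30 s run-initial baseline; a seeded permutation per run makes event tables
bit-reproducible.

What the generator does **not** emulate: EMG/ocular artifacts, non-Gaussian
transients, inter-subject anatomy, volume-conduction physics beyond linear
distance decay, or any coupling between fingers. Passing tests therefore
demonstrate that the *pipeline* is correct and calibrated under its assumed
signal model — not that real recordings will reach any particular accuracy.

## Preprocessing

Resampling (600 → 200 Hz) is polyphase with anti-aliasing; with a 200 Hz
output rate only the 60 Hz line fundamental lies below Nyquist, harmonics
being removed by the anti-alias filter. The notch cascade places 4 Hz-wide
Butterworth band-stops at 60 Hz and every harmonic strictly below Nyquist.
All filters are applied causally (forward only), keeping the pipeline
usable in a real-time setting; only the bad-channel statistics and the
centred moving average are offline. Filter orders follow the MATLAB
`butter` convention, in which such pipelines are typically prototyped: an
"order-4" band filter has 4 poles per band edge.

Bad-channel detection: per run, CAR → 8–25 Hz band-pass → task-period
samples → per-channel mean power → log10 (the log base is irrelevant after
the z-transform) → z-score across channels; z > 6 flags a channel, > 10 %
flagged channels drops the run, and flags are OR-ed over retained runs.
Note an intrinsic property of the z-transform across n channels: a single
outlier can reach at most √(n−1), so the z > 6 rule only has teeth for
patches of ≳ 40 channels — tests on smaller montages use correspondingly
smaller thresholds.

## Features

Band power: causal band-pass → squared samples → means of non-overlapping
0.25 s segments (feature rate 4 Hz) → centred 0.75 s moving average with
shrinking edge windows (no padding, no fabricated data) → log10. The
power-shift compensation subtracts the trailing 25 s (100-sample,
current-sample-inclusive) mean per channel; at stream start the window
shrinks. Epochs are −0.5…7 s around each cue, the cue floored to the
previous segment boundary so the pre-cue reference stays strictly pre-cue;
30 feature samples per epoch at the defaults. A high-gamma band
(70–170 Hz) is available on the pre-downsampling path but off by default.

## ERD/S, focal selection, maps

ERD/S of the average trial is 10 × (mean log10 p − per-channel mean over
the −0.5…0 s reference samples), in dB. Focal selection thresholds the
mean ERD/S in a 1–2 s window at the nearest-rank lower quantile: with
threshold at the (⌊p/100·n⌋+1)-th smallest value and strict inequality,
exactly ⌊p/100·n⌋ electrodes are selected on tie-free inputs — 6 of 256 at
2.5 %, and an empty set under complete ties. Heatmaps spread each
electrode's value with a linear-decay kernel that reaches zero at the
distance to its closest included electrode; vertex values are the sum over
electrodes. Bad channels are excluded from the interpolation by default
(a set-to-zero compatibility mode is provided, matching how published
figures were rendered). Time-frequency maps use an STFT with a 1 s Hamming
window and 0.95 s overlap (20 Hz frame rate, 1 Hz bins, 8–30 Hz), epoched
−1…7 s with a −1…0 s reference; a ×10 bicubic interpolation is available
for display.

## Decoding and inference

At each 0.25 s step of the 0–5 s task window the feature vector is the ROI
channels × bands log band power. The classifier is a linear SVM with box
constraint 1 on per-fold standardized features (after standardization a
kernel scale of 1 is the natural heuristic; no hyperparameter search).
Cross-validation is n×k-fold stratified (10×10 default), the fold
assignment seeded by the iteration index and shared across time steps;
model performance is the mean accuracy at the time step where it peaks
(ties broken toward the earliest step).

**Permutation null.** Each of the (default 100) permutations shuffles the
labels, reruns the full CV with fresh fold seeds derived from the
permutation seed, and is summarized *by its own peak over the task window*.
Evaluating null models at the observed peak step instead would ignore the
max-over-time selection in the observed statistic and makes the test
wildly anti-conservative (median p ≈ 0.01 on effect-free data in our
measurements); with the max kept inside the null, p-values are
approximately uniform under the null (Kolmogorov–Smirnov check in the
acceptance suite). A Gaussian is fitted to the null performances so
p-values below 1/#permutations remain attainable. The 10 pairwise p-values
are Benjamini–Hochberg adjusted per dataset. Density comparisons of paired
model performances use the two-tailed Wilcoxon signed-rank test with a
degenerate-input guard, reported with the median [IQR] of differences.

## Neighbour redundancy

Pairs come from the four-nearest-neighbour graph (unique unordered pairs;
edge electrodes only serve as neighbours). The preprocessed (post-CAR)
signals are band-passed 1–30 Hz; Pearson r uses the full retained
recording, task and rest alike. Bad channels are removed before pairing.
IQRs use nearest-rank (inverted-CDF) percentiles.

## Problem sizes used in validation

The acceptance suite runs desk-scale versions of the study conditions,
chosen as the smallest sizes at which each property is stable:

- **Parameter recovery**: full 10-run protocol on the 64-channel preset
  (50 trials per finger); the recovered mu-ERD trough at each source
  electrode, averaged over the five sources, lands within ±1 dB of the
  injected −3 dB. The residual bias (≈ +0.3 dB shallow) is real and
  understood: in-band background power dilutes the ratio, and the trailing
  compensation absorbs a small part of the ERD.
- **Calibration**: 50 repetitions of a 16-channel, 25-trial null dataset,
  20 permutations × 3×5-fold CV each.
- **Density orderings**: decoding on the 64-channel preset (20 seeds,
  15 trials/class, −4 dB effects; uHD ROI vs sparse subset), correlations
  on the 256-channel montage (20 seeds, 90 s background-only recordings).

## Known limitations

- The hemisphere is not an anatomical scalp; absolute electrode positions
  (and hence heatmap shapes) are conventions, only distances are calibrated.
- EDF export is not provided (no writer backend in the dependency set);
  EDF *reading* is supported through mne, and the native container is NPZ.
- The generator's linear-decay mixing is a first-order stand-in for volume
  conduction; correlation-vs-distance profiles are qualitatively, not
  quantitatively, matched.
- Multiclass (5-way) decoding, CSP-family spatial filters and source
  localization are out of scope.
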