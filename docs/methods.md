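# Methods

`gaitdecode` re-implements a single-trial EEG decoding pipeline for gait
speed changes during treadmill walking, together with a synthetic-EEG
generator that emulates the underlying experiment well enough that every
stage — forward modelling, artifact rejection, feature extraction,
classification and evaluation — can be verified end to end without any
recorded data.

## The experiment being emulated

A subject walks on a treadmill whose belt follows the subject: a linear
encoder measures the subject's speed, and when it deviates from the belt
plateau by more than ±0.12 m/s the belt steps by 1 km/h (4 s acceleration
ramps, 8 s deceleration ramps). One session lasts 380 s and steps through
speeds 0-1-2-1-2-1 km/h three times before a final rest block (19 blocks of
20 s when visually cued). Each subject performs 10 sessions, 7 cued and 3
self-paced (uncued), the uncued ones interleaved after every 2–3 cued
sessions. The decoding task is binary: *change-speed* (an 8 s window centred
on the detected speed-change onset) versus *constant-speed* (the preceding
[−12, −4) s of steady walking), 18 balanced trial pairs per cued session.

## Decoding pipeline

1. **Preprocessing** — Hamming-window zero-phase FIR band-pass 1–45 Hz with
   the automatic-order heuristic (per-edge transition bandwidth
   `min(max(0.25·edge, 2 Hz), distance to 0/Nyquist)`, overall minimum;
   length `ceil(3.3·fs/tb)` rounded up to even, plus one). At 2048 Hz this
   gives 6761 taps with −6 dB cutoffs at 0.5/45.5 Hz; the 8–40 Hz design at
   256 Hz gives 425 taps with cutoffs 7/41 Hz. The signal is then polyphase
   resampled to 256 Hz.
2. **Spatial filters** — two-pass ICA per cross-validation fold, fitted on
   the nine training sessions only. The signal is cut into 0.5 s segments;
   segments whose joint log-probability under per-channel histogram
   densities (50 bins) deviates more than 5 SD from the mean segment score
   are dropped. ICA pass 1 runs on the cleaned broadband data; the same
   probability criterion is then applied to the component activations, the
   surviving segments are band-passed 8–40 Hz, and pass 2 yields the final
   unmixing.
3. **Component screening** — one equivalent current dipole is fitted to each
   component scalp map in a 4-shell spherical head model (radii
   71/72/79/85 mm, conductivities 0.33/1.0/0.0042/0.33 S/m). Components are
   rejected when residual variance > 10 %, radial fraction > 70 % of the
   scalp radius, or dipole z < 0 mm, plus a two-criterion ocular detector
   (frontal map dominance and blink-like temporal statistics).
4. **Features** — windowed complex Morlet decomposition: 107-sample windows,
   50 centres over an 8 s epoch (−3.789…+3.789 s), 20 log-spaced
   frequencies 8–40 Hz, cycle counts 3→7.5, squared magnitude, floored,
   10·log10. Sparse (L1) logistic regression over all candidate components'
   features ranks components by selected-feature count; the scree-test
   acceleration factor (second difference of the sorted counts) places the
   elbow and components ranked strictly before it are retained (≥ 1).
   Epochs whose 20–40 Hz perturbation against the training constant-speed
   baseline exceeds +25 dB or −100 dB in any window are discarded.
5. **Classifier** — PCA on training features to the smallest dimension with
   ≥ 90 % variance, then L1 logistic regression (strength chosen by internal
   stratified 5-fold CV on the standardised training set). Decision:
   change-speed iff P > 0.5.
6. **Evaluation** — leave-one-session-out confusion matrices are summed;
   class-wise normalised accuracy (mean ± SD of the diagonal), Cohen's
   kappa, and the adjusted-Wald lower confidence bound

   k_l = k̂ − z·sqrt( p̂(1−p̂) / ((N+4)(1−p0)²) ),  p̂ = (C+2)/(N+4)

   (square root over the whole N+4 term; z = 1.96). Cued/uncued pooled
   kappas are compared by paired t-test across subjects; subclass kappas
   (0→1, 1→2, 2→1, 1→0 vs their preceding constant speed) and a pre-onset
   variant (windows wholly before onset, classifier refitted per fold) are
   also reported.
7. **Pseudo-online** — 2 s sliding epochs: 4 jittered training windows per
   class per trial (change centres 0…1.5 s step 0.5; constant −10…−7 s step
   1), 9 test epochs per trial (change −1…3 s, constant −9…−5 s, step 0.5),
   a 20 × 14 time–frequency grid spanning ±0.79 s. Each fold reuses the
   batch fold's unmixing and retained components. Trials are scored
   all-or-nothing (maximum of the m-epoch moving average of the 9 output
   probabilities, m ∈ {1, 2, 3}) and summarised by ROC/AUC and by the
   median/quartile output per time bin.

## Head model

The forward solution for a dipole inside concentric conducting shells is the
classical Legendre series. Per degree n the seven unknown expansion
coefficients follow from potential/current continuity at the three
interfaces and an insulating scalp boundary; because the system is linear in
the source term, one transfer coefficient per degree is precomputed per head
model, and a forward evaluation is a vectorised series sum over at most 100
degrees with a geometric early stop (relative tolerance 1e-12). The default
truncation is higher than strictly needed for deep sources so that sources
near the brain-shell boundary (the simulated ocular and neck-muscle dipoles,
at ~0.85 of the brain radius) still converge.

Correctness is anchored by an independent oracle: for equal conductivities
the series must reduce to the homogeneous-sphere surface potential, which we
derived in closed form from Legendre generating-function identities
(elementary functions of the source depth and the source–electrode angle; no
series). Agreement is at the 1e-12 level, far inside the 1e-6 oracle
tolerance.

The inverse fit searches over the source location with multi-start
Nelder–Mead (moment solved linearly per location; residual variance = the
unexplained fraction of mean-removed map variance). The search is bounded at
0.97 of the brain-shell radius because the series representation is only
valid for sources in the innermost compartment. One consequence: fitted
radial fractions cannot exceed ≈ 0.82, so the retained-vs-rejected QC
pairing (which, with unconstrained fitters, pools rejected dipoles at > 90 %
of the sphere radius) uses the 70 % rejection radius as its pool threshold
at the pipeline level; the underlying function keeps the looser default for
use with externally supplied fits.

The montage is an idealised spherical 64-channel layout in the standard
Biosemi ordering (Fp1, AF7, AF3, … O2), built from the standard template
positions, projected exactly onto the 85 mm scalp sphere and left/right
symmetrised; it ships as a TSV data file. Head frame: +x anterior, +y left,
+z superior.

## Synthetic data: what it emulates, and what it does not

Every source is a dipole forward-projected through the same head model the
analysis uses:

* **Parietal ERD source** at (−34.5, 7.7, 42.1) mm (55 mm radius, the
  posterior-parietal territory), mu (8–15 Hz) and beta (16–31 Hz)
  band-noise carriers whose power drops by 3 dB and 1.5 dB respectively
  over 0–2 s after each detected onset (raised-cosine 0.5 s edges).
* **Motor source** at (−25, −24, 46) mm with a weaker (1 dB) drop, present
  by default (configurable off, mirroring that it appeared in only part of
  the real cohort).
* **Background** — five 1/f (pink) sources at random interior locations.
* **Artifacts** — a blink source (frontal-inferior dipole, exponential
  inter-blink intervals, stereotyped pulses), two neck-EMG sources
  (high-passed noise with burst envelopes while walking), and a step-locked
  source (5 harmonics of the stepping fundamental, 0.75 Hz at 1 km/h to
  0.95 Hz at 2 km/h, active only when the belt moves).
* **Sensor noise** — white Gaussian per channel.

Oscillatory carriers wax and wane under a slow positive envelope. Background
sources are strongly modulated (depth 0.6, 0.25 Hz low-pass), which is also
what makes them identifiable to ICA; cortical carriers use a mild modulation
(depth 0.15, 0.4 Hz). Heavier cortical modulation is more naturalistic but
drowns the 3 dB desynchronisation in trial-to-trial band-power variability;
the chosen value leaves a single-trial effect comparable to what the real
study's accuracies imply. Uncued sessions draw plateau durations from the
published goniometer statistics (mean 17.4 s / SD 5.35 after acceleration,
12.8 s / SD 6.51 after deceleration, floored at 6 s, truncated at 380 s),
which reproduces the reported ~16 usable trials per class via the
12 s-preceding-steady rule.

All generator magnitudes (nA·m amplitudes, noise SD) are free parameters —
the study reports no SNR — held in `GeneratorConfig`. The sensor-noise and
amplitude defaults are set so that the default cohort's cross-validated
accuracy lands in the 70–85 % range the real study reports; this calibration
is part of the generator's definition, not a per-run adjustment.

Not emulated: biomechanics (the gait artifact is a harmonic caricature),
visual cues (cued/uncued differ only in block-duration statistics, so the
cue-invariance comparison is exercised but trivially satisfied),
inter-subject anatomical variability, electrode impedance drift, and
non-stationarities across sessions beyond fresh noise realisations. Passing
tests therefore demonstrate that the pipeline recovers what the generator
implants under realistic interference — not that it would reach the same
numbers on new human recordings.

## Problem sizes and numerical choices

* Default cohort: 2 subjects × 10 sessions × 380 s, generated at 512 Hz
  (the band of interest ends at 45 Hz; `simulate_recording` itself defaults
  to the hardware's 2048 Hz) and analysed at 256 Hz.
* ICA: 16 components (PCA-whitened via the covariance eigendecomposition),
  fitted on every 6th clean sample of the concatenated training sessions,
  FastICA contrast with tolerance 1e-4 and at most 150 iterations per pass.
  With partly Gaussian background subspaces the contrast cannot fully
  converge in the rotation-free subspace; the separating directions of the
  non-Gaussian sources stabilise long before the cap. Runs are deterministic
  given the seed.
* Dipole fits: 4 restarts from random directions at 60 % of the scalp
  radius, Nelder–Mead with 1e-8 residual-variance tolerance and 0.01 mm
  location tolerance; the search uses a 1e-9 series tolerance and the
  returned fit is re-evaluated at full precision. Noise-free maps are
  recovered to well under 0.1 mm.
* Segment probability score: 50-bin histograms per channel; "5 SD" applied
  two-sidedly to the segment score distribution.
* Wavelet power floor 1e-20 before the dB transform. Window centres are the
  50 (or 14) rounded evenly spaced positions between the first and last
  valid centre, which reproduces the printed −3789…+3789 ms grid for 8 s
  epochs; cycle counts interpolate linearly 3→7.5 across the 20 log-spaced
  bins.
* Scree elbow: retain sorted ranks strictly before the maximal second
  difference, minimum one component; flat profiles retain everything.
* k-means outlier rule: a member is dropped when its distance to the
  centroid exceeds the leave-one-out mean + 5 SD of its cluster's distances
  (leave-one-out so an extreme member cannot mask itself); centroids refit
  once.
* Eye detector thresholds (frontal dominance factor 2.0, < 4 Hz power
  fraction 0.55, excess kurtosis 10) are calibrated on the generator's blink
  and cortical sources.

## Known limitations

* The dipole search cannot place sources outside the brain shell, so truly
  extracranial generators are represented by their best intracranial
  equivalent (they are still rejected by the radius/z/eye rules).
* The Hamming-window FIR leaves ≈ −70 dB of DC leakage (inherent to the
  window choice); relevant only for signals with enormous offsets.
* The pseudo-online path is an offline emulation with zero-phase filters; a
  true real-time system would need causal filtering and would incur group
  delay.
* The paired cued/uncued t-test across two synthetic subjects has almost no
  power; it is reported for completeness and exercised properly only in the
  statistics unit tests.
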