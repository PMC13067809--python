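# Methods

This note documents the models, numerical choices and limitations behind
`epibench`. It is the place to look when a default needs justifying or a
behavior at a degenerate input needs explaining.

## Synthetic cohort model

Each participant is a `BeatTemplate`: five Gaussian components (P, Q, R,
S, T) with amplitude (mV), center (s, R at 0) and width (s), plus a mean
RR interval and its SD. Parameters are drawn from truncated-normal
cohort priors (`synthetic.COHORT_PRIORS`); the analytic truncated means
are exposed (`truncated_prior_mean`) so Monte-Carlo tests have a
closed-form oracle. The priors emulate a seated resting adult cohort:
R ≈ 1.10 ± 0.10 mV, T ≈ 0.30 ± 0.05 mV, heart rate ≈ 50–66 bpm. Template
invariants (ordered centers, positive widths, RR longer than twice the
P-to-T span) are enforced at construction.

RR variability is i.i.d. Gaussian per interval, truncated at ±3 SD — no
respiratory sinus arrhythmia model, which is adequate for alignment and
clustering but not for HRV studies.

**Leads.** The three leads share a participant's template through
per-lead diagonal gains on the five wave amplitudes
(`DEFAULT_LEAD_GAINS`). The gain vectors are deliberately
*non-proportional*: lead II is R-dominant, lead I has a small QRS with
accented P and T, lead III a deep S and inverted T. Two considerations
fixed these values. First, real chest montages differ between leads in
waveform shape, not just scale. Second, the lead-identification recovery
property constrains the geometry: the restart-selection rule for k-means
(maximize the sum of squared pairwise centroid distances, see below)
will happily prefer a partition that splits one lead's cluster along its
internal amplitude axis and merges two other leads whenever the leads'
mean beats are nearly collinear with the inter-participant amplitude
axis. With near-proportional gain vectors the lead partition is
recoverable by nearest-lead-mean assignment yet *not* selected by the
spread rule. The shipped gains make the three lead centroids angularly
separated so that the true partition also maximizes centroid spread; a
template-level margin analysis (true-partition spread vs the best
single-lead split) exceeds 1 across cohort draws, and full-pipeline lead
identification recovers the ground truth with accuracy ≥ 0.98 across
seeds at the default noise level.

**Noise.** `NoiseSpec` defaults: 0.15 mV baseline wander at 0.25 Hz,
0.05 mV at 50 Hz and 0.02 mV at 80 Hz (the 80 Hz component is injected
as an independent sinusoid, not phase-locked to 50 Hz), 0.03 mV
broadband white noise, 2 motion bursts/min (Hann-windowed lumps, 0.5 mV,
1 s). These are configuration representing a moderately noisy resting
recording, not measurements of any device.

**Electrode transfer.** A first-order low-pass (single pole at
`lp_cutoff`) plus two dimensionless gains scaling, respectively,
broadband/mains pickup (`noise_gain`) and drift/artifacts
(`drift_gain`). The hydrogel-like default (45 Hz, 0.6, 0.5) and
Ag/AgCl-like default (95 Hz, 1.0, 1.0) encode the qualitative contrast
of a capacitive, conformal interface versus a faradaic gel interface —
low-pass filtering, less pickup, less drift. No quantitative electrode
noise model is claimed; only orderings (e.g. hydrogel SNR above Ag/AgCl
at equal injected noise) are asserted in tests. The `ideal` electrode is
the identity with zero gains, so a zero-noise ideal recording *is* the
clean template train.

**AC coupling.** The clean beat train is mean-subtracted per lead before
noise is added, modelling an AC-coupled front end. A sum of positive and
negative Gaussians carries a net DC offset of order 10% of the R
amplitude; without AC coupling that offset would be removed by the
baseline filter during preprocessing and the clean-signal identity
(preprocessing changes a noiseless recording by < 1% of the R amplitude)
could not hold.

**Equivalent-circuit EIS.** Z(ω) = R_s + R_ct/(1 + jωR_ctC_dl), the
single-time-constant randles-style cell without Warburg diffusion. Its
−Z″ apex sits analytically at f = 1/(2πR_ctC_dl), making it the oracle
for relaxation-time recovery.

## Preprocessing chains

All IIR filters are Butterworth, applied forward–backward
(`sosfiltfilt`), i.e. zero phase: group delay would bias landmark and
similarity measurements downstream, so the stated pass/stop figures
refer to the squared magnitude response. Chains are length-preserving
and deterministic.

* **ECG**: order-4 low-pass at 90 Hz → order-2 band-stop notches at
  50 and 80 Hz (±1 Hz half-bandwidth realizes "narrow-band") → trailing
  ("lookback") 1-s moving-average baseline subtracted → variance-based
  segment rejection. Every step can be applied in isolation for
  band-power-ratio analyses, and the full chain is exactly the
  composition of the isolated steps.
* **EOG**: order-4 band-pass 0.1–15 Hz → mean subtraction → linear
  detrend → db4 level-3 wavelet denoising → 50 ms median filter
  (kernel rounded to an odd sample count). The 0.1 Hz edge rings for
  tens of seconds; the band-pass therefore uses an extended reflection
  pad (≈3/f_lo seconds) so the edge transient stays out of the record.
  Residual edge effects still dominate short records — attenuation
  figures are quoted on ≥60 s inputs.
* **EMG**: band-pass 20–90 Hz → 50 Hz notch → amplitude-scaled cardiac
  template subtraction (template = mean of ±150 ms windows around the
  supplied R times; per-beat least-squares scale) → db4 wavelet
  denoising. With fewer than three R times the template step is skipped
  with a warning.
* **EEG**: linear detrend → order-4 low-pass at 49 Hz (the order matches
  the ECG chain's convention; only the cutoff is protocol).

**Wavelet denoising** uses soft thresholding with the universal rule per
detail level, σ estimated by MAD/0.6745 within each level. Empirically
(and asserted in tests) neither wavelet thresholding nor median
filtering increases signal energy on zero-mean inputs.

**Segment rejection** computes the log-variance of non-overlapping 2-s
windows and rejects windows whose robust z-score (median/MAD, consistent
with a normal scale) exceeds 5, per channel, reason-coded `variance`. A
robust score is used because the plain mean/SD z-score is inflated by
the very outlier windows the rule exists to catch. The impedance rule
runs only when an impedance series is supplied (synthetic data has
none); otherwise it is skipped and logged. Numeric thresholds are
configuration with these defaults.

## Heartbeat extraction

R-peak detection follows the classic Pan–Tompkins stages: band-pass
5–15 Hz, five-point derivative, squaring, 150 ms moving-window
integration, running signal/noise threshold (SPKI/NPKI with the 0.125
update and threshold NPKI + 0.25·(SPKI − NPKI)), followed by snapping
each detection to the local absolute extremum of the input within
±40 ms. A 200 ms refractory period is enforced both at candidate-peak
spacing and after refinement (larger peak wins).

Beats are 121-sample windows with the R sample at the center (offset
60): inter-beat variability is then expressed bilaterally around the
alignment anchor. Windows crossing record edges, or touching rejected
segments when a mask is supplied (rejection happens *before* batching),
are dropped and counted. Multiple recordings of one participant are
pooled at the beat level (`concatenate_beats`).

## Identification pipeline

PCA retains the smallest number of components whose cumulative explained
variance reaches the target (0.99), which lands at roughly 10–20
components for these beats. Reconstruction error is bounded by the
discarded variance, which the tests assert directly.

k-means runs `restarts = 5` times for up to `iters = 1000` Lloyd
iterations; among restarts the result maximizing the sum of squared
pairwise centroid distances is kept. That selection rule is part of the
documented protocol; it is worth knowing that it favors spread-out
centroids rather than low inertia, with the geometric consequences
described under *Leads* above. Initialization is k-means++ seeding by
default: with plain uniform choice of data points, a restart that lands
two seeds inside one well-separated mode can never move a centroid
across empty space, and five restarts then leave a material chance
(roughly 30% for three equal blobs) that no restart finds the true
partition at all. `init="random"` remains available.

Cluster-to-class assignment minimizes a cost matrix of negated
co-occurrence counts via the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`). Because counts are integers,
ties between assignments are real; they are broken deterministically by
choosing the lexicographically smallest optimal assignment in
(cluster index, class index) order, so the lowest-indexed cluster keeps
the lowest-indexed of its equally good classes. Tests verify equivalence
with exhaustive enumeration for up to 6 classes. With more clusters than
classes the mapping is partial and unmapped clusters score as errors.

Metrics: accuracy A/N; micro-F1 = 2A/(N+A) (algebraically
2·acc/(1+acc), asserted as a property); macro-F1 as the mean over
classes of 2·TP_c/(N + TP_c) with the *global* N — this is the per-class
micro form, and it collapses toward the micro value instead of averaging
conventional class F1 scores (≈0.5 for a perfect 3-class result). It is
implemented verbatim because it is the documented formula; a standard
precision/recall macro-F1 is exposed behind `standard_macro=True`
without guessing which was intended.

t-SNE (perplexity 30, Euclidean metric, PCA initialization, seeded) is
visualization-only and excluded from any quantitative claim.

Participant identification runs independently per lead with K equal to
the participants present; lead identification pools all beats with
K = 3. On the synthetic cohort at default settings, lead identification
recovers ground truth at ≥0.98 accuracy and participant identification
reaches ≈0.30–0.44 per lead — roughly 12–17× the 1/39 chance level.
Passing these recovery tests shows the pipeline extracts the structure
the generator encodes; it does not certify performance on real
recordings, whose inter-lead redundancy and intra-participant
variability are larger and messier than the diagonal-gain model.

## Morphology and similarity

Amplitudes are referenced to the Q-point *value* (reading "distance from
the Q wave" as a voltage difference — a temporal distance would not be
an amplitude): P amplitude is the magnitude of the largest deflection
from the Q level before Q, T amplitude the same after S, so inverted
waves give positive amplitudes. On centroid beats, which carry no
detector annotations, Q and S are the minima within 60 ms before/after
the R sample. An empty pre-Q or post-S segment raises instead of
silently reporting zero.

ρ_max is the maximum over all lags (±(N−1), zero-padded outside the
overlap) of the cross-correlation normalized by the square root of the
product of the two beats' total energies — symmetric up to lag sign and
invariant to positive rescaling. NRMSE divides the RMS error by the
combined range max(b₁, b₂) − min(b₁, b₂); two identical constant beats
return 0 with a warning.

## Spectral quality

Welch PSDs use 2-s Hamming windows with 50% overlap (one-sided,
Parseval-consistent within the tested 5%). Band power is the
trapezoidal integral of the PSD over the band. Processed-to-raw
band-power ratios default to a 20-s Welch window so the lowest
(0.05–0.5 Hz motion) band has enough resolution; default band edges are
{motion 0.05–0.5, LF 0.5–4, MF 4–15, HF 15–40, UHF1 40–60, UHF2
60–90 Hz} and are configuration. A band with zero raw power reports NaN
with a warning. Time-resolved delta power uses 2-s windows at 0.5-s
steps (periodogram per window, 0.5–4 Hz integral, timestamps at window
centers). The scalogram uses an analytic Morlet (`cmor1.5-1.0`) with 12
voices per octave over 0.5–49 Hz and is visualization output.

The ECG SNR helper takes σ²_signal over the whole (preprocessed)
channel and σ²_noise pooled over the inter-beat windows; windows
crossing record bounds are dropped.

## Dielectric analysis

f_max is located on the raw frequency grid (no interpolation) so the
τ = 1/(2πf_max) identities are exact at grid points; an optional
quadratic refinement in log-frequency exists but is off by default. A
monotone −Z″ (grid not bracketing the relaxation) raises rather than
returning an extrapolated τ.

The permittivity conversion is the standard parallel-plate form
ε\* = 1/(jωC₀Z\*) with ε\* = ε′ − jε″ and M\* = 1/ε\* = M′ + jM″; the
ε\*↔M\* round trip is identity to 10⁻¹⁰ (tested). Geometry defaults to a
1.7 cm diameter, 1.5 mm thick disc with a warning when used, since
published electrode dimensions are often nominal and inconsistent
between figure captions and fabrication sections.

One physical subtlety: for the single-time-constant circuit the loss
tangent tan δ = Z′/(−Z″) is *monotone* when R_s = 0 and has no peak at
the relaxation frequency; the dielectric-side marker of the relaxation
is the M″ peak, which coincides with the −Z″ apex for the
series-resistance-corrected interface. The consistency check between
impedance- and dielectric-side relaxation estimates therefore uses M″,
not tan δ (`modulus_peak_frequency`).

Nyquist utilities compute per-frequency mean ± SD over replicate spectra
(triplicates in practice) and smooth the mean curve with a centered
moving average; the SD is reported unsmoothed.

## Problem sizes and determinism

The cohort-level recovery checks run at 39 participants × 3 leads × 60 s
at 200 Hz — a size chosen so the full pipeline (synthesis through
clustering) completes in well under a minute while keeping ≥ 2000 beats
per lead, enough for the 99%-variance PCA and K = 39 clustering to be
meaningful. All stochastic stages (template draws, noise, k-means
restarts, t-SNE) are driven by explicit seeds; identical seeds give
bit-identical outputs, which the tests and the experiment drivers'
byte-identical reports rely on.

## Known limitations

* No torso/dipole physiology: leads are diagonal gain projections, so
  inter-lead correlation structure is simpler than reality.
* No pathological rhythms, ectopy or QT/PR delineation.
* The electrode model is a single pole plus two gains — it reproduces
  orderings, not measured spectra.
* EOG/EMG/EEG generators are not modality-specific; tests construct
  those signals directly (tones, squares, bursts).
* The variance-based SNR depends strongly on the noise-window
  convention; values are comparable within this package, not across
  estimators.
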