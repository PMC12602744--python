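# Methods

This note documents the models, estimators, defaults and numerical
choices behind `vocalmarkers`, and what the synthetic-data tests do and
do not establish about real clinical recordings.

## Synthetic voice model

The generator produces a quasi-periodic train of smooth unipolar
glottal pulses. Each pulse is Rosenberg-style: a raised-cosine opening
phase of 0.40·T₀ followed by a cosine closing phase of 0.05·T₀. The
closure is continuous but abrupt, which matters: it supplies the
high-frequency source energy a real glottal flow has, so formant
filtering, cepstral analysis and LPC behave realistically. A symmetric
smooth burst was tried first and leaves the upper formants essentially
unexcited (its spectrum falls off roughly as f⁻³), making F3/F4
unrecoverable by any method.

Perturbations follow the cycle-to-cycle definition of jitter and
shimmer: periods are `Tᵢ = T₀(1 + εᵢ)` and pulse amplitudes
`Aᵢ = A₀(1 + ηᵢ)` with εᵢ, ηᵢ i.i.d. zero-mean Gaussian truncated at
±3σ. The spec parameters `jitter_rel` and `shimmer_rel` are calibrated
to the quantity the downstream extractors estimate — the expected mean
absolute consecutive relative difference. For i.i.d. Gaussian ε that
expectation is 2σ/√π, so the generator draws with σ = target·√π/2.
Noise is Gaussian, low-passed at 0.9 of Nyquist, and scaled after all
filtering so that the AC power ratio of the stored clean and noise
components equals the requested HNR exactly (the DC offset of the
unipolar pulse train carries no voice energy and is excluded from the
harmonic power on both the generator and analyzer sides).

Vowels are produced by cascading second-order all-pole resonators
(unity gain at resonance) at preset adult formant values for
/a,e,i,o,u/; speech-like items are three short vowel segments separated
by 100 ms silences — enough to exercise voiced-region segmentation
without any pretension of phonemic content. Every generator is a pure
function of its spec including the seed, and returns a ground-truth
sidecar (exact pulse times and amplitudes, separate clean and noise
components) so that no oracle ever depends on the pitch tracker under
test. On disk, recordings are 16-bit PCM WAV at 44.1 kHz in
`<root>/<subject>/<content>_<k>.wav` layout with a JSON sidecar per
file, matching the acquisition protocol the pipeline targets.

What the generator does *not* model: disease-specific articulatory
dynamics, breath groups, tremor, diplophonia, microphone/room effects,
or any claim about how Parkinsonian or MS voices actually sound. A
passing recovery test shows the estimator chain is correct on signals
that satisfy the perturbation model, not that it is clinically
validated.

## Cycle tracking and formants

Pitch/cycle analysis is two-stage. A coarse track computes the
normalized autocorrelation of 40 ms frames (hop 20 ms); the unbiased
lag normalization would favour octave-down errors, so the shortest lag
within 10% of the best peak is taken, then refined parabolically.
Frames whose peak falls below 0.45 are unvoiced. Within each voiced
region, cycle peaks are walked forward and backward from an anchor with
the search window constrained to ±30% of the locally adapted period; a
running amplitude reference (candidates below 0.2× are rejected) stops
the walk at region edges instead of latching onto silence or noise.
Peak instants are refined by parabolic interpolation, periods are their
successive differences, and per-cycle amplitudes are peak-to-peak
values in a one-period window centred on each peak. Fewer than five
cycles, or a mean F0 outside [f0_min, f0_max] (defaults 60–500 Hz), is
an insufficient-voicing error.

Formants come from order-12 autocorrelation LPC on the signal decimated
to ~11 kHz with 0.97 pre-emphasis and a Hamming window over the whole
phonation. Resonance candidates are complex pole angles; poles with
bandwidth under 400 Hz are trusted anywhere in (1.2·F0, Nyquist−50),
and broader poles (up to 700 Hz) are accepted only above the highest
sharp resonance, where source rolloff blurs the LPC bandwidth estimate.
Known limitation: when F1 approaches the harmonic spacing (e.g. /i/
with F1 ≈ 270 Hz at F0 ≳ 160 Hz) no spectral-envelope method can
resolve it reliably; estimates there drift toward the nearest harmonic.

HNR is estimated by cycle-synchronous averaging: one-period segments
centred on each detected peak, integer-shift realignment to the running
template (three passes, ±8 samples — detected peaks carry ±1 sample of
timing noise that would otherwise leak harmonic energy into the
residual), template = harmonic estimate, per-cycle residuals = noise.
The ratio is clipped to [−20, 40] dB; a noiseless train reports the
40 dB ceiling.

## Perturbation formulas, as printed vs classical

The jitter and shimmer metrics are implemented exactly as the study
prints them, idiosyncrasies included, because reproducing the reported
values is the point:

* Ja carries a 1/N prefactor over the N−1 consecutive differences;
  Jr, RAP and PPQ5 divide by (1/N)·(sum of the first N−1 periods);
  DDP is the same sum as Ja with a 1/(N−1) prefactor (so DDP = Ja·N/(N−1),
  not the classical difference-of-differences).
* SdB is a signed mean of 20·log₁₀(Aᵢ₊₁/Aᵢ) terms; it telescopes to
  (20/(N−1))·log₁₀(A_N/A₁) and can be negative.
* APQn compares each amplitude with the mean of its n−1 neighbours
  (k ∈ [−n/2, n/2] excluding 0, edge cycles skipped), keeps the printed
  1/N outer prefactor, and divides by the mean amplitude so the result
  is dimensionless like Sr. Reading the neighbourhood term as a proper
  mean is forced by the requirement that a constant amplitude series
  yield zero for every shimmer metric.
* The printed HNR ratio is inverted relative to its name; the standard
  orientation (harmonic over noise) is used and the discrepancy is
  documented here rather than silently resolved.

Every metric accepts `classical=True`, which switches to textbook
MDVP-style definitions (proper means, absolute dB differences,
neighbourhood including the centre cycle) for cross-checking against
other toolchains. The default is the as-printed form.

## Articulation and cepstral features

tVSA and qVSA are the absolute values of the signed (shoelace)
expressions over the corner vowels — an area must be non-negative and
vertex orientation is not meaningful. Formants are averaged over a
subject's available phonations of each vowel first, and the three
articulation features are broadcast onto all of that subject's records;
subjects with no usable vowel recordings get missing values, handled by
the imputation step.

MFCC uses 2048-sample Hann frames with hop 512 at 44.1 kHz, a 26-filter
triangular Mel bank over [0, Nyquist], log energies and an orthonormal
DCT-II keeping 13 coefficients; the mean and median are taken over the
flattened coefficient-by-frame matrix. CPP per frame is the height of
the cepstral peak — real cepstrum of the dB magnitude spectrum after a
60 Hz zero-phase high-pass and Hann windowing — above a linear
regression trend fitted to the cepstrum over the quefrency band of
plausible pitch periods [1/f0_max, 1/f0_min]; regression-line
normalization is the classic cepstral-peak-prominence convention, and
the band is shared with the pitch tracker. ZCR counts sign changes per
frame (zero samples inherit the non-negative sign, so a crossing
through an exact zero is counted once). The spectral centroid is the
magnitude-weighted mean frequency over Hann-windowed frames — Hann
because rectangular-window leakage otherwise drags the centroid of a
pure tone hundreds of Hz upward; frames with RMS below 10⁻⁶ are
excluded rather than contributing zero.

## Dataset pipeline

Consolidation walks the per-subject folder tree in sorted order, builds
each subject's formant inventory, extracts all 28 features per
recording, and writes one CSV row per recording (UTF-8, header row,
empty cells for missing, floats at 10 significant digits). Individual
extractor failures become missing values with a warning, never a
dropped record. Preprocessing imputes missing cells with column means
and z-scores every feature, estimating both on a designated fitting
subset — the training rows by default, with a `fit_on_all`
compatibility flag for standardize-before-split behaviour; fitting on
the training split only is the correct default because anything else
leaks test statistics into the scaler. A zero-variance column scales
with sd 1 under a warning; an all-missing column is an error naming the
column.

Augmentation operates on waveforms, not feature rows: minority-class
recordings are duplicated with a speed-perturbation factor drawn
uniformly from (0.99, 1.01) — wider ranges are rejected to avoid
deforming the voice — and augmented records are flagged and barred from
the test split, which prevents duplicate-leakage inflation of metrics.
The stratified split takes round-half-up of `test_fraction × N` test
records (reproducing 317/739 from 1056 at 30% and 134/536 from 670 at
20%) with per-class counts by largest remainder, so every class's test
share is within one record of its global share.

## Classification and metrics

The five families run with the study hyperparameters as defaults
(overridable per spec, with an optional exhaustive grid search selected
by 5-fold CV accuracy). Labels are encoded 0..K−1 internally; class 1
(pathological) is the positive class of the binary metrics. MCC is 0
with a flag when any margin factor vanishes; F1 is 0 when
precision + sensitivity is 0. Multiclass metrics are unweighted macro
one-vs-rest averages, accuracy being overall agreement. Values are
additionally reported half-up-rounded to two decimals for comparison
with printed tables. Cross-validation is stratified with shuffled,
seeded fold assignment; pooled metrics are computed from the
concatenated out-of-fold predictions (micro). ROC curves are threshold
sweeps over out-of-fold scores with trapezoidal AUC; constant scores
give 0.5 by the tie convention. Where calibrated probabilities are
unavailable the decision score is used for ranking.

## Explainability

Two value functions realize f_S: retraining the model on each feature
subset (the literal definition; with caching the full enumeration
trains 2^|F| models, practical to ~10 features) and
marginal-expectation masking over a background sample (out-of-coalition
features replaced by background rows and averaged), the default for the
28-feature space. The baseline f_∅ is the mean training prediction
(mean target for the retraining form, mean background score for the
marginal form). Exact enumeration evaluates each subset once and
combines with the combinatorial weights; the efficiency identity
Σφᵢ = f(x) − f_∅ then holds to machine precision and is asserted at
10⁻⁶. Permutation sampling is unbiased, seeded, and reports per-feature
standard errors; fewer than 10 permutations is rejected. Explanations
are computed on the model margin (pre-threshold score), so outputs may
lie outside [0, 1]; a record is oriented "healthy" when its output
falls strictly below the threshold (default: the baseline) and
"pathological" otherwise — ties break toward pathological, the cautious
direction for a screening tool. Global summaries rank features by mean
|φ| and retain signed per-record distributions.

## Problem sizes and test design

Sustained phonations are synthesized at 1–2 s for tests and at 44.1 kHz
throughout; 2 s at 100 Hz gives ~200 cycles, enough that the sampling
error of a mean-absolute-difference perturbation estimate is a few
percent, which is why recovery tests average 20 seeds per condition.
Classifier sanity checks train on a 100+100-record class-conditional
Gaussian table with class means 3 sd apart on 5 designated features
(Bayes error ≪ 1%) and evaluate on an independent 1000-record draw of
the same distribution, large enough that estimator variance cannot
obscure a real failure. Equation-level checks compare vectorized
implementations against literal loop transcriptions at 10⁻¹², and the
vowel-space areas against a generic shoelace oracle at 10⁻⁹ relative.

## Known limitations

* The cycle tracker assumes one dominant positive peak per cycle; it is
  not a robust pitch tracker for running speech in noise, creak, or
  diplophonia.
* Formant estimates degrade when F1 approaches the harmonic spacing
  (high F0 close vowels) and for very close formant pairs.
* Measured jitter/shimmer include a noise-induced component at low HNR;
  recovery tolerances are stated for clean trains.
* Record-level splitting follows the original evaluation design;
  subject-wise (grouped) splitting would be stricter and is deliberately
  not the default, a known caveat when several records share a subject.
* The 28-feature SHAP workflow uses sampled attributions; exact
  enumeration is reserved for ≤ 12 features.
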