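# Methods

`sarcoscreen` re-implements, on synthetic data, a wearable-sensor
screening pipeline for sarcopenia: coupled surface-EMG (sEMG) and
piezoelectric strain recordings from a handgrip protocol, a nine-feature
engineering stage, a three-stream CNN–LSTM fusion classifier, Shapley
attribution, and the AWGS-2019 rule engine that supplies ground-truth
labels. The clinical recordings the design is based on are not publicly
deposited, so the cohort generator is a first-class, tested component:
it defines the statistical structure every downstream claim is tested
against.

## Synthetic cohort generator

**sEMG model.** The sEMG is a superposition of motor-unit action-
potential (MUAP) trains. Each motor unit has:

* a biphasic MUAP kernel — the first derivative of a Gaussian with
  6-sigma time support `muap_duration` (default 10 ms healthy). Its
  power spectrum is `f² · exp(−(2π σ f)²)`, a Maxwell form whose median
  sits near `0.173/σ`; kernel duration is therefore the single knob that
  sets median frequency (MF), making spectral calibration tractable.
* a recruitment threshold drawn uniformly on [0, 0.7] of maximal effort,
  sorted ascending, with MUAP amplitude a monotone function of threshold
  (the size principle).
* a renewal firing process with Gamma inter-pulse intervals
  (mean rate 22 Hz, CV 0.15): physiological regularity without history
  dependence.

**Sarcopenia knobs.** Motor-unit loss with enlargement of survivors:
pool size 60 → 26; MUAP duration × 1.45 (slow-fibre reinnervation →
lower-frequency spectra); per-unit amplitude × 1.3 (expanded innervation
territories); composite amplitude × 0.55 (reduced raw envelope);
a stronger within-hold fatigue drift (below); and a convex effort
ramp `(t/T)²` in place of the linear healthy ramp, modelling slowed
rate of force development. With these frozen defaults the Welch MF of a
simulated maximal contraction averages ≈ 101 Hz (healthy) vs ≈ 70 Hz
(sarcopenic), inside the 90–120 / 65–75 Hz calibration bands, and the
MVC-window SNR is ≈ 34 dB (healthy) at the default sensor-noise SD of
5 µV.

**Protocol.** Three 5-s maximal voluntary contractions (MVC) per
session — 0.5 s ramp up, 4 s hold, 0.5 s ramp down — separated by rests
drawn uniformly from 4–6 s, sampled at 1000 Hz on four channels (sEMG +
strain for the brachioradialis and flexor digitorum superficialis).
Trial boundaries are 0-based half-open sample intervals of exactly 5000
samples.

**Fatigue.** During each hold the sEMG envelope is multiplied by
`1 + r·t` (r = 0.02 /s healthy, 0.10 /s sarcopenic, log-normal
between-subject jitter), relaxing back to 1 during the ramp-down as
drive collapses at release; MUAP durations additionally grow 2 % per
trial, so MF drifts down across the session. The amplitude drift up /
MF drift down pair is the standard electrophysiological fatigue
signature; making it stronger in sarcopenia is the package's generative
choice for producing the expected direction of the normalized amplitude
features — the direction is an empirical observation in this field, and
the mechanism behind it is a modelling decision of this package.

**Strain channel.** A PVDF film responds to deformation *rate*: the
grip-force envelope (effort × grip strength, kg) drives a first-order
high-pass with τ = 0.2 s and gain 0.02 V/(kg/s). Constant force decays
to zero; an effort ramp of slope s settles at `gain · τ · s · grip`.
Weaker subjects therefore produce proportionally lower peak strain.

**Metadata.** Sex, age (60–85), grip strength, skeletal muscle index
(SMI) and five-repetition chair-stand time are drawn from group- and
sex-specific normals chosen to straddle the AWGS-2019 cut-offs the way
a screening cohort does, then rejection-sampled until the AWGS rule
reproduces the intended group label — label consistency holds by
construction and is verified exhaustively in tests. Default cohort:
75 subjects at 40 % prevalence.

## Preprocessing

* **Trace normalization**: min–max to [−1, 1] after mean-centring;
  constant traces map to zero; the map is idempotent.
* **Active-window segmentation**: 100-ms moving-RMS envelope; activity
  threshold 3 × the rest baseline, floored at half the trial's
  95th-percentile envelope (an envelope half-maximum estimate of the
  hold, since ramps clear a noise-level baseline almost immediately);
  the window spans the first to last supra-threshold sample, centre-
  cropped to 4 s so that the length-dependent features (iEMG, WL, ZC,
  SSC) are comparable across trials and groups. If the envelope never
  crosses the threshold the central 80 % of the trial is used, with a
  warning.
* **Median frequency**: Welch PSD with 1-s Hann segments and 50 %
  overlap; MF is the half-power point of the cumulative PSD with linear
  interpolation between bins. Verified against a naive cumulative-
  periodogram oracle and against a pure sinusoid to within one bin.
* **STFT**: 0.5-s Hann window, 75 % overlap, linear magnitudes.
* An optional 20–450 Hz zero-phase band-pass is provided but off by
  default (no filtering is part of the modelled acquisition chain).

## Feature engineering

Per active window, six Hudgins time-domain features — RMS, MAV,
iEMG (rectangle-rule integral `Σ|xᵢ|·Δt`), waveform length, zero
crossings and slope-sign changes (dead-band ε = 0.01 × window RMS) —
plus three continuous-wavelet-transform features on a real Morlet with
32 logarithmic scales spanning 10–450 Hz equivalent frequency: mean
squared coefficient magnitude (`cwt_power`), Pearson kurtosis of the
pooled |coefficient| distribution, and wavelet entropy (Shannon entropy
in nats of the scale-energy distribution; ln 32 ≈ 3.47 is the maximum).

**MVC normalization.** Each feature is divided by the mean of the
subject's three MVC-trial reference values on the same channel. When
the reference is the table itself the per-subject mean of normalized
values is exactly 1 — useful as a contract, but it algebraically removes
any between-group mean difference. The screening pipeline therefore
normalizes *hold-phase* (active-window) features by *whole-trial*
references: inter-individual amplitude and impedance differences still
cancel, while the within-hold fatigue drift survives the ratio. With
the generator's group-dependent fatigue and ramp shape, normalized RMS,
MAV, iEMG and WL come out higher in the sarcopenia group, and the
spectral shift drives ZC/SSC lower.

**Group statistics.** Subject-level two-sided Mann–Whitney U per
feature, Benjamini–Hochberg corrected across the nine features. Its
type-I error is calibration-tested under the null (rejection rate in
[0.03, 0.07] at α = 0.05 over ≥ 1000 tests).

## Fusion classifier

Three streams per MVC trial:

* **A (signals)**: the raw 4-channel trial window, decimated ×4 with an
  anti-aliasing FIR (250 Hz effective rate; both groups' MF content
  lies well below the 125 Nyquist), through two Conv1D(ReLU)+MaxPool
  blocks (16 and 32 filters, kernel 7, pool 4) whose feature maps feed
  an LSTM with 64 hidden units (last hidden state).
* **B (features)**: the nine MVC-normalized features, lifted by a
  length-1 convolution (per-feature affine map) to 4 channels.
* **C (demographics)**: sex, age, grip strength, lifted the same way.

Streams are concatenated → dropout 0.3 → dense ReLU (32) → softmax over
{healthy, sarcopenia}. Training uses Adam (lr 1e-3, batch 16) on
softmax cross-entropy; all parameters, shuffling and dropout derive
from one seed, so a train/predict cycle is bit-reproducible on CPU.
Feature, demographic and per-channel raw standardization statistics are
computed on the training fold only and stored with the model.

The network is implemented in a small numpy layer library
(`sarcoscreen.nn`) with hand-written gradients; every layer's backward
pass is verified against central differences in the test suite.

Layer widths, kernel and pool sizes, dropout, and optimizer settings
are package defaults — the architecture facts fixed by design are the
two convolutional layers with ReLU, the 64-unit LSTM, the convolution-
based mapping of the auxiliary streams, and the softmax head. The
defaults (16/32 filters, ×4 decimation, 15 training epochs for
cross-validation runs) were chosen so a full 10-fold, three-
configuration evaluation of the 75-subject cohort completes in a few
minutes on one CPU core; at these sizes training converges well before
the epoch budget.

**Baselines.** SVM (RBF, Platt-scaled) and random forest on the
9-feature + demographics table; CNN-only (global average pooling in
place of the LSTM) and LSTM-only (average-pooled raw channels straight
into the LSTM) networks on raw windows.

**Modality ablation.** The raw stream can be restricted to sEMG or
strain channels without code change. Single-modality runs also drop the
auxiliary streams, so "sEMG only" and "strain only" see exactly that
signal; the fused configuration uses everything. This is the
interpretation under which the fused-versus-single comparison is
meaningful rather than a tie between demographic classifiers.

## Evaluation

Folds are split at the **subject** level (all of a subject's windows
travel together), stratified by label where the fold count permits;
per-subject scores are the mean predicted sarcopenia probability over
the subject's windows. The ROC curve is computed from subject scores;
AUC by trapezoid equals the Mann–Whitney concordance (ties get half
credit), verified against brute-force pair counting. Confusion matrices
are reported as counts plus both row-normalized and global-proportion
forms. t-SNE (perplexity 20, PCA init, fixed seed) embeds the
post-concatenation activations.

## Shapley attribution

Permutation-sampling estimator: for each explained sample, random
feature orderings are drawn, absent features imputed from one background
row per ordering, and marginal contributions averaged — an unbiased
estimator of the exact Shapley value with reported Monte-Carlo standard
errors. Tests verify local accuracy, the null-player and symmetry
axioms, the linear-model closed form `w_j (x_j − μ_j)`, and exact
agreement with full 3! enumeration on three-feature models. The
attribution target is the softmax sarcopenia probability; the analysis
script attributes both the fused network (raw stream held at the
sample's own recording) and a random-forest surrogate on the same
tabular inputs, labelled accordingly.

## Screening rules

AWGS-2019 cut-offs with the consensus boundary semantics: strict `<`
for grip (28 kg men / 18 kg women) and SMI (7.0 / 5.7 kg/m²), `≥ 12 s`
for the chair-stand. Sarcopenia = low mass AND (low strength OR poor
performance); healthy = no flag; otherwise indeterminate. Missing
measurements produce an explicit missing-data result, never a silent
default. The longitudinal worked example stores grip readings printed
in newtons verbatim with an annotation: the cut-offs are in kg and
≈ 1.5 kg is not a plausible adult grip, so the rule engine is fed
synthetic kg values consistent with the narrative.

## What the generator does and does not emulate

It reproduces: MUAP-superposition statistics with a realistic MF range
and its sarcopenic decline, the size principle, amplitude attenuation,
fatigue drift, rate-sensitive piezoelectric output, AWGS-consistent
metadata and the three-MVC protocol. It does **not** model: motion
artifacts, electrode–skin impedance drift, powerline interference,
inter-channel crosstalk, MUAP shape heterogeneity beyond duration and
amplitude scaling, or the clinical heterogeneity of a real cohort —
group differences here are cleaner than in practice. Passing tests
therefore demonstrate that the pipeline recovers the structure the
generator encodes (formula correctness, calibration, leakage-free
evaluation, axiom compliance), not that the reported clinical accuracy
transfers to real recordings: the perfect cross-validated accuracy on
the default cohort reflects the synthetic effect sizes.

## Numerical choices

Ties in the summary ranking break alphabetically; strictly-ascending
recruitment thresholds are enforced by an epsilon accumulate; constant
traces normalize to zero rather than raising; zero-power windows raise
on MF and wavelet entropy; the ROC handles tied scores by collapsing
threshold runs; standardization uses a 1e-12 floor on standard
deviations; Gamma renewal trains get a uniform random initial phase so
spike trains are not locked to recruitment onset.
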