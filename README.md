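# sarcoscreen

Synthetic multimodal sEMG + piezoelectric-strain cohorts and a CNN–LSTM
fusion pipeline for wearable sarcopenia screening.

Sarcopenia — age-related loss of muscle mass, strength and function —
is screened clinically with the AWGS-2019 criteria: low skeletal muscle
index (SMI) plus low handgrip strength and/or a slow five-repetition
chair-stand. Wearable sensing offers a cheaper route: during a maximal
handgrip, surface EMG (sEMG) captures motor-unit recruitment while a
piezoelectric strain film captures mechanical contraction, and both
change characteristically with sarcopenia (fewer, larger, slower motor
units → lower median frequency; weaker contraction → lower raw
amplitude; compensatory recruitment → higher MVC-normalized activation).

This package is for researchers in biomedical signal processing who
want a fully reproducible, end-to-end testbed of that screening idea:
a motor-unit-level simulator standing in for undeposited clinical
recordings, the nine-feature sEMG engineering stage, a three-stream
CNN–LSTM fusion classifier with baselines and modality ablations,
Shapley attribution, and the AWGS rule engine.

## The core pipeline

1. **Cohort simulation** (`sarcoscreen.cohort`) — sEMG as a sum of
   motor-unit action-potential trains, x(t) = Σᵤ (hᵤ ∗ sᵤ)(t) + noise,
   where hᵤ is a Gaussian-derivative MUAP kernel and sᵤ a Gamma-renewal
   spike train gated by recruitment threshold; strain as a first-order
   rate-sensitive (piezoelectric) response to grip force. Metadata are
   rejection-sampled until the AWGS rule reproduces the group label.
2. **Signal analyses** (`sarcoscreen.preprocess`) — active-window
   segmentation, SNR = 20·log₁₀(RMS_signal/RMS_noise), Welch median
   frequency (half-power point of the cumulative PSD), STFT.
3. **Features** (`sarcoscreen.features`) — the Hudgins set
   RMS = √(1/N Σ xᵢ²), MAV = 1/N Σ |xᵢ|, iEMG = Σ |xᵢ|·Δt,
   WL = Σ |xᵢ₊₁ − xᵢ|, ZC, SSC, plus CWT power, CWT kurtosis and
   wavelet entropy; all normalized to the mean of the subject's three
   MVC trials.
4. **Classification** (`sarcoscreen.model`, `sarcoscreen.nn`) — raw
   windows → Conv×2 → LSTM(64), fused with the 9 features and
   demographics via length-1 convolutions → softmax; trained with Adam
   in a small numpy layer library with hand-verified gradients.
5. **Evaluation & interpretation** (`sarcoscreen.evaluate`,
   `sarcoscreen.interpret`) — subject-level stratified 10-fold CV,
   ROC-AUC (≡ Mann–Whitney concordance), t-SNE of the fused
   representation, permutation-sampling Shapley values.

## Worked example

```python
import numpy as np
from sarcoscreen.cohort import generate_cohort
from sarcoscreen.preprocess import median_frequency, segment_active_windows
from sarcoscreen.model import FusionModelConfig, build_dataset
from sarcoscreen.evaluate import kfold_cv

recordings, profiles = generate_cohort(n_subjects=75, prevalence=0.4, seed=11)

mf = {"healthy": [], "sarcopenia": []}
for rec, prof in zip(recordings, profiles):
    for w in segment_active_windows(rec, "br_semg"):
        mf[prof.group_label].append(median_frequency(w))
print({g: round(float(np.mean(v)), 1) for g, v in mf.items()})

dataset = build_dataset(recordings, profiles)
report = kfold_cv(dataset, FusionModelConfig(epochs=15), k=10, seed=11)
print(round(report.mean_accuracy, 3), round(report.auc, 3))
```

prints

```
{'healthy': 100.9, 'sarcopenia': 70.3}
1.0 1.0
```

— the median frequency of the sarcopenic group's sEMG sits ≈ 31 Hz
below the healthy group's (the slow-fibre shift the simulator encodes),
and the fused classifier separates the groups perfectly under
subject-level 10-fold cross-validation at the generator's default
effect sizes. The numbered scripts under `analysis/` run the same
pipeline step by step (cohort → signal analysis → features → models →
Shapley → longitudinal screening example) and write their tables under
`results/`.

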