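# qushab

Quantitative-ultrasound (QUS) tumor **hab**itat analysis: a pipeline for
predicting breast-cancer response to neoadjuvant chemotherapy from
pre-treatment ultrasound radiofrequency (RF) data.

Locally advanced breast cancer is treated with chemotherapy before
surgery, but a large fraction of tumors do not respond, and response is
currently confirmed only months later. The frequency content of
backscattered ultrasound RF echoes carries information about tissue
microstructure, and intra-tumor regions ("habitats") with distinct
acoustic properties turn out to be informative about whether a tumor
will respond. This package implements that analysis chain end to end for
researchers in quantitative ultrasound and imaging biomarkers, with a
synthetic-data module standing in for clinical data so every stage is
testable on a laptop.

## What it computes

1. **Spectral parametric maps** (`qushab.spectral`). Sliding-window
   (2 mm, 95% overlap) analysis of RF frames with reference-phantom
   normalization: `S(f) = 10·log₁₀(P_sample/P_ref)`. A line fit on the
   3–8 MHz band gives the spectral slope SS, 0-MHz intercept SI and
   mid-band fit MBF = SI + SS·f_mid; a spherical Gaussian form-factor
   fit `BSC(f) ∝ f⁴·exp(−0.827 k²a²)` gives the effective scatterer
   diameter ESD = 2a and acoustic concentration EAC (dB). Spectra are
   compensated for frequency-dependent attenuation with a two-layer
   (intervening tissue + tumor) path model and a spectral-difference
   attenuation estimate (ACE).
2. **Habitat segmentation** (`qushab.segmentation`). A hidden Markov
   random field over the (ESD, EAC, MBF, SI) pixel vectors:
   class-conditional multivariate Gaussians with a Potts prior
   `P(Y) ∝ exp(−β·Σ_{i~j} 1[y_i≠y_j])`, fitted by EM with ICM MAP
   labeling (K-means init, ≤15 EM × ≤10 ICM iterations). The number of
   regions comes from a BIC elbow; regions are numbered by MBF mean
   (region 1 = highest); reproducibility is scored by the in-group
   proportion (IGP).
3. **56-feature descriptor** (`qushab.features`). Mean and SNR
   (mean/std) of each map over core, margin and the three regions,
   region-mean differences, region area proportions and relative margin
   area, averaged over imaging planes.
4. **Response prediction** (`qushab.response`). SMOTE balancing, mRMR
   ranking to 21 features, sequential forward selection to 4 by 5-fold
   CV accuracy, and an AdaBoost decision-tree classifier evaluated once
   on a held-out test split (accuracy, sensitivity = non-responder
   recall, specificity, AUC, ROC).
5. **Survival validation** (`qushab.survival`). Kaplan–Meier
   recurrence-free-survival curves for predicted and pathological
   response cohorts and the two-group log-rank test.

## Worked example

Segment synthetic multi-parametric maps, extract the descriptor, and
train the response model:

```python
import numpy as np
from qushab.synthetic import (SyntheticMapConfig, SyntheticCohortConfig,
                              generate_label_field, generate_multichannel_maps,
                              generate_cohort)
from qushab.segmentation import Plane, hmrf_em, order_regions, select_num_regions
from qushab.response import split_cohort, run_experiment

# 1. ten synthetic tumor planes with known 3-region ground truth
planes = []
for s in range(10):
    cfg = SyntheticMapConfig(seed=s)
    labels = generate_label_field(cfg)
    planes.append(Plane.from_maps(generate_multichannel_maps(labels, cfg)))

# 2. how many habitats? (BIC elbow) — and fit the HMRF
K, bics = select_num_regions(planes, K_range=range(1, 7), seed=0)
model, labels = hmrf_em(planes, K=K, beta=1.0, seed=0)
model, labels = order_regions(model, planes, labels)
print("selected K =", K)
print("region MBF means (dB):", np.round(model.region_mbf_means, 2))

# 3. cohort-level response modelling on a synthetic feature table
cohort = generate_cohort(SyntheticCohortConfig(n_patients=181, seed=0))
cohort = split_cohort(cohort, test_fraction=0.3, seed=0)
_, result, selected = run_experiment(cohort, feature_set="habitats", seed=0)
print("selected features:", selected)
print(f"test accuracy={result.accuracy:.3f}  AUC={result.auc:.3f}")
```

Output:

```
selected K = 3
region MBF means (dB): [ -1.99  -6.01 -10.  ]
selected features: ['M_3-1_EAC', 'M_1_MBF', 'SNR_1_SI', 'M_2_ESD']
test accuracy=0.778  AUC=0.790
```

`selected K = 3` is the BIC elbow over K = 1..6; the region MBF means
confirm the ordering convention (region 1 loudest) and recover the
generating values (−2/−6/−10 dB). The selection finds features carrying
the simulated class shift (three of the four shifted biomarker features
here), and the held-out metrics show what a 1 SD effect on 4 of 56
features buys at n = 181 with a 70/30 split: ~0.79 AUC.

The same chain is scriptable from the shell (`qushab run --config
run.yaml`, or per stage: `qushab maps`, `qushab segment`,
`qushab features`, `qushab train`, `qushab survival`).

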