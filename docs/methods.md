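# Methods

This note records the models implemented in `qushab`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic data do and do not establish.

## Spectral parametric maps

**Model.** Backscattered RF echoes are analyzed in 2 mm × 2 mm sliding
windows (95% overlap, i.e. a 0.1 mm map grid). Each scan line in a
window is Hann-gated and its periodogram computed; the periodograms are
averaged across the window's lines. The averaged sample spectrum is
divided (in dB: subtracted) by the spectrum of a reference phantom with
known acoustics measured at the same depth, which cancels the system
transfer function and transducer beam shaping. Line-fit parameters on
the 3–8 MHz band are the spectral slope SS (dB/MHz), the 0-MHz
intercept SI (dB), and the mid-band fit MBF = SI + SS·f_mid. The
effective scatterer diameter (ESD) and effective acoustic concentration
(EAC) come from fitting a spherical Gaussian form factor
`BSC(f) ∝ f⁴·exp(−0.827·k²·a²)` (k = 2πf/c, ESD = 2a) to the
attenuation-corrected normalized spectrum by least squares in the log
domain; the amplitude offset is profiled out in closed form and
reported as EAC in dB, so region contrasts are dB differences.

**Attenuation.** A single convention is used end to end: a coefficient
α (dB/MHz·cm) removes 4·α·f·d dB from the round-trip power spectrum of
an echo from depth d cm. The RF simulator shapes each echo by this law,
the spectral-difference ACE estimator divides the per-frequency depth
slope by the same factor 4, and point compensation adds back
4·f·(α_tumor·d_tumor + α_tissue·d_tissue − α_phantom·d_total) dB under
a two-layer path model (intervening breast tissue fixed at
1 dB/MHz·cm, phantom at 0.576 dB/MHz·cm, phantom sound speed 1488 m/s,
tissue depth conversion at 1540 m/s). Because estimator and simulator
share the convention, self-consistency tests (phantom vs itself → 0 dB;
depth invariance after compensation) are exact.

**Numerical choices.** Band center for MBF is the 3–8 MHz midpoint
(5.5 MHz). The ESD search runs on a 1 μm grid over [10, 300] μm with
bounded refinement; a fit at a search bound is flagged unreliable and
the pixel masked invalid, as are non-finite or non-positive parameter
fits. Windows whose footprint is not fully inside core∪margin produce
no pixel. The ACE is a single scalar per plane, from per-frequency
regressions of normalized log power against depth pooled over lateral
columns with at least a 4 mm depth span; when no column has the span,
the phantom value is used and the result flagged by construction (the
correction then reduces to the intervening-layer term). Negative ACE
estimates are clipped to zero and flagged.

## Habitat segmentation (HMRF-EM)

**Model.** Valid pixels of the co-registered (ESD, EAC, MBF, SI) maps
are class-conditional multivariate Gaussians; labels follow a Potts
(Gibbs) prior with pairwise weight β on an 8-connected lattice. The MAP
labeling maximizes P(X|Y,θ)·P(Y). One pooled model is fitted across
the planes of all training tumors, so the test-time labeling can reuse
a single global θ. Channels are z-scored with pooled training
statistics (the same transform is reused at test time) because the
units are incommensurate (μm vs dB).

**Fitting.** K-means (10 restarts, seeded) initializes labels and class
Gaussians. Each EM iteration runs red-black ICM sweeps (at most 10, or
until no label changes) minimizing the Gaussian negative log-likelihood
plus β times the count of disagreeing valid neighbors, then updates
class means and covariances as posterior-weighted moments, where the
pixel posterior combines the Gaussian likelihood with a neighbor-field
prior exp(−β·U_i(l)) read off the current labeling. The outer loop runs
at most 15 iterations or until the maximum relative parameter change
drops below 1e−4. Singular covariances receive a small diagonal ridge.
Invalid pixels are excluded from likelihoods and treated as missing
neighbors (the neighbor count shrinks), not imputed. The complete-data
pseudo-log-likelihood is tracked per iteration as a diagnostic; it is
non-decreasing up to the ICM approximation on the synthetic inputs
tested. The interpretation of the emission parameter Σ is the standard
covariance of the class Gaussian.

**Defaults.** β = 1.0 (the prior weight and connectivity are modelling
choices; β = 0 reduces exactly to per-pixel Bayes classification, which
the tests exploit as an oracle). The number of regions is selected by
the BIC elbow over K = 1..6: the BIC uses the non-spatial mixture
likelihood (spatial partition functions are intractable) with
K−1 + K·14 free parameters, and the elbow is the smallest K whose
improvement toward K+1 falls below 10% (configurable) of the largest
single-step improvement; a monotone decline resolves to the smallest K.
Regions are renumbered by training-set MBF mean, highest first; exact
ties break by EAC mean descending, then original index.

**Reproducibility score.** The in-group proportion (IGP) is computed
within each patient's pixels (nearest neighbor in standardized channel
space), then aggregated as mean and median across patients. The
within-patient choice keeps the score independent of cohort-level
pixel imbalance; a cohort-wide neighbor search is a plausible
alternative and would score similarly on well-separated regions.

## Feature descriptor

56 features per tumor: per map (ESD, EAC, MBF, SI) the mean and SNR
over the core, over the 5 mm margin, and over each of three regions;
the three pairwise region-mean differences per map (defined
higher-index minus lower-index, e.g. M₃₋₁ = M₃ − M₁); the three region
area proportions within the core; and the margin/core area ratio.
Regional SNR = mean/std with the sample (n−1) standard deviation; dB
channels can legitimately produce negative SNR values and are left as
computed. Regions absent from a plane yield missing entries; plane
aggregation is the unweighted mean over planes ignoring missing
values, and a tumor with partially missing features is flagged rather
than imputed at extraction (the modelling stage may impute from
training data if required). SS maps are computed but feed no feature,
matching the descriptor's definition over the other four maps.

## Response modelling

Labels follow the modified-response rule: grades 1–2 (<30% size
reduction) are non-responders, grades 3–5 (>30% reduction, or very low
residual cellularity) responders. The training split is balanced by
SMOTE (synthetic minority samples as convex combinations with one of
k = 5 minority nearest neighbors, k shrunk for small minorities);
implemented in-package since no SMOTE implementation is part of the
dependency set. Features are ranked by greedy mRMR with the
mutual-information difference criterion on 3-bin discretization at
μ ± σ (the classic recipe) and cut to 21; sequential forward selection
then maximizes mean stratified 5-fold cross-validated accuracy of the
AdaBoost decision-tree classifier, stopping at 4 features (an optional
minimum-improvement rule can stop earlier). SMOTE is re-applied inside
each training fold only. The final classifier is AdaBoost over depth-2
trees, 100 estimators, learning rate 1.0; the wrapper search inside SFS
uses a 10-estimator version of the same classifier, a deliberate
speed/fidelity trade-off for the O(pool × folds) fit count of forward
selection — selection quality on the synthetic cohorts is unaffected
(null selection stays at chance; strong effects are found).

Sensitivity is recall on the non-responder class and specificity recall
on responders: with ~24% non-responders the minority class is the
clinically actionable one, and this orientation is consistent with the
reference operating point (13/15 ≈ 86.7% vs 34/40 = 85%). AUC is the
trapezoidal area under the ROC of the non-responder score. Test rows
are untouched by SMOTE, ranking, selection and training; the tests
assert this by poisoning test rows and checking the fitted pipeline is
bit-identical. ER/PR/HER2 enter the clinical feature set as separate
binary indicators.

## Survival analysis

Kaplan–Meier product-limit curves per cohort and the standard two-group
log-rank test (chi-square, 1 df), both via `lifelines`, with the usual
aggregation of tied event times and administrative censoring at the
10-year horizon. Tests verify the estimator against the empirical
survival function on uncensored data and the log-rank statistic against
a brute-force hypergeometric accumulation.

## Synthetic data: what it emulates, and what it does not

* **RF frames** are 2-D superpositions of Gaussian-envelope pulse
  echoes from point scatterers with frequency-dependent attenuation;
  no diffraction, elevational beam, or nonlinear propagation is
  modelled. Since sample and phantom share the pulse, the
  reference-phantom normalization cancels system effects by
  construction — which is precisely the property the real method relies
  on, but it means transducer-specific artifacts are not exercised.
  Fully developed speckle (Rayleigh envelope) requires ≳10 scatterers
  per resolution cell; the tests use 300/mm².
* **Parametric maps** are drawn directly from the segmentation's
  generative model: spatially coherent labels (per-region smoothed
  Gaussian noise fields, argmax over regions, blob scale 8 px, every
  region ≥ 5% of pixels) and per-region multivariate Gaussian channel
  vectors. Default region means (ESD 70/90/110 μm, EAC 38/34/30 dB,
  MBF −2/−6/−10 dB, SI −8/−5/−2 dB, diagonal stds 8/1.5/1.5/1.5) give
  pairwise Mahalanobis separation ≥ 3 and reproduce the characteristic
  anti-correlation of MBF/EAC against ESD/SI across regions. Real maps
  violate Gaussianity and spatial stationarity; recovery results here
  bound the algorithm's behaviour only under its own model.
* **Cohorts** carry unit-variance Gaussian features with class-mean
  shifts (default 1 SD on the four biomarker features), clinical
  covariates matching the study marginals (age 50.6 ± 11.5 y, tumor
  size 5.2 ± 2.7 cm, ER/PR/HER2 rates 63.4/54.7/34.3%), 76.2%
  responders in a 181-patient default, and exponential recurrence-free
  survival (defaults 0.03 vs 0.12 events/year, i.e. hazard ratio 4)
  with uniform censoring over the 10-year window for a 20% fraction.
  Real feature correlations, non-proportional hazards and informative
  censoring are not modelled.

Passing tests therefore demonstrate internal correctness and
calibration of each algorithm under its stated model, not clinical
performance; the reference clinical dataset is not publicly deposited,
so the study's patient-level numbers are not reproducible here.

## Problem sizes in the checks

The standing checks use 64×64 maps (20 for model-order selection, 5 for
recovery), 30–50 speckle realizations for ensemble spectral estimates,
20-seed calibration of the modelling chain at n = 200 training / 80
test patients, 500 simulations for log-rank null uniformity and 100 for
power. These sizes keep every quantity's Monte-Carlo error well inside
the asserted margins.

## Known limitations

* ICM is a local MAP optimizer: with very strong spatial priors it can
  freeze domain walls rather than reach the global optimum; β = 1 on
  standardized channels is far from that regime.
* The per-plane scalar ACE ignores lateral attenuation heterogeneity;
  the depth-bin layout of the spectral-difference estimator is a free
  choice (window pairs pooled per lateral column, ≥ 4 mm span).
* SFS with a fixed budget of 4 features does not test whether a smaller
  set suffices; the optional no-improvement rule covers that use.
* The form-factor fit assumes the Gaussian form factor is the correct
  family; model mismatch maps into biased ESD rather than a flag.
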