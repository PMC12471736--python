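# Methods

## The model

`hemonam` fits a neural additive model (NAM) for binary diagnosis from a
23-feature routine blood panel (age, leukocyte and erythrocyte indices,
platelet markers, and the four derived ratios NEU/LY, PLT/LY, MPV/LY,
LY/MO). Each feature `x_i` passes through its own small feed-forward
subnetwork `f_i` (scalar input, two hidden ReLU layers, scalar output);
the prediction is

    logit(x) = sum_i f_i(x_i) + b0,        P(y=1 | x) = sigmoid(logit)

Because the logit is a plain sum, the model is exactly additive: the
contribution of feature `i` to any prediction is `f_i(x_i)` itself, read
off the forward pass. The attribution layer centers these contributions on
a reference population (the training split), `phi_i(x) = f_i(x_i) -
E_ref[f_i]`, which for an additive model equals the interventional Shapley
value — a theorem the test suite verifies numerically against a
brute-force coalition-enumeration oracle for p <= 6.

The network is implemented directly in numpy. The architecture is a stack
of p independent scalar-input MLPs, so one batched forward pass is three
einsums and the backward pass is written out explicitly; the analytic
gradient is verified against central finite differences in the test suite.
All randomness (initialization, shuffling, dropout masks, bootstraps) flows
through seeded `numpy.random.Generator` streams, making every fit
bit-reproducible.

## Training protocol and defaults

| parameter            | default | notes                                   |
|----------------------|---------|-----------------------------------------|
| hidden sizes         | [64, 32]| per-feature subnetwork widths           |
| dropout rate         | 0.2     | inverted dropout on both hidden layers  |
| optimizer            | Adam    | lr 0.001, L2 weight decay 1e-5          |
| weight decay scope   | weights only | offsets and global bias undecayed  |
| loss                 | binary cross-entropy, probabilities clipped to 1e-7 |
| max epochs           | 150     | early stopping patience 20              |
| LR schedule          | halve on plateau, patience 10, factor 0.5 |
| batch size           | 64      | unstated in the protocol; configurable  |
| initialization       | He-scaled Gaussian weights, zero offsets, b0 = 0 |

The monitored quantity drives both the plateau schedule and early
stopping, and the best-epoch weights are restored at the end.  Two monitor
modes exist because the source protocol is ambiguous about what was
monitored: the default carves a stratified 10% validation slice out of the
training split and monitors its loss (leakage-safe); `monitor="accuracy"`
instead monitors test-split accuracy, replicating the literal published
stopping rule, which leaks test information and is not the default.
"Improvement" means beating the incumbent by more than 1e-6, so float
noise cannot reset patience counters.

Preprocessing is leakage-safe by construction: an 80/20 stratified split
with largest-remainder apportionment of per-class test counts (477/504 at
0.2 gives exactly 95 + 101 = 196 test rows), then z-scoring with
population SD (divisor n) fitted on training rows only. Bootstrap
augmentation (append one resample-with-replacement of equal size, doubling
n) defaults to the training split only; a `pre-split` mode doubles the
whole cohort first — the literal published flow — and emits a leakage
warning, since resample twins can then straddle the split.

## Evaluation

Threshold metrics use a 0.5 cutoff with probability-equal-to-threshold
counting positive. Undefined quotients (e.g. LR+ when specificity = 1)
propagate as NaN, never 0 or infinity. ROC AUC is the rank-statistic
(Mann-Whitney) form with ties counted 1/2 (scikit-learn's
`roc_auc_score`); a test cross-checks it against exhaustive pair
enumeration. Confidence intervals are percentile bootstrap (default 1000
iterations, level 0.95) over resampled (probability, label) pairs;
iterations where a metric is undefined are dropped and counted. The
percentile method was chosen as the simplest faithful reading of
"bootstrap resampling"; BCa is out of scope.

Calibration reports equal-width reliability bins (default 10). The
*calibration deviation* is defined here as the unweighted mean over
non-empty bins of |mean predicted - observed frequency|; a count-weighted
variant (the usual ECE) is available via `weighted=True`. With small test
sets (~200 rows) the unweighted deviation is noisy because mid-range bins
hold few samples; the Brier score is the more stable summary at that size.

## The synthetic cohort generator

The generator stands in for the clinical dataset so that training,
evaluation and explanation are testable without any download. It emulates:

- **Marginals** calibrated to published control-group medians and IQRs:
  lognormal for skewed counts (solving sigma from
  IQR/median = 2*sinh(0.6745*sigma)), normal for symmetric indices,
  truncated normal for age (mean 59.17, SD 10.851, floor 20). Basophil
  count has no published row, so it uses a clinically typical lognormal
  (median 0.03, IQR 0.03, in 10^3/uL). One printed PDW row (41 %) conflicts
  with the accompanying text (12 fL); the text value is used.
- **A correlated red-cell block** (RBC, HGB, HCT, MCV, MCH, MCHC) sharing
  one latent Gaussian factor with loading 0.7, mirroring the mathematical
  and physiological coupling of erythrocyte indices.
- **Exact ratio columns**: NEU/LY, PLT/LY, MPV/LY, LY/MO are computed from
  their components, never sampled.
- **A known additive ground truth**: labels are Bernoulli(sigmoid(sum_i
  g_i(z_i) + b0)) where z are cohort-standardized features and each g_i is
  zero, linear, a logistic ramp, or a centered quadratic. The intercept b0
  is calibrated by root-finding so expected prevalence matches 477/981
  within 0.01.

The default ground truth plants its five strongest shapes on NEU, WBC,
RDW-CV, BA and LY — in that order, matching the published global
importance ranking — plus moderate effects on PDW and MO, with at least
sixteen exact-zero shapes. Signal strength was set so the Bayes-optimal
balanced accuracy is ~0.93-0.95, comparable to the separability the real
data must have supported (reported accuracy 0.941, AUC 0.96); a fitted NAM
reaches ~0.88-0.90 at n = 2000.

Two design points deserve emphasis because they are where the generator's
statistics meet identifiability:

1. **LY's direction.** The ratio columns contain LY in three denominators,
   and MPV/LY in particular is a near-deterministic monotone transform of
   LY (MPV varies little). If LY's effect ran opposite to NEU's, a single
   monotone shape on NEU/LY would absorb *both* signals coherently and the
   per-feature decomposition would be unidentifiable — the fitted model
   would (correctly) park the signal on the ratio. The planted LY effect
   is therefore risk-increasing, consistent with the published class-wise
   attribution analysis (LY contributes positively in the patient group)
   and with the slightly higher patient-group LY median. It is also a
   steep ramp, so the noise in any ratio proxy smears it and the true
   channel holds a genuine loss advantage.
2. **PDW, not MPV, as the moderate sixth effect.** MPV appears in MPV/LY;
   an active MPV would recreate the same coherent-absorption channel. PDW
   belongs to no ratio and is strongly class-separated in the published
   cohort (12 vs 15.9 fL).

What the generator does **not** emulate: the real joint distribution
beyond marginals plus one correlation block, leukocyte compositional
constraints (WBC is sampled independently of its subtypes), measurement
rounding, or any temporal structure. Passing tests therefore demonstrate
that the pipeline recovers known additive structure under realistic
marginals and prevalence — not that the clinical data is this clean, nor
that real AMI risk is additive.

## Numerical choices and degenerate inputs

- Exact additivity is bit-level: the logit is computed as
  `contributions.sum() + bias`, and tests assert the reconstruction with
  the same summation order.
- Missing values, non-numeric cells, constant training columns, zero ratio
  denominators, single-class splits and empty inputs are hard errors that
  name the offending row/column; there is no imputation.
- A constant (all-zero-shape) model yields a uniform intrinsic importance
  vector with a warning rather than 0/0.
- Intercept calibration brackets b0 in [-30, 30] and fails loudly if the
  target prevalence is unreachable.
- The enumeration Shapley oracle refuses p > 10 (cost 2^p).

## Problem sizes

Default experiments run at the study scale (n = 981, 196 test rows);
shape-recovery analyses use n = 2000 so each subnetwork sees enough data
for stable curve estimates; generator-level statistical checks use
n = 5000-10000. A full fit takes well under a minute on one CPU core.

## Known limitations

- Importance of features that are near-deterministic transforms of one
  another (the derived ratios and their components) is only identifiable
  up to the coherent-absorption caveat above; on real panels the split of
  credit between, say, NEU and NEU/LY should be read jointly.
- The bootstrap CI is percentile, which can undercover for strongly
  skewed statistics at small n.
- Early stopping on test accuracy (the literal published rule) is
  supported for replication but leaks test information; results obtained
  with it should not be reported as held-out performance.
- The calibration deviation on ~200-row test sets is dominated by bin
  sparsity; prefer the Brier score or `weighted=True` there.
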