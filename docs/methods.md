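# Methods

## Problem and analysis chain

The package asks whether a *combination* of two routine health-check
characteristics predicts the development of metabolic syndrome (MetS) better
than either alone, and whether the combination can be read back as an
interpretable rule. The chain is: (1) label subjects from longitudinal
check-up panels; (2) screen 16 candidate characteristics (none of which is a
MetS component) with a fuzzy-neural-network classifier under fivefold
cross-validation and greedy forward selection; (3) extract the learned rule
as thresholds plus a 2×2 case/control matrix with rule weights; (4) verify
the selected characteristics with adjusted logistic odds ratios and
correlation ratios.

## Cohort labeling (JASSO criteria)

A subject-year is MetS-positive iff obese (waist ≥85 cm; BMI ≥25 kg/m² when
waist is unmeasured — the synthetic data carry no waist, so the BMI rule is
always used) **and** at least two of: SBP ≥130 or DBP ≥85 mmHg; TG ≥150
mg/dl or HDL <40 mg/dl; fasting glucose ≥110 mg/dl. All boundaries
inclusive. Labels: any antihypertensive / lipid-lowering / anti-diabetic
medication ⇒ `excluded`; MetS already at baseline ⇒ `excluded` (cases must
*develop* MetS — the handling of prevalent cases is our choice, as is
requiring the component-free state already at baseline for healthy
controls); MetS in any follow-up year ⇒ `case`; certified free of all four
components at baseline and every follow-up year ⇒ `healthy_control`;
otherwise `normal_control`. A year can certify "component-free" only when
all six component measurements are observed and negative; partially missing
years therefore block the healthy-control label but never create a case
(indeterminate flags are treated as not-present when testing the MetS rule,
so MetS is never over-called from missing data).

## The fuzzy neural network

Standardized inputs (training-fold mean/SD; an optional log transform per
input is off by default — the sigmoids absorb monotone skew), two sigmoid
memberships per input f(x) = 1/(1+exp(−Wg·x+Wc)) with sign constraints
Wg_low < 0 < Wg_high, product rule activations over the 2^k low/high
combinations, output y\* = Σ Wf_r Π_r. Classification is by sign of y\*;
y\* = 0 is always incorrect.

Training is deliberately plain: full-batch gradient descent on the mean
squared error against targets ±1, learning rate 0.05, 500 epochs, sign
constraints maintained by projection (|Wg| ≥ 1e-3). Initialization is
deterministic and symmetric — Wc = 0, Wg = ±2, Wf = 0 — so training needs no
random restarts and the whole pipeline is reproducible from the data order
alone. Training stops early if the loss ever fails to improve (a divergence
guard, not a convergence criterion). These optimizer details are this
package's design; the architecture, the ±1 coding, the sign rule and the
selection protocol are fixed by the method being implemented.

## Selection protocol

Subjects are shuffled once (seeded) and cut into five near-equal contiguous
folds. Each candidate set is reduced to its own complete cases first, so
subject counts shrink as inputs accumulate, exactly as they do in real
check-up data with characteristic-specific missingness. Per fold the model
trains on the other four folds and the weighted accuracy
100·[(train correct fraction)/3 + 2·(test correct fraction)/3] is computed;
the per-fold values are averaged (averaging across folds, rather than
pooling counts, is our documented choice). The null baseline is the
majority-class accuracy on the same complete-case subset, which is why
baselines differ between selection stages. Stage 2 always extends the
stage-1 winner (strict parameter increase, not an exhaustive pair search);
ties break toward the earlier candidate in the fixed screening order. The
linear and logistic comparators reuse the identical folds; a perfectly
separated logistic fold falls back to an L2-penalized fit and flags the
result.

## Rule extraction

The reported threshold per input is the raw value where the *high*
membership crosses 0.5 (standardized Wc_high/Wg_high mapped back through
the training mean/SD; exponentiated for log-transformed inputs). Among the
conventions the high-membership midpoint is ours; cell assignment is crisp
(value ≥ threshold ⇒ high), with a max-membership alternative behind a
flag. Reported weights are the raw Wf, unnormalized.

## Statistical verification

Odds ratios come from maximum-likelihood logistic regression of case vs
healthy control, Wald 95% CIs. γ-GTP enters per doubling (log₂ transform),
WBC per 1000 cells/μL. Adjustment ladder: model 1 unadjusted; model 2 age,
drinking, smoking; model 3 adds the MetS components (BMI, SBP, DBP, TG,
HDL, glucose); model 4 adds exercise habit. The ladder is reconstructed
from the adjustment description accompanying the original analysis; the
exact footnote definitions were not recoverable, which is why it is stated
prominently here. Correlation ratios are reported *signed* as point-biserial
correlations (for a binary grouping |r| equals the classical η), p from the
exact t transform with n−2 df. Group comparisons use the pooled-variance
Student t (Welch behind a flag) and Pearson chi-square without continuity
correction — the pair of standard choices that reproduces the recoverable
published p-values; a 2×2 with an all-zero column (e.g. a characteristic
present in 100% of both groups) is assigned χ² = 0, p = 1.

## Synthetic cohort generator

The generator emulates male employee check-up cohorts. Continuous
characteristics are normal with physiologic floors (the floor-induced mean
shift is compensated analytically); γ-GTP, triglycerides, GOT and GPT are
log-normal (their clinical SD/mean ratios are far too large for
normality). Structure:

- log γ-GTP = intercept + 0.04·(age − mean age) + 0.45·drinker + ε; the
  intercept is solved in closed form so the raw marginal mean hits its
  target. The shift sizes give a raw-scale correlation ratio with alcohol
  habit of ≈0.13–0.22 across presets (the log-normal skew attenuates the
  point-biserial below its log-scale value of ≈0.25) and reproduce the
  age-driven difference between the two study populations' healthy-stratum
  γ-GTP means (≈16 vs ≈27 IU/L).
- WBC = intercept + 1100·smoker + ε (cells/μL), giving η(WBC, smoking)
  ≈ 0.37.
- GOT/GPT share the γ-GTP residual (loading 0.3) so the liver enzymes
  correlate realistically while carrying no direct onset effect.
- Urinalysis flags are pure Bernoulli noise; no female subjects (the
  emulated studies are male-only).

MetS onset is drawn once per subject: logit P(onset) = −4.3 + 1.1·z_G +
0.9·z_W + 0.5·z_G·z_W, where z_G, z_W are the cohort-standardized log γ-GTP
and WBC. The marginal coefficients are derived from the published
unadjusted odds ratios (OR 4.71 per γ-GTP doubling ≈ 1.1 per SD of log
γ-GTP; OR 1.83 per 1000 WBC ≈ 0.9 per SD); the interaction size 0.5 is our
choice (the source quantifies the synergy only through rule weights). The
onset year is uniform over the follow-up window, and from that year on the
subject's components are forced over the thresholds (BMI, then SBP and TG).
Onset is a single window event, not a per-year hazard — the analysis only
consumes developed-ever labels. Non-onset components evolve as baseline +
small aging drift + an annual random walk (12% of the marginal SD per
year), so some subjects develop MetS "naturally" without any γ-GTP/WBC
signal and others drop out of the component-free state — both dilutions are
intentional realism. The onset intercept and the SBP/TG marginal means were
calibrated once so the default original-study preset yields a
case : healthy-control ratio near 1:2, then frozen.

Missingness is injected completely at random per characteristic (serum and
hematology 10%, urine flags 5%, components and habits 1–2% — the real data's
missingness was characteristic-specific and heavier for serum panels; only
the *pattern*, varying complete-case counts per input set, matters to the
analysis). Missingness applies to the baseline analysis table; follow-up
panels stay complete, so labeling noise and predictor missingness are
separated.

What the generator does **not** emulate: real measurement error structure,
informative (non-MCAR) missingness, within-subject biomarker tracking over
years, seasonal or assay effects, and any genetics. Passing tests therefore
show that the *method* recovers a known embedded interaction under
realistic marginals and missingness — not that it would perform identically
on real check-up data.

## Problem sizes and numerical choices

The repeated-seed recovery experiment uses 20 cohorts of n = 2000 subjects
(16 candidates, fivefold CV, 500-epoch training); the parameter-recovery
odds-ratio check uses 20 cohorts of n = 4392. These sizes give stable pass
rates while keeping a full run in minutes on one core. Degenerate inputs
(zero variance, single-class folds, empty candidate sets, nonpositive
values under the doubling transform) raise informative errors rather than
propagating NaNs. Seeds: every stochastic step derives from a single base
seed via a fixed affine fan-out, so stages are independently rerunnable and
end-to-end runs are bit-identical.

## Known limitations

- The trainer is a faithful gradient implementation of the stated
  architecture, not a byte-level reproduction of the original training
  software (whose exact update rules are not public); absolute accuracies
  should be compared qualitatively.
- k is capped at 2 by default (configurable); no exhaustive subset search,
  no nested CV for hyperparameters, no alternative MetS definitions.
- The published data-dependent numbers (77.4%/67.1% accuracy, thresholds
  26.9 IU/L and 5.83×10³ cells/μL, the OR and η tables) are not
  reproducible without the private records; the package recovers their
  qualitative pattern on synthetic cohorts and reproduces exactly the
  quantities that are arithmetic functions of published counts.
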