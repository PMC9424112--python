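# Methods

## Data model

The unit of analysis is a cohort of dysplastic lesions, each assessed once
by each of r raters for a panel of binary histological features, with two
right-censored time-to-event outcomes per case: malignant transformation
(progression to carcinoma at the same site) and recurrence after active
treatment. Times are months from the baseline biopsy; "five years" is 60
months throughout. Censored cases must reach 60 months of follow-up (the
cohort's minimum-follow-up inclusion rule); reading a cohort file with
`strict_followup=False` relaxes this for external data.

Missing assessments are representable (a ternary present/absent/missing
cell) even though the motivating study has none: agreement statistics use
pairwise deletion and consensus keeps its absolute vote threshold, so
real-world panels with gaps degrade gracefully rather than erroring.

## Consensus

A feature is called present when at least `min_agree` raters scored it 1;
the default is a strict majority (⌊r/2⌋+1, i.e. 2 of 3). For even panels
this stays a strict majority (3 of 4), matching the intent of the 2-of-3
rule rather than allowing ties. Missing votes shrink a case's effective
panel but never the threshold — a case with one vote of three present and
two missing is called absent — and the situation is logged. Lowering the
threshold is monotone (never removes a call); the extremes r and 1 are
logical AND and OR across raters.

## Agreement statistics

Per feature, with n cases and r raters:

* observed agreement `Pa` — agreeing rater pairs over all pairs, pooled
  across cases (each case weighted by its own pair count, which is the
  pairwise-deletion treatment of missing votes). For three binary raters a
  non-unanimous case is necessarily a 2–1 split and contributes exactly 1/3.
* pooled prevalence `π` — positive assessments over all assessments.
* Fleiss-type kappa — `(Pa − Pe)/(1 − Pe)` with `Pe = π² + (1−π)²`. With
  complete data this is exactly Fleiss' multi-rater kappa (cross-checked
  against statsmodels in the tests). The multi-rater "Cohen's kappa" of
  agreement tables in this field is usually this pooled-marginal form; an
  average-pairwise Cohen variant (rater-specific marginals) is available as
  `variant="pairwise_cohen"` but is not the default, because the pooled form
  reproduces the published table cells.
* Gwet's AC1 — same correction with `Pe = 2π(1−π)`. For binary ratings the
  two chance terms are complementary (`Pe_kappa + Pe_ac1 = 1`), so AC1 ≥
  kappa whenever π ≠ 0.5, strictly when Pa < 1. AC1's chance term is
  bounded by 0.5, so it remains defined at prevalence extremes where kappa
  degenerates (π ∈ {0,1} yields a flagged NaN kappa).

A consequence used heavily in testing: for three binary raters the pair
(positive assessments, complete-agreement cases) determines Pa, Pe, kappa
and AC1 in closed form, so any panel rebuilt from a printed table's
marginals must reproduce its kappa/AC1 cells exactly at the printed
rounding (2 dp, half away from zero). `panel_from_marginals` performs that
reconstruction. Three printed cells in the motivating study's table are
inconsistent with its own marginals under these formulas (likely a
different software variant); they are excluded from exact checks. No
variances or CIs are attached to kappa/AC1 (none are reported in this
literature for the design), and no weighted/ordinal extension is provided.

## Prognostic scores

Equal-weight point counts over the consensus (or a single rater's) profile.
The six-point model counts bulbous/drop-shaped rete pegs, hyperchromatism,
loss of epithelial cohesion, loss of stratification, suprabasal mitoses and
nuclear pleomorphism — the features univariately associated with both
outcomes — with canonical strata 0–1 / 2–3 / 4–6 (configurable; threshold
exploration is an evaluation concern, the strata stay fixed). The two-point
model restricts to the two features with the best inter-rater agreement and
reports the four presence categories (neither / cohesion_only /
bulbous_only / both). No learned or regression-derived weights: the
univariate hazard ratios are of comparable magnitude, which is the
justification for equal weights.

## Survival

Kaplan–Meier estimation and Cox regression are delegated to lifelines
behind this module's interface. The KM curves carry at-risk and event
counts, Greenwood variance `S² Σ d/(n(n−d))`, and confidence intervals on
the log(−log S) scale (the asymmetric intervals standard in Stata-style
output); `risk_at(t) = 1 − S(t)` gives the 2- and 5-year stratum risks. A
stratum with zero events returns a flat flagged curve.

Cox fits use Efron's correction for tied event times (lifelines' default;
verified in the tests against an independently written Efron partial
likelihood maximised by scipy, on tied and tie-free data — with no ties
Efron coincides with the exact partial likelihood). Reported are β, HR,
Wald 95% CI `exp(β ± 1.96·SE)` and two-sided Wald p-values, matching the
HR+CI presentation convention. Constant covariates and zero-event designs
are rejected as non-identifiable before fitting; convergence complaints
(e.g. monotone likelihood under complete separation) are captured on the
fit object. The univariate feature table fits one single-covariate model
per feature per outcome (24 fits), flagging p < 0.05.

## Discrimination

The evaluation outcome is binary — event at any time during follow-up —
not time-to-event (few events occur beyond five years in this design; no
time-dependent ROC). AUROC is the Mann–Whitney probability with midrank
ties, computed from ranks and property-tested against all-pairs
enumeration; ROC point sets come from scikit-learn. Correlated AUCs on the
same cases are compared with DeLong's test (the method is unnamed in the
motivating work; DeLong is the field default and is documented here as an
assumption). Covariate-augmented models (score + age/gender/WHO
grade/binary grade, encoded numeric/0-1/ordinal 1–3/0-1) are in-sample
logistic fits — no held-out split, mirroring the apparent original
approach — with a ridge-penalised fallback, flagged, under separation.
Per-rater evaluation recomputes both scores from each rater's own profile
and tabulates AUROCs beside the consensus column.

## Synthetic cohort generator

The generator defines the study conditions for every stochastic test.
Per case:

* latent feature `L_j ~ Bernoulli(p_j)`, independent across features
  (feature covariance is not identifiable from published aggregates; an
  optional shared-severity Gaussian copula over the six scoring features is
  provided, default off, because real atypia co-occurs);
* rater scores are conditionally independent flips of `L_j`: sensitivity
  0.85, specificity 0.90 by default, chosen to land agreement in the
  published kappa ≈ 0.3–0.7 band. The latent prevalences are back-solved
  through this channel, `p_j = (π_j − (1−spec))/(sens+spec−1)`, so pooled
  assessment prevalences target the published per-feature values;
* event times are exponential with rate `h0 · exp(Σ_j L_j log HR_j)`; the
  per-feature hazard ratios default to the published univariate point
  estimates for the six scoring features (transformation 8.27, 2.96, 3.78,
  5.35, 3.06, 3.74; recurrence 2.52, 2.90, 3.50, 4.50, 3.17, 3.45) and 1
  elsewhere. Transformation and recurrence are drawn independently given
  features (their dependence is likewise not identifiable from aggregates);
* censoring is administrative at 120 months, with a 20% fraction censored
  early, uniform on [60, 120] months, so censored cases always satisfy the
  minimum-follow-up rule;
* baseline hazards `h0` are calibrated by root-finding (Brent) so the
  *expected observed* event fraction — exact expectation over the latent
  profile distribution and the censoring mixture — equals 18%
  (transformation) and 25% (recurrence), the cohort-scale event rates;
* covariates: age ~ round N(66, 13²) clipped to [25, 95]; gender 39%
  female; site and treatment from the cohort's frequency tables; WHO and
  binary grade from ordinal-logistic models whose linear predictor is the
  latent six-feature count (slope 0.8), with cutpoints anchored so the
  marginal grade mix approximates 31/44/25% and 67/33% at the mean count.
  Grade therefore carries real but noisy severity signal, which is what
  makes "score + grade ≥ score alone" reproducible in simulation.

Everything is driven by one integer seed; identical configs give
byte-identical studies (event and follow-up times are rounded to 3
decimals so CSV round-trips are exact). The generated truth frame exposes
latent features and per-case hazards, closing the parameter-recovery loop:
Cox fits on generated cohorts recover the generating hazard ratios.

What the generator does *not* emulate: treatment-dependent hazards (the
published cohort's moderate-grade lesions transformed more often than
severe ones, attributed to treatment differences — this non-monotonicity
is not modelled), per-site effects, feature definitions drifting between
raters, and any real histology. Passing tests therefore demonstrate the
statistical machinery is correct under the stated generative model, not
that the published cohort-level AUROCs or risks are reproduced — those
require the undeposited per-case data.

## Problem sizes and numerical choices

Stochastic checks run at sizes chosen to make Monte-Carlo error small
relative to the asserted tolerance: pooled-prevalence calibration at
n = 5000 (±2 pp), single-cohort hazard-ratio recovery at n = 5000 (±15%),
median recovery and CI coverage over 100 replicates at n = 1000 (median
within 10%, coverage within [90%, 99%] of nominal 95%), DeLong null
calibration over 1000 simulated pairs at n = 100 (rejection rate within
[3%, 7%] at α = 0.05), and the unit-suite recovery grid at 40 replicates of
n = 600. Agreement oracle equivalence enumerates all rater pairs on 500
random panels (n ≤ 50, r ≤ 5) and asserts equality to 1e−12.

Report rounding is 2 dp, half away from zero, matching how agreement
tables are conventionally printed. Percentages with zero denominators are
NaN internally and an em dash in CSV exports, never 0%. The pipeline's
report bundle (JSON) is the single source of truth: every CSV artefact is
regenerated from it, and a rerun with the same seed reproduces the bundle
byte-for-byte.

## Known limitations

* The intraoral-site covariate is never modelled jointly with the scores
  (sparse site categories; out of scope as in the motivating analysis).
* Consensus is majority-rule only; no latent-class (Dawid–Skene) raters.
* No multivariable Cox over all features, no proportional-hazards
  diagnostics, no optimism correction for the in-sample AUROCs.
* The exponential baseline hazard and the censoring mixture are modelling
  conveniences; acceptance of the survival machinery rests on parameter
  recovery, not on reproducing any real follow-up distribution.
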