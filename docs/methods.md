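# Methods

`dietspan` implements a complete diet–mortality–life-expectancy analysis as
a tested library: five a priori dietary pattern scores, a longevity
polygenic risk score (PRS), Cox proportional-hazards models of all-cause
and cause-specific mortality with trend, interaction and joint analyses,
and a period life-table engine that converts hazard ratios into life
expectancy and years of life gained. A synthetic cohort generator with
known ground truth makes every stage testable end to end without any
individual-level data.

## Synthetic cohort model

**Latent diet factor.** Each participant carries one standard-normal latent
"diet quality" factor `z`. The log intake of every food group and nutrient
is normal with a field-specific location, a loading on `z`, and independent
residual noise; intakes are therefore lognormal and nonnegative, with
assessment-level multiplicative noise (log-SD 0.20 by default) around the
participant-level value. Healthy foods (whole grains, fruits, vegetables,
nuts, legumes, fish, fiber, polyunsaturated fat) load positively, adverse
foods (red and processed meat, sugar-sweetened beverages, sweets, sodium,
trans fat, glycemic index) negatively. Loadings are scaled so that the five
computed scores inter-correlate at Spearman ρ ≈ 0.63–0.83 — the
moderate-to-high range typical of a priori diet scores computed on one
cohort. Alcohol is zero-inflated (25% never-drinkers by default).

Because the mortality ground truth acts on `z`, not on any single score,
all five indices are imperfect proxies of the same behaviour — mirroring
reality and making relative attenuation observable.

**Genotypes and PRS.** Dosages are independent Binomial(2, maf) draws; the
PRS is the weighted allele sum with weights in years of life gained per
effect allele. The shipped default (19 SNPs, maf 0.6, weight 0.772) gives
analytic binomial moments mean 17.60 and SD 2.33 years, matching the scale
on which such scores are reported. SNP identities and weights are inputs,
never hard-coded; effect-allele orientation is the weight table's
responsibility.

**Survival.** The hazard is Gompertz in attained age with sex-specific
parameters, multiplied by log-linear effects of the standardised latent
diet factor (default HR 0.85 per SD, protective) and the standardised PRS
(default HR 0.93 per SD):

    λ(t) = α_sex · exp(γ·(age₀ + t)) · exp(β_d·z + β_g·z_PRS)

Event times come from the closed-form inverse of the Gompertz cumulative
hazard (exponential when γ = 0), with administrative censoring at 11 years.
This data-generating process is exactly proportional-hazards on the
follow-up time scale with a log-linear age effect, so a Cox model with age
and sex as covariates is correctly specified and recovery of β_d is a
meaningful known-truth check. Defaults (α_male 1.8e-5, α_female 1.2e-5,
γ 0.095, age ~ N(58.3, 7.8) truncated to 40–72, 43.6% male) produce roughly
6–9% deaths over follow-up in a middle-aged cohort. Cause of death is
assigned from a fixed multinomial mix independently of covariates; the
cause-specific machinery needs only this structural support.

**Data flaws.** A configurable fraction of participants receives a single
dietary assessment (the default assessment-count distribution includes 25%
with one), implausible energy intakes, or prevalent-disease flags, so the
exclusion rules always have work to do.

**Randomness.** One root seed fans out through named `SeedSequence` child
streams (demographics, intakes, genotypes, survival, flaws, causes); adding
a component never perturbs the draws of another, and identical seeds give
byte-identical cohorts.

## Cohort preparation

Exclusions are conjunctive and applied in a fixed order: missing sex (an
explicit bucket, never silently kept) → fewer than two assessments →
implausible mean energy (<800 or >4200 kcal/day in men, <600 or >3500 in
women; applied to the mean across assessments because the exposure is the
averaged profile, with a per-assessment switch) → prevalent cardiovascular
disease or cancer → missing genotype when a genetic subset is requested.
The retained set is order-invariant; the per-rule counts are not, and the
report reconciles exactly.

Averaging is the arithmetic mean over assessments; a missing nutrient value
on one day is averaged over the non-missing days and flagged. Person-years
run from the last dietary assessment to death, loss to follow-up, or the
administrative censoring date (2022-11-30 by default), using 365.25-day
years; deaths after the administrative end are censored. ICD-10 codes map
to five cause classes (I00–I99 cardiovascular, C00–C97 cancer, G00–G99
neurodegenerative, J00–J99 respiratory, otherwise "other"). Alcohol
covariate bands default to the finer categorisation (0, 0.1–5, …, >30
g/day) used in fully adjusted models; the coarser variant is available.

## Dietary scoring

Each index is a declarative `ScoringSpec` — components, each mapping one or
more intake fields (summed) to points through an absolute-anchor linear
rule, an intermediate-best tent rule, or a cohort-relative quintile rule.
The spec validator proves range closure: component extremes must sum to the
declared range (AHEI-2010 0–110, AMED 10–50, hPDI 17–85, DASH 8–40, DRRD
9–45).

Published tables of per-component cut-offs for this kind of analysis are
usually cohort-specific; the shipped defaults encode the canonical
definitions of each index and every anchor is overridable:

* **AHEI-2010** — 11 components, 0–10 points by absolute anchors
  (vegetables 0→5 servings/day, fruit 0→4, whole grains 0→75 g/day for
  women and 0→90 for men, and so on), with sugary drinks, red/processed
  meat, trans fat and sodium reverse-anchored. Sodium uses fixed anchors
  (1112 and 3337 mg/day, the extreme decile medians of the index's source
  cohort) rather than recomputed cohort deciles, keeping the component
  anchor-linear. Alcohol is intermediate-best (full points at moderate
  intake, zero for heavy drinking) with never-drinkers earning 2.5 points.
* **AMED** — 10 components, 1–5 points by sex-specific cohort quintiles;
  red meat and processed meat are separate reverse-scored components, and
  alcohol is intermediate-best (5–25 g/day earns full points) because more
  alcohol is never better. This 10-component 1–5 variant reproduces the
  10–50 range.
* **hPDI** — 17 components by cohort quintiles: 7 healthy plant foods
  scored positively; 5 less-healthy plant foods and 5 animal-food groups
  reverse-scored.
* **DASH** — 8 food groups by cohort quintiles; sodium, red/processed meat
  and sugar-sweetened beverages reversed.
* **DRRD** — 9 components by cohort quintiles, including cereal fiber and
  glycemic index directly; GI, SSB/juice, red/processed meat and trans fat
  reversed.

Only AMED stratifies quintiles by sex; the others use whole-cohort
quintiles.

**Tie rule.** Quintile (and tertile) points use average ranks: tied values
share the mean of the ranks they occupy and rank r of n maps to group
⌈k·r/n⌉. All tied values get identical points, groups are near-equal apart
from ties, and the rule is deterministic. A stratum with fewer than five
distinct values is an error directing the user to an absolute-threshold
rule. Scorers are scikit-learn transformers: `fit` stores the cohort
distributions, `transform` ranks new profiles against the fitted cohort
(reproducing the average-rank convention exactly on the training data).

## Survival models

All fits use lifelines' Cox partial likelihood with Efron tie handling
(heavy ties are expected with rounded follow-up, and the choice is
standard). Two covariate sets exist: model 1 (age continuous, sex) and
model 2 (model 1 plus ethnicity, education, deprivation quintile,
assessment centre, smoking, physical activity, BMI class, total energy,
prevalent dyslipidemia/hypertension/diabetes, PRS tertile, 10 ancestry
components, genotyping batch, and alcohol bands for the three indices
without an alcohol component). "Unknown" levels are ordinary dummy
categories, never dropped.

* **Quintile models** report HR (95% Wald CI) per quintile against the
  lowest, with events and person-years per level; a level with zero events
  is an error suggesting level merging.
* **Trend** recodes each participant at their quintile's median score and
  reports the Wald p of that continuous term.
* **Per-SD** effects standardise the raw score by its sample SD (ddof 1).
* **Dose-response** uses a restricted cubic spline with three knots at the
  10th/50th/90th percentiles (one nonlinear basis column, the standard
  natural-spline construction, implemented directly and tested against the
  textbook formula); the curve is referenced to the cohort median score and
  the Wald p of the nonlinear coefficient tests departure from linearity.
* **Interaction with PRS**: multiplicative interaction is a likelihood-
  ratio test adding a single ordinal(quintile)×ordinal(tertile) product
  term to the adjusted model; additive interaction is RERI = HR₁₁ − HR₁₀ −
  HR₀₁ + 1 computed on the extreme 2×2 (top vs bottom diet quintile, high
  vs low PRS tertile, middle categories excluded from the 2×2 view) with a
  delta-method CI from the coefficient covariance. The identity holds
  exactly at the point estimates by construction. The dichotomisation is a
  documented, configurable choice.
* **Joint classification**: 15 dummy-coded diet-quintile × PRS-tertile
  cells, reference = lowest quintile + low PRS.
* **Stratified analyses** fit per stratum (the modifier leaves the
  covariate set) and report a pooled LRT on modifier×trend product terms.
* **Food groups** are modelled one at a time per SD; leave-one-out
  substitution models include every standardised food group except the
  omitted one plus the total, reading the coefficient of group A as
  substituting A for the omitted group.
* **Cause-specific** fits censor deaths from other causes (cause-specific
  hazards). A Fine–Gray competing-risks refit is out of scope: no installed
  routine provides it, and cause-specific hazards carry the analysis.
* Proportional hazards can be inspected via a library-delegated Schoenfeld
  test (`schoenfeld_check`); it is reported, never gating.

## Life-table engine

Hazard ratios act on rates, not probabilities: each annual death
probability q is converted to a rate m = −ln(1−q), the reference-group rate
solves m_ref = m / Σ_g p_g·HR_g with banded prevalences expanded to single
years piecewise-constantly, group rates are HR_g·m_ref, and group
probabilities 1 − exp(−m_g). This keeps probabilities below 1 for moderate
HRs and conserves the prevalence-weighted marginal rate exactly (checked to
1e-9 at every age). Life expectancy at a start age (45 by default, with
50/55/60 variants) accumulates cumulative survival with a half-year credit
in the year of death (a_x = 0.5, standard abridged-table practice), the
table closing at age 100. Years gained is the difference vs the reference
group.

CIs propagate hazard-ratio uncertainty only: log-HRs are drawn from the
normal distributions implied by each group's CI, independently across
groups by default (a covariance hook exists), the whole engine is rerun per
draw, and percentile 2.5/97.5 bounds are reported. Fewer than 100 draws
records a warning in the output metadata. Population life-table and
prevalence uncertainty are not propagated — a documented limitation.

## Validation and problem sizes

The test suite checks every operation against independent oracles:
pairwise-counting rank points, a plain-Python rank-and-sum scorer (exact
agreement on cohorts of ~200), the events/person-years rate-ratio estimator
for two-level exponential data (2%), the geometric closed form for
constant-hazard life expectancy (1e-9), and algebraic RERI identities
(exact). Known-truth recovery uses n = 20,000 cohorts: the per-SD HR must
average within 2% of the generating 0.85, and the Monte-Carlo CI for the
Q5-vs-Q1 life-expectancy gain must cover the gain implied by the generating
hazard ratios in at least 90% of replicates. Null calibration simulates
cohorts with both effects at zero and requires trend, nonlinearity and
interaction p-values to pass a Kolmogorov–Smirnov uniformity test. Problem
sizes in the shipped suite (10–30 recovery replicates, 60 calibration
replicates of n = 1500) were chosen so the full suite runs in about two
minutes on one CPU; they are reduced-replicate versions of the same checks
run at larger sizes during development.

## What the generator does not emulate

Real food-frequency distributions and food-composition lookups; linkage
disequilibrium between SNPs; time-varying diet; covariates correlated with
diet quality (education, smoking and the rest are drawn independently, so
confounding adjustment is exercised structurally, not substantively);
informative censoring. Passing tests therefore demonstrate the statistical
machinery is correct under the stated model, not that any particular
epidemiological estimate transfers to real cohorts — reproducing published
cohort-specific estimates would require the original individual-level data
and national life tables.
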