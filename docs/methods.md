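# Methods

## Scope and model

`grschd` evaluates weighted multi-marker genetic risk scores (GRSs) as
additions to classical 10-year coronary heart disease (CHD) risk
assessment in multi-ancestry cohorts. The analytic chain it implements:

1. **Score construction.** GRS = Σᵢ βᵢ·dᵢ + w_hap·h, where βᵢ is a
   published per-allele log-hazard effect size, dᵢ ∈ {0,1,2} the
   effect-allele dosage (best-guess rounded when imputed), and h a term
   for the 4-variant *ALOX5AP* haplotype B (weight w_hap = 0.131). Two
   compositions are supported: a 12-unit score (8 weighted variants + the
   haplotype) and a 51-unit score (47 + haplotype). Variants imputed with
   r² < 0.85 are excluded at read time.
2. **Baseline clinical risk.** The sex-specific categorical Framingham
   function of Wilson et al. (1998): a Cox linear predictor over age and
   JNC-V/NCEP categories of total cholesterol, HDL-C, blood pressure,
   diabetes and current smoking, mapped to a 10-year probability via
   p = 1 − S₀(10)^exp(L−G). Probabilities fall in four clinical bands:
   <10%, 10–14.9%, 15–19.9%, ≥20% (left-closed cuts, so 0.10 is
   intermediate-low and 0.20 is high).
3. **Association.** Cox proportional-hazards suites per ancestry stratum:
   the score per SD (family 1) or as tertile contrasts (family 2), with
   cumulative covariate tiers a–d (principal components; + risk-function
   covariates; + family history; + education, BMI, treatment flags,
   alcohol). Stratum estimates are pooled by inverse-variance
   fixed-effects meta-analysis with Cochran's Q / I².
4. **Incremental value.** Harrell's C, Hosmer–Lemeshow calibration over
   risk deciles, category-based NRI and IDI on the 10-year horizon, and a
   two-stage screening comparison (treat all intermediates vs treat only
   up-reclassified intermediates, 24% assumed statin relative risk
   reduction).

## Handling censoring at the 10-year horizon

Follow-up averages ~8.7 years, so 10-year event status is not observed
for everyone. All horizon quantities use Kaplan–Meier (KM) machinery:

* `km_survival(t*, extrapolate=True)` extends the product-limit curve
  beyond the last observed time with a constant hazard equal to the
  average hazard over the final observed year.
* Reclassification cells receive expected events = cell n × cell KM event
  probability at 10 years; the NRI's event/nonevent masses come from these
  expectations.
* The IDI weighs each subject by a fractional event mass: 1 if an event is
  observed by the horizon, 0 if followed event-free past it, otherwise the
  KM conditional probability of an event between the censoring time and
  the horizon. On censoring-free data every metric reduces exactly to its
  direct counting definition (tested).
* Bootstrap confidence intervals resample subjects and recompute metrics
  end to end, KM steps included, so KM uncertainty is in the interval.

## Bias-corrected intermediate NRI

Restricting the NRI to subjects whose *baseline* category is intermediate
selects on the base model and is optimistically biased: refitting noise
alone reclassifies intermediates asymmetrically. The correction subtracts
a resampling null — the intermediate NRI obtained when the updated model
is replaced by the base specification refit on bootstrap-resampled data,
averaged over `b_null` replicates (default 100). This is an
interpretation of the cited correction idea, not a transcription of a
formula: the null term is genuinely nonzero (≈ −0.1 to −0.2 on its
nonevents component in our synthetic cohorts), precisely because category
membership was defined on the base model. Under the null — an "updated"
model that is just the base specification refit on resampled data — the
corrected NRI averages to ~0 (tested); with a truly informative marker it
stays positive.

## Synthetic-data generator

The generator (`cohort_sim`) emulates the statistical structure the
analysis assumes, not any particular person-level dataset:

* **Genotypes.** Independent Hardy–Weinberg dosages Binomial(2, f) per
  variant; the 4 haplotype variants share a per-person draw of two
  haplotypes (risk haplotype with probability q = 0.15 by default, else
  background alleles with frequency adjusted to preserve the marginal
  allele frequency). No LD beyond the haplotype is simulated.
* **Weights.** A 55-row table: 51 candidate variants with effect sizes
  U(0.04, 0.22) (4 of them flagged at imputation r² = 0.80 and hence
  excluded, leaving 47), 8 carrying the 12-unit flag, plus the 4 haplotype
  members with their published effect alleles.
* **Covariates.** Per-ancestry truncated-normal/Bernoulli/categorical
  draws matching the published baseline table of the target population
  (African-American / Latino / East-Asian mix 2,089 : 4,349 : 4,804);
  principal components standard normal; covariates mutually independent
  within ancestry because only marginals are published.
* **Outcomes.** Weibull proportional hazards, shape 1.2, with a linear
  predictor over standardized covariates (default per-SD log-HRs: age
  ln 2, male ln 1.8, SBP ln 1.3, TC ln 1.2, HDL ln 0.8, current smoking
  and diabetes ln 1.5) plus the standardized score (default ln 1.17 per
  SD, the pooled model-1a estimate). The scale is calibrated numerically
  so the expected cumulative event fraction by year 9 is 4%
  (≈ 450/11,242). Observed time is the minimum of the event time,
  exponential dropout (0.005/year) and staggered administrative censoring
  U(7.95, 10.25) years, giving ≈ 8.7 years mean follow-up.

What passing tests on these cohorts shows: the estimators are correct and
unbiased under the generating model's assumptions (proportional hazards,
independent censoring, HWE, covariate independence). What they do not
show: robustness to LD, admixture-PC-genotype coupling, informative
censoring, or measurement error in real electronic-health-record data.

## Experiment sizes and numerical choices

* Parameter recovery runs 20 seeds × 20,000 subjects with the score as
  the only effect. Follow-up is extended (administrative censoring at 40
  years, no dropout, ≈ 4,300 events) so the per-seed standard error
  (~0.015 on the log scale) is small against the ±0.04 acceptance band —
  the band then measures bias, which is what a recovery experiment is
  for. Null confidence-interval coverage runs 200 replicates of n = 1,500
  under the study-condition censoring.
* Cox fits use lifelines (Efron tie handling — standard for
  electronic-record-scale ties; exact replication invariance would
  require Breslow). Non-convergence and separation raise a distinct
  error.
* The proportional-hazards diagnostic is the Schoenfeld-residual score
  test against follow-up time (identity transform), the score-test
  analogue of a score × time interaction term.
* Tertiles: within-ancestry cuts at the 33.33%/66.67% empirical quantiles
  (type-7 interpolation), ties assigned to the lower tertile.
  Standardization uses the n−1 denominator, within ancestry.
* Hosmer–Lemeshow: 10 risk-decile bins, observed events from KM at 10
  years, χ² = Σ(O−E)²/(E(1−E/n_b)), reported against bins−1 = 9 degrees
  of freedom to match the reporting convention. Tied risks collapse bins
  (logged). With known true probabilities the null distribution lies
  between χ²₉ and χ²₁₀, so the nominal-rate test uses a tolerance band
  rather than exact 5%.
* Meta-analysis uses z = 1.959964 internally; rounding happens only at
  report time. Standard errors reconstructed from printed 2-decimal CIs
  reproduce the published combined rows at print precision for the rows
  the package asserts; one row (51-variant score, tertile 3, model 2a)
  pools to 1.51 vs a printed 1.52 — within the resolution of the printed
  inputs.
* Screening arithmetic rounds events prevented (C = 0.24·B) half-up to
  one decimal, then NNT (D = A/C) to the nearest integer, then the
  efficiency ratio to one decimal. Two published one-stage NNT cells are
  not reproducible from their printed inputs under any standard rounding
  (473/9.8 ≈ 48 vs 47; 876/11.5 ≈ 76 vs 73 — likely computed from
  unrounded internal values); the package reports computed values and
  treats published NNTs as inputs where a ratio of published cells is
  requested.
* Missing dosages: a sample missing more than 10% of a score's variants
  gets no score (NaN); otherwise missing dosages are imputed at twice the
  effect-allele frequency of the non-missing samples, keeping scores
  comparable across samples.
* Haplotype scoring defaults to `presence` (a single 0.131 contribution
  whenever every constituent dosage is ≥ 1, i.e. the risk haplotype may
  be carried); `min_dosage` is offered because unphased dosages cannot
  confirm the cis configuration, and it upper-bounds the copy count.

## Known limitations

* Strand-ambiguous (A/T, C/G) variants are an error in strict mode; there
  is no frequency-based strand inference.
* The 10-year extrapolation rule (constant final-year hazard) is a
  package choice; published analyses acknowledge extrapolating without
  specifying a rule.
* No competing risks, no time-varying covariates beyond the diagnostic,
  no random-effects meta-analysis (the strata share one source
  population), no cost-effectiveness modeling.
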