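# Methods

This note documents the models, conventions and numerical choices behind
`prsjoint`, and what the synthetic cohort does and does not establish.

## Synthetic cohort generator

### Genotypes (Gaussian copula)

Variants are laid out in blocks (default 10 variants, 5 kb spacing) assigned
cyclically to chromosomes 1–22; successive blocks on a chromosome sit 3 Mb
apart, so no block straddles a chromosome, every block is < 1 Mb wide, and
chromosome 6 blocks start at 28.45 Mb so that some variants fall inside the
MHC window (chr6:28,477,797–33,448,354) and exercise the exclusion path.

Each individual carries two independent haplotype latents per block,
stationary AR(1) Gaussians with correlation `ld_rho^distance`. A haplotype
carries the counted allele when its latent falls below the Φ⁻¹(MAF)
quantile, so marginal genotypes are Binomial(2, MAF) — exact Hardy–Weinberg
— and dosages are hard calls in {0, 1, 2}. MAFs are uniform on
`maf_range` (default 0.05–0.5). The dosage-scale correlation implied by the
copula is the standardised bivariate-normal orthant probability, which is
*smaller* than the latent correlation (e.g. latent 0.9 → dosage r ≈ 0.70 at
MAF 0.3); the test suite checks the panel against this orthant-probability
oracle rather than against the latent value.

### Discovery summary statistics

Sampled analytically rather than by simulating a discovery cohort: for each
variant, β̂ ~ N(β_marginal, se²) with the binary-trait approximation
se = 1/√(2·N·MAF·(1−MAF)·φ·(1−φ)), φ the discovery case fraction
(default 0.25, N = 100,000), and a two-sided Wald p. The marginal effect of
an LD partner is the projection β_marginal = Σⱼ r·βⱼ using the *latent*
AR(1) correlation as r. This is an approximation — the dosage-scale
correlation is attenuated relative to the latent one — so tagged variants
carry slightly optimistic weights; it is exact for LD-free configurations,
which is what the calibration experiments use. `discovery_n = inf` gives
the noise-free limit (β̂ = β_marginal, p = 0 for associated variants).

### Lifestyle fields

Raw questionnaire-style fields are generated so the *derived* indicators hit
configured prevalences (defaults follow the emulated cohort's descriptive
table: 61% non-smoking, 71% regularly active, 78.1% moderate BMI, 6% no
alcohol):

* smoking — 30% former smokers with Uniform(0, 40) years since quitting
  (so a quarter qualify as long-quit), never-smoker share solved to hit the
  target; valid for targets in (0.075, 0.775);
* alcohol — current-drinker share and within-current frequency solved so
  that "current AND more than monthly" has the complementary prevalence;
* activity — actives drawn from a mixture (vigorous-led, or a combination
  satisfying 2·vigorous + moderate ≥ 150), inactives constrained below every
  clause of the rule;
* BMI — log-normal with σ = 0.09 and location solved by root-finding so the
  [18.5, 24) window carries the configured mass (upper root, giving a
  population mean ≈ 24);
* diet — six independent log-normal component frequencies. The k-of-6
  median rule pins the derived prevalence at ≈ 0.344 for independent
  continuous components, which matches the emulated table's 33.7%, so diet
  intentionally has no prevalence dial.

### Disease

One linear predictor η = (G − Ḡ) + Σ_f γ_f L_f + β_age z_age + β_sex female
(G the true genetic score; optional product term available) drives both
designs, mirroring parallel case-control and prospective analyses:

* prevalent-at-baseline: Bernoulli(expit(α + η)) with α solved by
  root-finding so the population mean equals `baseline_prevalence`;
* incident: exponential onset with rate h₀·exp(η); administrative censoring
  uniform over `censor_year_range` (default 8–14 years, median ≈ 11).

Defaults are calibrated to the emulated cohort: OR 1.4 per true-score SD
(causal effects rescaled to the analytic score variance; exact when
LD-free), lifestyle ORs 0.70 (non-smoking), 0.75 (activity), 0.72 (moderate
BMI), age ≈ +3 years in cases, ~67% female cases, prevalent 0.35% and
incident ≈ 0.9% (h₀ = 1.1e-3/yr; the population mean of exp(η) is ≈ 0.74
under the default lifestyle mix, which the calibration accounts for).

With rare outcomes both components are log-linear in η, so a logistic fit
of ever-disease recovers the generative coefficients to second order in the
prevalence; the parameter-recovery experiment confirms nominal CI coverage
at n = 50,000.

### What the generator does not emulate

Real human LD maps and allele-frequency spectra; imputation dosage
uncertainty and INFO scores; relatedness and population stratification
(PCs are pure noise covariates); time-varying lifestyle; diagnosis-code
phenotyping; correlated lifestyle factors (independent unless configured).
Passing tests therefore certify the *statistical machinery* — selection,
scoring, model fits, interaction estimates — under a controlled generative
model, not performance on real biobank data.

## Analysis conventions

* **QC filter**: MAF strictly > 0.02, HWE p > 1e-7 (1-df chi-square against
  p², 2pq, q²), call rate ≥ 0.95. The source description of the missingness
  filter ("missing ratio > 0.95") is garbled; it is implemented as a
  call-rate floor and flagged here.
* **LD r²** is squared Pearson correlation of dosages (composite LD,
  pairwise-complete over missing entries) — the convention for unphased
  data. Constant vectors raise an error; clumping treats them as r² = 0.
* **Clumping** is greedy: smallest p first, ties broken by (chrom, pos);
  the window is ± `window_bp` on the same chromosome. The post-hoc
  invariant (no two survivors within a window share r² ≥ threshold) is
  asserted on every run.
* **Scores** are unnormalised weighted sums (no division by the number of
  alleles); missing dosages are mean-imputed (2 × allele frequency);
  weights are harmonised to the panel's counted allele (swapped alleles
  flip the beta; mismatched pairs and variants absent from the panel are
  dropped with warnings; same-strand files assumed).
* **Standardisation** uses the whole cohort (train + test), per the design
  being modelled; quartile/decile groups default to whole-cohort cuts as
  well (configurable to test-only via `PipelineConfig.group_population`).
  Quantiles are type-7 (linear interpolation); values exactly at a cut go
  to the lower group; fully tied scores all land in "low" with a warning.
* **Threshold selection** evaluates candidates in cutoff order (loosest
  first), primary criterion smallest score-term p, tie-break larger AUC of
  the score+covariates model, remaining ties to the earlier candidate; the
  full per-threshold table is always emitted so the choice is auditable.
* **Regression**: logistic fits are Newton ML (tolerance 1e-10, LBFGS
  fallback on singular Hessians) with aliased columns dropped by a QR rank
  test and perfect separation raised as an explicit error; Cox fits use the
  partial likelihood with Efron tie handling (many tied integer follow-up
  times make Breslow biased on simulated data). All CIs are two-sided 95%
  Wald intervals on the log scale.
* **BMI window** is half-open [18.5, 24.0) to avoid double counting at
  category edges (both-closed and the 18.5–25 sensitivity window are config
  switches). The non-smoking rule is never-smokers or former smokers quit
  ≥ 30 years (a "no current smoking" variant is available). The activity
  "equivalent combination" is 2·vigorous + moderate ≥ 150 min/week (WHO
  convention), with an additional both-intensities-on-≥5-days clause. The
  healthy-diet rule is ≥ 4 of 6 food groups on the healthy side of cohort
  medians (diet is not part of the 3-factor index). Missing lifestyle
  fields propagate to exclusion, never imputation.
* **RERI/AP** come from indicator coding (G-only, L-only, both) against the
  doubly-unexposed reference; the delta method gives default CIs with a
  parametric bootstrap (MVN draws from the coefficient covariance) as an
  option. AP = RERI / RR₁₁ identically.
* **Splines**: natural cubic basis, k − 1 columns, knots at Harrell
  percentiles (5/35/65/95 for the default 4 knots; 3–5 configurable).
* **Scan**: per-variant logistic fit with a dosage × lifestyle product
  term; non-converged or aliased variants are flagged with missing p, not
  raised; raw p-values are reported without multiplicity correction (the
  analysis this mirrors reported nominal p < 0.05 hits as weak evidence).
* The batch/chip covariate ambiguity in the source design is resolved as a
  single categorical batch covariate.

## Calibration experiments (`prsjoint.validation`)

* **RERI null coverage** — 200 replicates of n = 20,000 with exactly
  additive risks (p = 0.01 + 0.01·G + 0.008·L, so risk-scale RERI = 0);
  outcomes kept rare so the OR-scale RERI is essentially risk-scale. The
  delta-method 95% CI covers zero at its nominal rate.
* **Parameter recovery** — 50 replicates of n = 50,000 at the calibrated
  conditions (LD-free panel so the recorded truth is exact); the adjusted
  logistic fit's CIs cover the generative per-SD and lifestyle effects
  ≥ 90% of the time, and the joint grid's high/unfavorable cell exceeds the
  intermediate/moderate cell.
* **Threshold selection** — selection among the five cutoffs cannot be
  separated by a homogeneous architecture (discovery z-scores carry unit
  noise, so a looser grid that gains true borderline associations is
  genuinely better). The designed architecture that makes 5e-7 uniquely
  optimal therefore has three parts: a small strong tier (z ≈ 9) passing
  every cutoff, a large borderline tier (z ≈ 5.8) straddling the 5e-8
  boundary so the strictest grid clips real signal, and a genome-scale null
  background (24M variants) whose chance passers dilute the looser grids.
  Tier sizes were set by signal/variance bookkeeping so both selection
  margins exceed ~2 SD of between-replicate noise. Null passers are sampled
  from their exact truncated-tail distribution and dosages materialised
  only for variants entering a grid (equivalent by construction for an
  LD-free background). Training selection picks 5e-7 in ≥ 90% of 50
  replicates.

## Problem sizes

The shipped analyses use desk-scale cohorts chosen as the package's
standard demonstration sizes: 20,000 × 2,000 for the demo drivers,
50,000 × 2,000 for `scripts/acceptance.py`, 50,000 × 120 (LD-free) per
recovery replicate, 12,000 training rows per selection replicate. All
estimators are O(n) per fit and scale to biobank sizes.

## Known limitations

* The latent-correlation projection slightly overstates tagged-variant
  weights under strong LD (see above); calibration experiments avoid this
  by construction, and the C+T pipeline is insensitive to it because
  clumping removes tight LD partners.
* OR- and HR-scale estimates coincide only for rare outcomes; the test
  suite asserts agreement within 15% at incidence ≤ 1%.
* The emulated cohort's published sex-specific prevalences (1.59%/0.91%)
  do not reproduce exactly from its own printed counts (2,361/150,939 ≈
  1.56%); summaries here always recompute percentages from counts rather
  than storing them.
* Delta-method RERI CIs are symmetric and can be anticonservative for very
  sparse cells; the bootstrap option is preferable there.
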