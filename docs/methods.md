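# Methods

## Model and estimators

The package implements one-sample Mendelian randomization with a binary
exposure proxy (insulin resistance, IR) and a right-censored survival
outcome (colorectal cancer, CRC). The exposure side of each instrument is
a per-allele log odds ratio β_X from logistic regression of the binary IR
phenotype; the outcome side is a per-allele log hazard ratio β_Y from a
Cox proportional-hazards model. The causal estimand is the log hazard
ratio per unit increase in the log-odds of IR, estimated per instrument by
the Wald ratio β_Y/β_X and pooled by fixed-effect inverse-variance
weighting.

**Ratio confidence intervals.** Published per-SNP tables print the outcome
HR with a 95% CI but no SE. The default CI for a Wald ratio therefore maps
the outcome CI bounds directly: log bounds divided by β_X and re-sorted
(division by a negative β_X flips the interval). This is first-order — it
ignores exposure-side uncertainty — and is exact for the arithmetic used
in such tables; a delta-method alternative (`ci_method="delta"`) adds the
exposure variance term. The SE implied by a printed CI uses z = 1.96, not
the exact 97.5% quantile, to match table arithmetic; other confidence
levels use exact quantiles.

**Pooling.** Fixed-effect IVW is the default because single-cohort
instrument sets are small and the per-phenotype groups here have 2–6
members; a DerSimonian–Laird random-effects option exists but is not
default. A single-estimate "pool" reproduces its component exactly,
including the asymmetric ratio CI. Cochran's Q is reported with its
χ²(k−1) p-value; with one instrument the p-value is undefined and is
emitted as an absent marker ("N/A" in pretty tables, NaN in the
machine-readable ones), never zero.

**Sample overlap.** With exposure and outcome measured in the same
participants, the two regression stages are correlated. The package
adjusts by inflating the pooled variance by f(ρ) = 1/(1−ρ²), where ρ is
the Spearman correlation between the IR phenotype and the CRC indicator
(estimable from cohort data via `rho="estimate"`). f is a pragmatic
reconstruction — it is 1 at ρ = 0, increases in |ρ|, and leaves the point
estimate untouched. Published CI widths that embed an unknown overlap
adjustment are therefore not reproduced, only point estimates.

**MR-Egger.** Weighted least squares of β_Y on β_X with a free intercept,
weights se(β_Y)⁻². Standard errors use the unscaled (X'WX)⁻¹, consistent
with fixed-effect weighting (so an exact fit yields p_intercept = 1 rather
than 0/0); a multiplicative-overdispersion option (`scale="mult"`) applies
max(1, σ̂²). The intercept p-value uses a normal reference by default, with
a Student-t option for very small instrument counts. Constraining the
intercept to zero reproduces the IVW slope exactly (tested).

**Instrument strength.** Per SNP, T² = (β_X/se(β_X))²; when only a
p-value is printed, T² = z² with z the two-sided normal quantile. The set
passes when ΣT² exceeds 10 units (the conventional weak-instrument
threshold). A p-value of exactly 1 implies z = 0 and an infinite SE; such
SNPs are flagged for exclusion with a warning.

## Instrument QC

Stages run in order: missing-call rate (< 3%), Hardy–Weinberg exact test
(p ≥ 1e-4), imputation quality (R² ≥ 0.6), genome-wide significance
(p < 5e-8, strict), and greedy LD pruning (pairwise r² < 0.1). Boundary
conventions follow how the thresholds are printed: significance and
missingness strict, HWE and imputation inclusive. LD pruning orders
candidates by ascending exposure p-value (most significant wins) because
no prioritization is published; the kept set provably contains no pair at
or above the r² threshold. The HWE test is the exact conditional test
(probabilities of heterozygote counts no more likely than observed, given
allele counts), validated against full enumeration. The obesity
pleiotropy screen drops SNPs whose obesity-association p-value falls
below a configurable nominal 0.05 — a conservative default, since no
threshold is published; SNPs without a p-value are kept with a warning by
default.

## Association scans

Logistic fits use maximum likelihood (statsmodels); separation or
non-convergence flags the SNP and excludes it downstream. Cox fits use
lifelines with Efron's tie approximation (ties are possible after time
rounding; the choice is conventional and documented here because no tie
method is published). Dosages enter additively (per-allele trend), the
standard GWAS coding. Zero-variance covariates are dropped with a
warning. The PH check correlates scaled Schoenfeld residuals with
Kaplan–Meier-transformed event times (lifelines' default transform) and
reports the χ² test per covariate. Subgroup stratification assigns the
boundary value to the ≥ side: obese = BMI ≥ 30 kg/m², active = MET ≥ 10,
high-fat = SFA ≥ 7.0% of calories.

## Synthetic cohorts

The generator emulates the structure of an ~11,000-woman postmenopausal
cohort. Defaults: n = 5,000 (a practical scale-down of 11,078); 13
independent SNPs tagged 4/3/6 to FG/FI/HOMA-IR; alternative-allele
frequencies spanning 0.001–0.95; binary IR per phenotype from a logistic
model with intercept tuned to 30% prevalence (a typical IR fraction in
postmenopausal populations; the source cohort's IR definition and
prevalence are unpublished, so this is the package's choice); lifestyle
covariates (age, BMI, MET, SFA%) with plausible marginals and 10
standard-normal "principal components" that exercise adjustment plumbing
only; exponential event times with independent uniform censoring tuned by
root-finding so the expected event fraction equals 736/11,078 ≈ 6.6%.

**Causal scale.** The outcome hazard is baseline·exp(θ·L + …), where L is
the total (centred) IR liability — the log-odds scale on which the
per-allele exposure effects are linear. This makes the per-allele outcome
effect exactly θ·β_X, so the Wald ratio and the pooled IVW estimate are
consistent for θ, matching the estimand's interpretation ("per unit
increase in log-odds of IR"). Had θ multiplied the *binary* IR indicator
instead, the per-allele outcome effect would be ≈ (e^θ−1)·Δp per allele
and the ratio would estimate an attenuated quantity (≈ θ·p(1−p) for small
effects) — a scale mismatch, not a causal effect; `simulate_survival`
still accepts any exposure vector, binary included, for experiments that
want that design. Pleiotropy is injected as per-SNP direct log-HRs added
to the hazard; confounding as a latent normal variable entering both the
IR liabilities and the hazard.

What the generator does **not** emulate: linkage disequilibrium between
instruments, imputation dosage uncertainty, real population structure
(the PCs are pure noise), the cohort's sampling design, and any
particular biochemical definition of IR. Passing recovery tests therefore
show estimator correctness under the stated generating model, not
fidelity to the source cohort.

## Numerical choices and degenerate inputs

- z = 1.96 for all 95% intervals (printed-table convention).
- Exposure effects of exactly 0 make the Wald ratio undefined (error);
  SE = 0 components are rejected by IVW (infinite weight).
- Harmonization re-expresses records for the IR-increasing allele;
  palindromic (A/T, C/G) sites warn but do not fail, since strand cannot
  be resolved from summary data alone.
- The exact HWE test guards probability ties with a 1e-12 relative
  tolerance; monomorphic sites return p = 1.
- Event times are floored at 1e-12 to avoid zero follow-up from floating
  underflow.
- Censoring-window root-finding uses Brent's method with a growing
  bracket; it fails loudly if the target event fraction is unreachable.

## Validation experiment sizes

The stochastic calibration tests use 200 cohorts of n = 5,000 with six
instruments at true HR 0.85 (bias and CI coverage of the pooled IVW
estimate) and 500 null cohorts of n = 2,000 (type-I error at nominal
0.05, judged within 3σ binomial bands). Unit-level Monte Carlo checks
(logistic/Cox parameter recovery, confounding robustness) use smaller
replicate counts with tolerance bands tied to their Monte-Carlo standard
errors.

## Known limitations

- The overlap adjustment f(ρ) is a documented reconstruction; published
  CI widths that depend on an unpublished adjustment are out of reach.
- First-order ratio SEs understate uncertainty when instruments are weak;
  the strength gate (ΣT² > 10) is the guard, and the delta method is
  available.
- Fixed-effect IVW assumes a common causal effect across instruments;
  heterogeneity is reported (Q) but not modelled by default.
- The QC stage operates on per-SNP metrics supplied by the caller (or a
  012 dosage matrix); it does not parse full VCF semantics.
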