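# mrsurv

One-sample Mendelian randomization (MR) with a survival outcome.

`mrsurv` estimates the causal effect of genetically determined insulin
resistance (IR) on colorectal cancer (CRC) risk in a single cohort, using
SNPs as instrumental variables. It is aimed at genetic epidemiologists who
have per-SNP summary statistics (odds ratios for a binary IR phenotype,
hazard ratios for CRC) or individual-level cohort data (genotype dosages,
covariates, a right-censored cancer outcome), and want the full analysis
chain: instrument QC, association scans, single-instrument and pooled MR
estimates, and pleiotropy/heterogeneity/strength diagnostics.

## The statistics

For instrument *j* with exposure effect β̂_Xj (log odds ratio of IR per
allele) and outcome effect β̂_Yj (log hazard ratio of CRC per allele), the
single-instrument **Wald ratio** is

    θ̂_j = β̂_Yj / β̂_Xj ,   se(θ̂_j) = se(β̂_Yj) / |β̂_Xj|   (first order),

interpreted as the change in CRC log-hazard per unit increase in the
log-odds of IR. Instruments are combined by fixed-effect
**inverse-variance weighting** (IVW),

    θ̂ = Σ w_j θ̂_j / Σ w_j ,   w_j = se(θ̂_j)⁻² ,   se(θ̂) = (Σ w_j)^(-1/2),

with **Cochran's Q** = Σ w_j (θ̂_j − θ̂)² ~ χ²(k−1) testing heterogeneity,
**MR-Egger** (weighted regression of β̂_Yj on β̂_Xj with a free intercept)
testing directional pleiotropy, and instrument strength summarized as
Σ_j T²_j with T_j = β̂_Xj/se(β̂_Xj), gated at the conventional 10 units.
Because exposure and outcome come from the same participants, the pooled
variance can be inflated by 1/(1−ρ²), ρ the exposure–outcome Spearman
correlation.

Individual-level scans use per-SNP logistic regression (exposure side) and
Cox proportional-hazards regression with Efron ties (outcome side), with
covariate/principal-component adjustment, Schoenfeld-residual PH checks,
and subgroup stratification at BMI 30 kg/m², 10 MET, and 7% of calories
from saturated fat.

## Worked example

The package bundles the 13-instrument summary table of a postmenopausal
IR–CRC study (4 fasting-glucose, 3 fasting-insulin and 6 HOMA-IR
instruments). Pooling all 13 instruments:

```python
from mrsurv import MRModel, load_fixture_table1

exposures, outcomes = load_fixture_table1()
print(MRModel(exposures, outcomes).fit().summary())
```

```
One-sample Mendelian randomization (summary statistics)
============================================================
Instruments:        13
Pooling:            fixed-effect IVW (rho = 0)
HR per unit IR log-odds: 0.950  (95% CI 0.846-1.067)
log HR: -0.0511  SE 0.0590  p = 0.386
Cochran's Q: 21.996 on 12 df  (p_het = 0.038)
------------------------------------------------------------
snp_id              HR   ci_low  ci_high  weight%
rs13431652       0.750    0.478    1.189      6.4
rs560887         0.596    0.366    0.960      5.7
...
```

The pooled hazard ratio of 0.95 (0.85–1.07) says that, across all 13
instruments, a unit increase in genetically conferred IR log-odds is not
significantly associated with CRC hazard; the heterogeneity p of 0.038
reflects the opposing subgroup effects that single instruments carry
(e.g. rs560887, fasting glucose in the high-fat-diet subgroup, gives a
protective Wald ratio of 0.60).

The same analysis from the shell, writing the full result bundle
(per-SNP ratios, pooled table with "N/A" heterogeneity for single-SNP
cells, strength, Egger, forest-plot data, QC log):

```bash
mrsurv reproduce-study --out out/
cat out/pooled.tsv
```

Synthetic cohorts with known ground truth (HWE genotypes, logistic IR
phenotypes, exponential proportional-hazards CRC times at the study's
~6.6% event fraction) come from `mrsurv.simulate`:

```bash
mrsurv simulate --seed 4 --out sim/
mrsurv scan --cohort sim/cohort.tsv --adjust age-pcs-only --out sim/scan.tsv
mrsurv pool --summary sim/scan.tsv --out sim/mr/
```

## Layout

- `mrsurv.summaries` / `mrsurv.core` — summary-statistic containers,
  harmonization, and the MR estimators.
- `mrsurv.model` — `MRModel` / `MRResults`, the fitting interface.
- `mrsurv.instruments` — significance/LD/HWE/missingness/imputation QC
  and the obesity pleiotropy screen.
- `mrsurv.associations` — logistic and Cox scans, PH check, Spearman ρ,
  stratification.
- `mrsurv.simulate` — synthetic cohort generator with `TrueParams`.
- `mrsurv.pipeline` / `mrsurv.cli` — orchestration, result bundles, CLI.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and design choices.
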