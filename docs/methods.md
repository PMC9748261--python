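# Methods

## Generative model

The simulator produces families with a fixed within-family structure:
four grandparents (two founder couples), a father and mother each with a
configurable number of full siblings (default 1), and a configurable
number of children (default 2). Three generations guarantee that both
first-degree (parent-offspring, full sibling) and second-degree
(grandparent-grandchild, avuncular) pairs arise from a single coherent
pedigree; a two-generation mode (founder couple plus a sibship) exists
for analyses that only need siblings. Half-siblings are recognised by the
pair-enumeration code but do not occur under the default structure, which
has no remarriages.

Per disease, liability decomposes as `L = G_s + G_r + C + E`:

* `G_s` — scored genetic component, variance ρ². Founders draw
  N(0, ρ²); a child receives the midparent average plus an independent
  Mendelian-sampling term N(0, ρ²/2). The PRS is `G_s/√ρ²`.
* `G_r` — residual genetic component, variance h² − ρ², transmitted the
  same way and independent of `G_s`; `G = G_s + G_r`.
* `C` — shared environment, variance c². All children of one nuclear
  family receive the same value, composed of a parental-mean part and a
  per-nuclear-family innovation so that the child-parent C-correlation is
  a configurable share (default 0.5, which requires
  `po_env_share ≤ √½` for a valid variance split); full siblings share C
  completely.
* `E` — unique environment, variance 1 − h² − c², independent.

This makes Var(L) = 1 in expectation, corr(PRS, L) = √ρ², and the PRS
correlation of any relative pair exactly twice the kinship coefficient —
the assumption under which the bivariate-normal concordance values
(32.4% / 19.3% at the top decile) are exact. When ρ² = 0 the PRS is
undefined and the column is emitted as missing; PRS analyses then refuse
to run rather than silently standardising a constant. An optional nested
sub-component of `G_s` (variance `rho2_small`) produces a second,
lower-capture score for sensitivity analyses comparing genome-wide-like
and sparse scores.

Onset ages are truncated normal on (0, 100] (default mean 60, SD 12
years), optionally shifted earlier in proportion to liability above the
threshold (`onset_liability_shift`, years per liability unit, default 0).
Mortality is a truncated-normal death age on (30, 105] (default mean 75,
SD 12) independent of disease; with `onset_death_link` enabled, a case's
death age is capped at onset plus a truncated-normal post-onset survival
(default mean 15, SD 5 years), which ties parental death age to familial
liability and is what makes the parental-death age-tertile analysis
informative. A diseased decedent's death record lists the disease among
its causes with probability `cause_of_death_prob` (default 0.7; causes of
death are deliberately lumped, with no distinction between immediate,
contributing and underlying). Death years after the end of follow-up mean
the individual is recorded as alive.

Birth years are uniform over a configurable range for the youngest
generation (default 1945–1975) and shifted one generation gap (default
28 years) earlier per generation above. The default range centres
parental deaths inside the 1964–2018 causes-of-death window so that the
FH_P eligibility machinery is exercised with a realistic mix of
observable, pre-window and post-cutoff deaths.

### Randomness and reproducibility

One root seed drives everything. Every draw site (a component × role
block, e.g. "founder values of G_s for disease 2") gets its own PCG64
stream seeded `[root_seed, site_index]` and draws an
`(n_families, k)` row-major matrix. Family *i* therefore always consumes
the same slice of the same streams: regenerating with a larger
`n_families` reproduces the existing families byte-for-byte and appends
new ones. Identical plans yield byte-identical cohort tables.

## Registry emulation and FH derivation

Registry windows default to the Finnish configuration: hospital
discharges from 1968, cancer diagnoses from 1953, causes of death
1964–2018, follow-up ending 2019. A relative counts as affected
(morbidity or mortality) if their diagnosis year (birth year + onset age)
falls inside the relevant diagnosis window, or the disease appears among
the causes on a death record inside the death-registry window.
Sex-restricted diseases (breast, prostate cancer analogues) restrict both
the index persons and the counted relatives.

FH_1st and FH_2nd use only relatives present in the cohort; individuals
without any relative of the relevant degree stay in the table with FH = 0
but are flagged out of the analysis set, mirroring ascertainment that is
"primarily based on one relative" rather than imputing unobserved family.
FH_P eligibility follows the registry-linkage rule literally: excluded
exactly when both parents died before the death registry opened or both
parental records are missing. A parent dying after the 2018
parental-cause cutoff leaves the record cause-unobservable but the index
person eligible (their FH_P is 0 unless the other parent's record is
positive). Among FH_P-positive individuals, the (youngest) cause-positive
parent's death age is cut into per-disease tertiles with boundary ties
assigned to the lower tertile.

Degree classification follows the standard KING ranges — first degree
(0.177, 0.354], second degree (0.0884, 0.177] — half-open below and
closed above, so a boundary value belongs to the more distant class whose
upper bound it touches. Kinship coefficients are inputs (taken from
pedigree expectations in simulation); no genotype-based estimation is
performed.

## Estimation

Logistic regressions are maximum-likelihood Newton/IRLS fits (statsmodels)
with a hard iteration cap; non-convergence, perfect separation and
degenerate estimates raise explicit errors — there is no silent fallback.
Default covariates are sex and birth year (the genotyping-array, cohort
and principal-component covariates of real biobank analyses exist only in
real data, but extra covariate columns are accepted). Continuous
covariates are internally centred and scaled for conditioning; this does
not affect exposure coefficients. The PRS is standardized to zero mean
and unit variance within each analysis set before fitting, so its
coefficient is per SD. Confidence intervals are Wald on the log-odds
scale: `exp(β ± 1.96·se)`.

Cross-adjustment fits exposure-alone and joint models on identical rows
and reports the proportional decrease `1 − β_adj/β_unadj`; **positive
decrease means attenuation**. Summaries across diseases are unweighted
means and sample SDs of the decreases on the log-odds scale. Interaction
tests are Wald tests of the FH × standardized-PRS product term, flagged
against `alpha/n_tests` (default 0.05/39, displayed at two significant
digits as 0.0013). Percentile bands (top-decile-vs-rest; the seven bands
0–10/…/90–100 with 40–60 as reference; low/average/high with the bottom
tertile as "low" and the 33rd–90th band as reference) are computed from
within-analysis-set average ranks, with values exactly on a boundary
assigned to the lower band.

Simulated relatives share liability components, so regressions over whole
families contain correlated rows and independence-based Wald standard
errors are anti-conservative (a pilot showed ~20% rejection of a true
null interaction at nominal 5%). Effect estimates are unbiased either
way, but calibrated inference (type-I error, CI coverage) is checked on
one index person per family (`one_index_per_family`, the first
youngest-generation member), with family history still derived from the
complete pedigree. On independent index persons the interaction test
rejects at 5.0% under the null and the per-SD Wald CI covers the
liability-model-implied slope at ~95%, where the implied slope is the
pseudo-true value solving the population logistic score equations under
the probit-style conditional risk `P(D|PRS) = Φ̄((T − √ρ²·PRS)/√(1 − ρ²))`
(evaluated by Gauss-Hermite quadrature in the test oracle).

## Concordance

`theoretical_concordance(r, q)` reduces the bivariate-normal upper-orthant
mass to a one-dimensional integral,
`∫_z^∞ φ(x)·Φ̄((z − rx)/√(1 − r²)) dx`, evaluated by adaptive quadrature
(absolute tolerance 1e−12, far below the 1e−6 requirement) and divided by
the marginal tail `1 − q`; it is validated in tests against both a dense
two-dimensional grid integration and scipy's multivariate normal CDF.
Negative correlations are out of scope (relatives only). The observed
estimator pools all (index, relative) directions — the pair table stores
both — and counts pairs whose relative exceeds the within-sample
q-quantile among pairs whose index does; stratified estimates condition
on the relative's disease status only. Because relatives cluster in
families, the Monte-Carlo error of the observed concordance shrinks more
slowly than the raw pair count suggests; the acceptance script therefore
counts over 25,000 families (750k/600k ordered pairs), where a 50k-family
diagnostic shows convergence to the analytic values with no systematic
bias.

## Cumulative incidence

Kaplan-Meier product-limit curves (lifelines) run on age with entry at
birth; cases contribute onset age as the event, others are censored at
death age or at age at the end of follow-up, whichever is earlier. Left
truncation (delayed entry) is an extension point for real registry data,
not used by the simulator. Strata are FH × PRS-group
(low/average/high) labels; strata with fewer than 10 cases are flagged
and omitted rather than estimated. `cum_inc_80` is 1 − S(80). A
late-onset disease can simply be left out of the incidence stage by
config, the analogue of excluding diseases whose onset is too late for
age-80 incidence to be meaningful.

## What the simulator does and does not show

The generator reproduces the *structural* assumptions of the registry
analyses: additive transmission, a PRS that is exactly a liability
sub-score, threshold disease, registry-windowed observability, and
family-clustered shared environment. Passing tests therefore demonstrate
that the pipeline's estimators recover the quantities this structure
implies (per-SD odds ratios, attenuation asymmetry, concordance equal to
the 2φ bivariate-normal value, Kaplan-Meier stratification patterns).
They do not demonstrate robustness to what real data add: diagnostic
error and under-reporting, assortative mating, dominance or epistasis,
ancestry structure and PRS portability, family-size variation,
hospital-biobank ascertainment enrichment, or secular trends in
registries. In particular, simulated FH is a *cleaner* genetic signal
than registry FH, so simulated FH-by-PRS attenuations are larger than the
~10% seen in biobank data; only the direction and asymmetry of the
effect, not its magnitude, transfer.

## Numerical and design choices

* Liability thresholds via the normal inverse survival function; tested
  against bisection of the CDF.
* Truncated normals are sampled by inverse-CDF on per-site uniform
  streams, keeping stream consumption independent of parameter values.
* Onset before death is not enforced: status is lifetime liability
  exceedance, and a diagnosis "at death" is acceptable; mortality is
  disease-independent unless `onset_death_link` is set.
* Tertile and percentile ties go to the lower category, everywhere.
* Per-family reproducibility is implemented as per-site streams with
  family-sliced matrices (see Randomness above) rather than one generator
  per family — the same guarantee, fully vectorised.
* `attenuation_summary` refuses fewer than two diseases; empty PRS bands
  and FH prevalences of exactly 0 or 1 are errors, while empty KM strata
  and case-free tertiles are flagged omissions, matching how partial
  panels are reported rather than failed.
* Pipeline `summary.json` contains no timestamps and rounds floats to 10
  decimals, so identical config + seed reproduce it byte-for-byte; the
  manifest carries the timestamp.

## Problem sizes

Default test and demonstration runs use 1,500–2,500 families
(15,000–25,000 individuals); Monte-Carlo checks of pair correlations and
concordance use 20,000–25,000 families (200,000–750,000 ordered pairs);
the type-I-error study uses 1,000 replicates of 1,000 families with one
index person each. These sizes put binomial/Wald Monte-Carlo error
comfortably inside the asserted tolerances while keeping any single test
run in seconds-to-minutes on one CPU.
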