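# Methods

This note records the statistical procedures `exposcore` implements, the
choices made where the design was genuinely open, and what the synthetic
calibration does and does not establish.

## Exposome scoring

**Binarization.**  Every raw exposure becomes a 0/1 risk indicator.
Categorical exposures are coded so that any value ≥ 1 means the risk is
present.  Numeric exposures are dichotomised at the quartile of their
*risk tail*: variables whose low values are the risk (sleep hours, physical
activity, NDVI greenness, natural views) flag values ≤ the empirical 25th
percentile; variables whose high values are the risk (media exposure,
alcohol intake, NO₂, urbanization) flag values ≥ the 75th percentile.  The
direction is declared per variable in the exposure catalogue; a single
undirected "lowest 25 %" rule would mark the *protective* tail of
high-is-risk variables.  Quantiles use linear interpolation between order
statistics and ties at the cut-off count as risk — deterministic and
conventional.  A constant numeric column carries no information and yields
all-zero flags with a warning.

**Redundancy.**  Exposures measuring nearly the same thing (|Pearson r| >
0.8) are grouped by connected components of the thresholded correlation
graph and one representative is kept per component.  The representative is
the first in catalogue order unless a member is explicitly designated; no
principled selection rule exists for interchangeable measurements, so the
rule is fixed and recorded in the output report, along with the largest
remaining absolute pairwise correlation.

**Tetrachoric correlation.**  Dependence between binary risk indicators is
summarised by the tetrachoric correlation: the correlation of the latent
bivariate-normal pair assumed to underlie the two dichotomies.  The
estimator sets the latent thresholds from the margins and solves
Φ₂(h, k; r) = p₁₁ by root-finding on the bivariate-normal CDF.  Empty 2×2
cells receive a +0.5 continuity correction; estimates are clamped to
±0.999; a degenerate margin (a variable that is constant) has no defined
threshold and returns NaN, which downstream clustering imputes as 0 with a
warning.  The test suite checks the estimator against an independent
double-quadrature oracle to |Δr| < 1e−3.

**Clustering and domains.**  Variables are clustered by Ward's method on
the distance d = 1 − r (signed, since grouped risks are expected to co-vary
positively; an absolute-value distance is a one-line change where wanted),
and the k = 3 cut is read as candidate domains.  Final domain assignment is
interpretability-first: explicit per-variable overrides (outdoor access
with behaviour; living alone and caregiving with social factors; chronic
disease and COVID-19 with the wider environment) take precedence, and all
remaining variables take the majority nominal domain of their cluster, ties
broken in domain order.  The shipped 18-variable catalogue partitions
6/6/6.  Whether the source analysis clustered tetrachoric or Pearson
correlations is not fully specified; tetrachoric is the default here since
it is the reported correlation measure.

**PERS.**  Domain scores are unweighted sums of the domain's indicators and
the total score sums all 18, so `pers_total = pers_soc + pers_life +
pers_env` exactly.  Equal weights are a deliberate simplicity choice;
weighting schemes are out of scope.  Known-group validity is an OLS of an
external criterion (education, self-perceived health, deprivation) on a
PERS column with sex adjustment.

## Polygenic scoring

Weight files in PGS-catalog scoring format are harmonized against the
genotype variants: indel entries and strand-ambiguous (A/T, C/G) SNPs are
dropped (their orientation cannot be resolved from alleles alone), allele
pairs that disagree with the genotype file are dropped as discordant, and
when the counted dosage allele is the weight file's other allele the weight
is negated.  Raw scores are sums of dosage × weight (sum vs. per-variant
average changes nothing after standardization for a fixed variant set; sum
is fixed and recorded in the output metadata).  Missing dosages are imputed
at the variant's mean observed dosage (2 × counted-allele frequency), the
PLINK-style default.  Raw scores are standardized within cohort with the
n−1 SD so reported odds ratios are per SD of score.

## Outcome definitions

HADS-D (0–21) maps to nested binaries at ≥ 5 / ≥ 8 / ≥ 11 and a four-band
severity category (none 0–4, mild 5–7, moderate 8–10, severe ≥ 11).  The
pre-pandemic mental-health score adds one point for diagnosis evidence and
one for sustained medication dispensation; only 2/2 counts as confirmed.
The upstream EHR logic (ICD-9 code lists, the ≥ 12-dispensations rule) is
consumed as pre-computed boolean flags.

## Regression models

Binary outcomes use maximum-likelihood logistic regression; the four-band
outcome uses a multinomial logit with the no-depression band as reference.
Wald 95 % confidence intervals and p-values are reported throughout
(matching the OR (95 % CI) reporting convention; profile-likelihood
intervals are not implemented).  Education enters as two indicator
contrasts of the 3-level ordered factor.  Age, sex and education are forced
into selection by default — their eligibility for elimination is exposed as
a flag since either reading is defensible.  Model quality is summarised by
AIC and Nagelkerke's pseudo R²,
R² = [1 − exp((2/n)(LL₀ − LL₁))] / [1 − exp((2/n)LL₀)],
with LL₀ from the intercepts-only fit on the same data.

**Stability selection.**  For each of B bootstrap resamples (plain
resampling with replacement at the participant level, size n), backward
elimination repeatedly removes the candidate term whose deletion most
decreases AIC until no deletion decreases it; a term's retention frequency
is the fraction of resamples in which it survives, and terms at ≥ 60 %
enter the final model.  Selection operates on the per-threshold binary
models by default, with final inference multinomial — the two-step reading
of the source procedure; the multinomial likelihood can be selected over
instead via the model spec.  Non-converging resamples are redrawn and
counted, with a hard cap.  A noise variable that happens to be associated
with the outcome *in the realised dataset* is legitimately retained often:
retention frequencies concentrate on dataset-level evidence, so null-
retention claims are distributional (over replications), not per-dataset.

**FDR.**  Benjamini–Hochberg across all main-effect terms of an analysis
block; the family is a documented configuration choice since no exact
family definition is fixed by the source description.

**G×E.**  The multiplicative interaction model adds the product of a PERS
term and a standardized PRS to both main effects.  An interaction OR below
1 with positive main effects reads as attenuation: the per-unit
environmental effect shrinks as polygenic liability rises.  The
leave-one-out sensitivity recomputes the environment score without one
component at a time, refits, and flags components whose omission moves the
interaction p across 0.05.

## Synthetic cohort generator

The generator emulates the cross-sectional analysis sample: 18 exposures
drawn from a Gaussian copula (latent multivariate normal; binaries by
thresholding at the marginal quantile, numerics by affine transformation to
normal marginals), four correlated standardized PRS (broad depression
paired with the first endorsement-based score at r = 0.55, 0.30
background), covariates (age 54.6 ± 7.1, 59.4 % female, education
10.8/42.3/46.9 %, ten standard-normal PCs, pre-pandemic score 0/1/2 at
69.3/19.2/11.5 %), and a four-band severity outcome drawn from a
multinomial logit with planted log-odds.  The integer HADS-D value is then
uniform within the drawn band — the analysis consumes only the bands, so
the within-band law is a reproducibility convention.  All draws flow from
one seeded NumPy generator; identical (config, seed) gives bit-identical
cohorts.

**Calibration.**  Published binary-exposure prevalences are planted
directly (loneliness 0.753, household conflicts 0.095, job loss 0.073,
rent/food struggle 0.084, no outdoor access 0.10, chronic disease 0.323,
COVID-19 0.049); numeric exposures contribute 0.25 each by the quartile
rule.  The remaining free prevalences are tuned so the domain-score means
match the published 1.01 / 1.44 / 1.92 (total 4.37): current smoker 0.34
and low natural views 0.798 — and, notably, the published social-domain
numbers force the two unpublished social prevalences (caregiving, living
alone) to ≈ 0.005 combined, far below their plausible population values;
the printed domain mean is treated as binding.  The latent correlation
matrix is a modelling choice (the full joint matrix is unpublished): weak
0.10 within-domain dependence plus the three reported strong pairs (living
alone–caregiving −0.6, NDVI–urbanization −0.6, NO₂–urbanization +0.6, with
NO₂–NDVI −0.35 for coherence) and outdoor access–natural views +0.4.
Outcome effects plant the published multinomial odds ratios (social
1.48/·/2.36, lifestyle 1.20/·/1.94, environment 1.17/·/1.40 across
mild/moderate/severe; broad-depression PRS 1.18 at moderate; interaction
0.87/0.84/0.92); unpublished moderate-level domain ORs are filled with the
published single-threshold values (1.87, 1.63, 1.36), which bracket the
mild/severe pair.  Covariate effects are modest realistic values (female
excess risk, small age and education gradients).  Intercepts were solved
once by fixed-point iteration against a 2,000,000-draw feature sample so
that the expected band frequencies equal the published 65.02/18.75/10.26/
5.97 %; the procedure is `scripts/tune_calibration.py` and its output is
frozen in the source.

**Collapsed-threshold calibrations.**  Two variants support the binary
single-score models.  A logistic model for HADS-D ≥ 8 fitted to data from a
four-band multinomial is correctly specified only when the planted effects
are zero at the mild level and equal at the moderate and severe levels —
otherwise the mild band makes the collapsed log-odds non-linear and the
fitted coefficient is attenuated away from any planted value.  The
`exposome_total_calibration` (PERS_Total OR 1.52) and `genome_calibration`
(PRS_B OR 1.18) therefore plant effects on the collapsed scale.

**Driver-identification scenario.**  `interaction_driver_calibration`
routes the entire interaction through the NO₂ flag (log-OR −0.6 per level).
Two departures from the default structure are required for single-component
identifiability, and both are instructive about the sensitivity analysis
itself: the driver is decorrelated from its co-members (a driver proxied by
a correlated neighbour, as NO₂ is by urbanization, leaves part of its
signal behind when omitted), and the driver carries no main effect (a main
effect on an omitted interacting flag induces a small spurious interaction
when the model marginalises over it).  Leave-one-out identification of a
single driver is therefore only expected when the driver is neither
strongly proxied nor a strong main-effect risk.

**What the generator does not emulate.**  Real exposure distributions are
skewed and partly ordinal, not normal; missingness (handled upstream by
complete-case exclusion) is absent; PRS are drawn directly as correlated
Gaussians rather than scored from genotypes (genotype→score arithmetic is
tested separately on small fixtures); covariates are independent of
exposures, whereas real education and age gradients in exposure exist; and
there is no selection, healthy-volunteer or ancestry structure.  Passing
recovery tests therefore demonstrates the *pipeline's* correctness under
the assumed data-generating model, not robustness of the scientific
conclusions to real-data violations of it.

## Problem sizes and numerics

Recovery checks run at n = 50,000, where every planted coefficient is
recovered within ~1–2 estimated SEs; calibration checks use 3σ Monte-Carlo
tolerances.  Stability-selection behaviour is checked at B = 100,
n = 2,000 over ten replications.  Logistic/multinomial fits use Newton
iterations (statsmodels) with analytic Wald SEs; the tetrachoric solver
uses Brent root-finding to 1e−10 on r; quasi-separation is flagged and
falls back to a weakly regularized fit rather than failing.
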