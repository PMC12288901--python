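# Methods

This note documents the models, parameter choices and numerical decisions
behind `neosep`, and what the synthetic cohorts do and do not establish
about real data.

## The analysis model

The pipeline targets a case-control cord-blood proteomics design: a small
EOS group (culture-confirmed sepsis, n = 14 by default) against a large
control group (n = 150), profiled by label-free quantification in technical
duplicate across 4 MS batches, each batch carrying runs of one pooled
reference sample. A third, unlabeled cohort of presumed-sepsis (PS) infants
(n = 56) — treated for sepsis despite negative cultures — is modeled as a
latent mixture of EOS-like and control-like infants. Alongside the LFQ
matrix, three immunoassay biomarkers (CRP, SAA, LBP; mg/mL) and the usual
perinatal covariates (gestational age, sex, chorioamnionitis, PROM,
preeclampsia, multiple gestation, delivery route, labor, plasma protein
concentration) are available per infant.

### Batch normalization

Pooled controls anchor the correction: for protein *p* and batch *n*,
`offset(p, n) = mean_pooled(p, n) − mean_pooled(p, reference)` on the log2
scale, subtracted from every batch-*n* run. Consequences the tests verify:
pooled-control means agree exactly across corrected batches, the operation
is idempotent, and it is exactly invertible from the stored offset table.
Proteins detected in a single batch are excluded beforehand (they cannot be
anchored). A missing pooled anchor for a (protein, batch) pair yields
offset 0 plus a log entry rather than dropping the protein — the choice
preserves data and stays auditable, at the price of leaving that batch
uncorrected for that protein.

### Detection partition and two-step imputation

Detection fractions are computed on the specimen-level matrix (after
replicate averaging, where a specimen is missing only if *all* its
replicates are); "kept" means strictly >20% detection, everything else is
analyzed as presence/absence. A replicate pair with one missing value
averages over the available value — the maximal-data-use reading of
replicate averaging.

Imputation (used only for ordering/PCA-style outputs; all inference uses
the non-imputed matrix) runs separately per sample group: proteins with
<30% missingness go through scikit-learn's `IterativeImputer`
(ridge-style Bayesian conditional regression, round-robin over incomplete
proteins, max 10 cycles, tolerance 1e-3, initialized at per-protein means);
proteins at or above 30% have missing cells drawn uniformly from that
protein's observed within-group values at or below the 10th percentile —
the left-censoring assumption appropriate for abundance-dependent dropout.
Observed values are never altered; proteins with zero observations in a
group stay missing and are logged. One seeded generator stream per group
makes the draws reproducible.

### Statistics

The two-sided Mann-Whitney p-value is `min(1, 2·min(tail probabilities))`.
For tie-free samples with n_x + n_y ≤ 12 the null distribution of U is
computed exactly by the classical counting recursion; larger or tied
samples use the normal approximation with tie and continuity correction
(scipy). Degenerate inputs where every value ties give p = 1. BH adjustment
is the standard step-up procedure; it is applied across the kept-protein
family only — rare proteins are never assigned p-values, because their
observed abundances are conditioned on detection. Rare-protein enrichment
is instead operationalized as a detection-fraction difference exceeding a
margin (default 0.15), since no formal test is attached to these.
Demographics tables use Mann-Whitney for continuous variables and Pearson
chi-square without continuity correction for categorical ones; constant
variables are skipped and logged. The gestational-age sensitivity
reanalysis drops controls at ≥37 weeks (strict cutoff) and keeps all EOS
infants, who are preterm by construction.

### Predictive modeling

Logistic models are ranked by AIC = 2k − 2lnL with k counting every
estimated coefficient including the intercept; classification metrics use
the 0.5 probability threshold. Perfect or quasi-separation (non-convergence
or a coefficient diverging past 15 on the log-odds scale) is flagged and
the AIC reported as not comparable. Constant covariate columns are dropped
from the design to avoid singular fits. Correlated clinical variables are
pruned by linking pairs whose association (Cramér's V for binary pairs,
|r| otherwise) exceeds 0.7 and keeping, per linked component, the variable
with the best single-variable AIC. The delivery sum score is defined as
vaginal-delivery indicator + labor indicator (0–2); the construction is a
package choice, as is entering biomarkers log10-transformed (they span
orders of magnitude; a raw option remains).

The random-forest protocol: 10 stratified 50/50 shuffle splits; on each
training half a grid search over n_estimators {50, 100} × criterion
{gini, entropy} × max depth {4, 5, 6} × min samples per leaf {2, 3},
cross-validated with stratified 3-fold CV scored by F1 with EOS positive
(fold count and scorer are package choices); EOS carries a 10:1 class
weight; metrics are computed on the held-out half with EOS as the positive
class; permutation importance uses 20 repetitions with an accuracy scorer
on the held-out half. A split that lands no EOS case in either half is
redrawn and logged (it cannot occur at default sizes). All randomness
derives from one master seed via named substreams, so the evaluation is
bit-reproducible.

The PS classifier is a single random forest refit on all labeled infants
(outliers excluded) with the modal best grid point across the 10 runs —
chosen over an ensemble vote for interpretability and determinism. A PS
infant with predicted probability exactly at the threshold classifies as
EOS (conservative toward sepsis detection).

Advisory outlier flagging identifies EOS infants whose log10 biomarker
vector falls inside the control group's Mahalanobis 97.5% ellipsoid
(chi-square cutoff, 3 df); a singular control covariance falls back to a
per-marker quantile box. Flagging never excludes anyone by itself —
exclusion requires explicit ids, mirroring how late-positivity cases
(blood cultures positive only after ~2 days, i.e. sepsis likely acquired
postnatally rather than in utero) would be adjudicated by hand.

## The synthetic cohort generator

On the log2 LFQ scale each run is
`mu_p + spike_p·[EOS-like] + shift_batch + specimen_effect + replicate_noise`
with `mu_p ~ N(25, 3)` for background proteins, specimen effects N(0, 0.7),
replicate noise N(0, 0.2) (duplicates share the specimen effect), and batch
shifts N(0, 0.5) applied to every run including pooled controls; the pooled
control is the same physical pool in every batch. Five spiked proteins
(named for the acute-phase reactants they emulate) gain +2.0 log2 in
EOS-like infants and are drawn abundant, N(28, 1) — acute-phase reactants
are high-abundance plasma proteins. Three rare proteins are drawn faint,
N(21, 1), and toggle per specimen with detection probability 0.7 in EOS vs
0.05 in controls.

Missingness is logistic-in-abundance dropout,
`P(drop) = logistic((midpoint − value)·slope)` with midpoint 26.5 and
slope 1.0. These defaults were chosen so that, with duplicate runs and
base means N(25, 3), roughly 250–260 of 437 proteins clear the 20%
specimen-level detection threshold — the kept/rare split the analysis is
designed around. The mechanism itself is the standard proteomics dropout
model; the underlying study design implies abundance-dependent detection
but no explicit mechanism, so the logistic form is a package choice.

Gestational ages are truncated normals matching the cohort demographics
(EOS 30.7 ± 3.3 weeks, all preterm; controls 33.6 ± 4.5 with a full-term
tail), and covariate rates follow the same table (chorioamnionitis 43% vs
0.7%, PROM 64% vs 11.3%, vaginal delivery 71% vs 51%, female 36% vs 49%).
Rates without a published analog (preeclampsia, multiple gestation,
labor-after-cesarean, plasma protein moments) are set to plausible
obstetric values and exposed in the config. PS infants draw gestational
age, sex and delivery route from EOS-like distributions for everyone
(mirroring frequency matching of PS to EOS on those variables), while the
remaining covariates and the biomarkers follow each infant's latent class,
drawn EOS-like with probability `ps_mixture_fraction` (default 0.25).
Specimens are assigned to batches by stratified randomization on
(group, sex, GA epoch).

Biomarkers are log-normal per group with log10-mean separations ordered
SAA > LBP > CRP (SAA ≈ 4 control-SDs, CRP ≈ 2.3 — CRP's distributions
overlap most), which is what makes SAA the dominant permutation-importance
variable. Optional planted "late-positivity outlier" EOS infants draw
biomarkers from the control distribution with the log-sd halved —
concentrations squarely in the control range.

**What passing tests show, and what they do not.** The generator reproduces
the *statistical geometry* of the study data — group sizes, batch
structure, duplicate correlation, MNAR detection, effect sizes, class
imbalance, a latent PS mixture — so green tests demonstrate that the
pipeline's algebra, error control, ranking behavior and determinism are
correct under those conditions. They do not certify performance on real
cord blood: real proteomes have correlated proteins, non-Gaussian
abundance distributions, batch effects that are not purely additive, and
biomarker distributions with heavier tails than a log-normal.

## Problem sizes and numerical tolerances

Acceptance-level checks run at the default cohort scale (437 proteins ×
164 specimens). Multi-seed sweeps keep the infant-level structure at
default and shrink only what the checked quantity cannot depend on: the
permutation-importance and PS-mixture sweeps use a 12-protein panel (the
models consume biomarkers + covariates, not the LFQ matrix) and the
importance sweep runs 3 shuffle splits per seed; the byte-reproducibility
check uses a 120-protein cohort. Batch-shift recovery is assessed on
proteins whose pooled anchors are fully observed and ≥3 log2 units above
the dropout midpoint, where detection selection bias is negligible.
Pooled-mean equality after normalization is asserted to 1e-9; BH oracles
to relative 1e-12. The iterative-imputer gain check uses rank-3 data
(60 specimens × 40 proteins, 10% missing completely at random), where
conditional regression must beat per-protein means.

## Known limitations

* The batch correction assumes additive, protein-specific batch effects
  measurable in a pooled sample; intensity-dependent distortions are out of
  scope (no quantile/VSN-style alternatives).
* Differential abundance is unadjusted for covariates; the GA-matched
  subset reanalysis is the only confounding control, as in the underlying
  design.
* With 14 cases, the RF protocol's held-out halves contain 7 EOS infants;
  metric estimates per run are correspondingly coarse, which is why the
  protocol reports 10-run distributions rather than single numbers.
* Rare-protein enrichment is descriptive (fraction difference over a
  margin), not inferential.
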