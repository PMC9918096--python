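# Methods

`mirseed` implements a circulating-miRNA biomarker discovery pipeline for a
rat model of traumatic brain injury (lateral fluid-percussion injury, LFPI)
with post-traumatic epilepsy (PTE) follow-up. This note records the models,
the default parameters and why they were chosen, what the synthetic cohort
does and does not emulate, and the numerical conventions.

## The scientific setting

Plasma is sampled acutely after injury (day 2, "D2") from three arms —
naive, sham-operated (craniotomy without impact) and TBI animals. Small-RNA
sequencing yields a miRNA × sample count matrix; candidate biomarkers are
validated by RT-qPCR and droplet digital PCR (ddPCR); injured animals are
followed by video-EEG to label epilepsy outcome (TBI+ / TBI−) and by
quantitative T2 MRI to measure the cortical lesion. The statistical
questions are: which plasma miRNAs report injury, whether any single marker
or panel predicts epileptogenesis, and whether acute marker levels scale
with structural injury severity.

## Synthetic cohort generator

The generator is first-class, tested code — it defines the study
conditions under which every downstream stage is exercised.

**Counts.** Counts are gamma-Poisson (negative binomial):
`K_ij ~ NB(mean = L_j · p_i · 2^(e_ij), dispersion α)` with variance
`μ + αμ²`. Baseline abundances `p_i` are heavy-tailed (log-normal on the
log-abundance, σ = 2) so the matrix spans the usual five decades of plasma
miRNA abundance. Library sizes `L_j` are log-normal (default mean 1e6
mapped reads, CV 0.3), with a configurable low-depth multiplier for one arm
(`low_depth_factor`, to emulate the depth collapse of sham libraries at a
late timepoint, where sham depth was ~17% of TBI depth).

**Effects.** The first `n_injury_responsive` miRNAs are "brain-enriched,
injury-responsive": their exponent is `sham_log2fc` in the sham arm
(craniotomy alone elevates most of these markers) and
`sham_log2fc + injury_log2fc · s_k` in the TBI arm, where `s_k` is a latent
per-animal injury severity, log-normal with mean 1 (σ = 0.5). Defaults
(`injury_log2fc = 2`, `sham_log2fc = 1`) put simulated TBI/sham fold
changes in the few-fold to tens-of-fold range reported for the validated
markers (4- to 41-fold across assays).

**Outcomes.** Epilepsy is Bernoulli with log-odds
`logit(epilepsy_rate) + epilepsy_coupling · (s_k − 1)`. The default
`epilepsy_rate = 21/90` matches the validation cohort (21 TBI+ of 90), and
the default `epilepsy_coupling = 0` reproduces the study's central null
finding — acute plasma miRNA levels carry no information about
epileptogenesis. The coupling is exposed for power studies only. Seizure
counts exist only for epileptic animals (1 + Poisson(3)), and a seizure
cluster (≥3 seizures within 24 h) can only occur in animals with ≥3
seizures.

**Severity couplings.** Cortical lesion volume is `lesion_coupling · s_k`
mm³ (strictly monotone in severity; default slope 30 mm³ gives lesions in
the tens of mm³) and the chronic histological lesion area scales as
`s_k^(2/3)` (area vs volume). Because responsive miRNA levels and lesion
volume share `s_k`, they are positively correlated — the simulated
analogue of the reported marker/lesion Spearman correlations (ρ ≈
0.3–0.6) — while non-responsive miRNAs and the reference assay are not.

**Hemolysis QC variables.** A414 (hemoglobin absorbance) is Normal(0.14,
0.05) clipped at 0.01, and plasma volume is sufficient with probability
0.78. These two numbers were set once so that the expected qualified
fraction (A414 < 0.25 and volume ok) is ≈ 0.77 — the reported attrition of
115/150 samples — and the A414 distribution among qualified samples
matches the reported 0.13 ± 0.04.

**ddPCR.** Each droplet is positive with probability `1 − exp(−c·v)`
(c copies/µL, v = 0.00085 µL, 20,000 droplets per well). Target assays
follow the arm/severity effects on a copies/µL scale; the endogenous
reference (miR-28-3p) sits near 100 copies/µL with 15% log-normal
measurement noise and no group effect.

**T2 maps.** Healthy cortical voxels are Normal(50, 2.551) ms — chosen so
the 2.5th/97.5th percentiles fall at 45 and 55 ms, the published normal
band — and the lesion is a contiguous central core (fraction set by the
animal's lesion volume) shifted by +30 ms. Grids default to 16×16×8 voxels
of 0.06 mm³; tests use smaller grids.

**What the generator does not emulate.** Compositional closure of
sequencing (effects are injected per-miRNA without renormalizing library
totals), sequence-specific capture bias, hemolysis-driven contamination of
specific miRNAs, batch/plate effects, spatially realistic lesion geometry,
and any real count spectrum (the per-miRNA abundance distribution of the
study is unpublished). Passing tests therefore demonstrate statistical
correctness of the pipeline under a faithful generative model, not
recovery of the study's specific miRNA lists.

**Reproducibility.** One global seed; all sub-streams (design, counts,
severity, ddPCR, T2, QC) are spawned from it, so a cohort is bit-identical
under a fixed config.

## QC and normalization

CPM is `count / sample_total × 1e6`; zero-total samples are an error naming
the sample. The hemolysis rule is strict: a sample with A414 ≥ 0.25 is
hemolyzed (0.25 itself fails), and QC percentages are rounded half-up to
integers, the reporting convention of attrition tables. Detection sets use
"≥1 raw read in ≥1 sample of the group"; singleton detections are reported
but downstream prevalence filtering excludes them. The prevalence filter
keeps miRNAs with ≥`min_count` reads in ≥`ceil(min_fraction · n)` samples
(default ≥1 in ≥80%). PCA operates on log2(CPM+1) with per-miRNA centering;
whether the original analysis logged its CPM is unstated, and the log is
the defensible default for five-decade abundance data.

## Differential expression

A deliberately transparent DESeq2-style stand-in:

- **Size factors** — median-of-ratios over miRNAs with all-positive
  counts, normalized to geometric mean 1; total-count fallback (with a
  warning) when no miRNA is shared by all samples. The median is taken in
  ratio space.
- **Dispersion** — per-miRNA method of moments on normalized counts,
  `α̂ = max(floor, (s² − μ̄)/μ̄²)` with floor 1e-8 and cap 20. When group
  labels are available the variance is pooled within groups so true effects
  do not inflate α̂.
- **Wald test** — per-miRNA NB GLM with log link, design
  `[intercept, group]`, offset log size factor, fit by IRLS (tolerance
  1e-8, max 100 iterations; the 2×2 weighted LS step is solved in closed
  form and vectorized across all miRNAs). The statistic is
  `log2FC / SE(log2FC)` against a standard normal; BH adjustment is applied
  per contrast. Non-converged fits carry missing p-values; miRNAs with zero
  reads everywhere are excluded before testing.

Omitted relative to DESeq2: Cox–Reid adjusted-profile dispersion
shrinkage, the mean–dispersion trend, independent filtering, LFC
shrinkage, outlier replacement. Validity is established by simulation:
under the null the raw p < 0.05 rate is ≈0.05 and the BH rule yields
essentially no discoveries; planted 2-fold effects at n = 10/10 and
dispersion 0.2 are recovered with recall above the declared floor of 0.35
(power at these conditions is intrinsically modest; the floor is a
regression guard, not a claim of high power).

## Candidate selection

Upregulated shortlist: log2FC ≥ 1.0, adjusted p ≤ 0.05, mean CPM ≥ 30 in
the injury group, brain-enriched per the annotation table. Downregulated:
log2FC ≤ −1.0, adjusted p ≤ 0.05, mean CPM ≥ 100 in both groups. All
thresholds inclusive — boundary candidates (CPM 31 under "CPM ≥ 30") are
admitted, matching how the rules were applied. "Low p-value" is
operationalized as the DE significance rule (adjusted p < 0.05); no
separate cut is published. Brain enrichment is an input annotation (the
original lookup was literature/atlas-based); manually added candidates
(markers quantifiable by PCR but absent from sequencing) enter via an
allow-list, since the rule that generated them is editorial.

## PCR quantification

qPCR expression is `2^−(Ct_target − Ct_reference)` with replicates averaged
on the Ct scale. ddPCR concentration is the Poisson partition correction
`c = −ln(1 − k/n)/v`; replicate wells are merged by pooling droplet counts
before correction (more stable than averaging per-well concentrations);
zero positives report 0 (below detection); saturated wells are an error.
Normalized expression is target/reference concentration; zero-reference
samples are unevaluable. Reference stability is geNorm's M (mean SD of
pairwise log2 expression ratios, lower = more stable) with the classic
iterative exclusion ranking. Per-plate control samples can be checked for
drift (> configured fold from the grand geometric mean flags the plate); no
correction is applied because none is described for this design.

## Univariate statistics

Kruskal–Wallis for ≥3 groups, two-sided Mann–Whitney post hoc (exact
enumeration for tie-free samples below n = 20, otherwise tie-corrected
normal approximation), unadjusted post hoc p-values by default (a BH option
exists). Fold changes are ratios of group means rounded half-up to one
decimal (or to integer percent). ROC AUC is the pooled-rank probability
`U/(n₁n₂)` (ties count ½), never flipped below 0.5, with the two-sided
Mann–Whitney p as its significance. The optimal cutpoint maximizes
sensitivity + specificity over all observed values, classifying positive at
value ≥ cutoff; criterion ties break toward higher specificity, then lower
cutoff (cutpoint software differs in tie handling, so the rule is pinned by
an exhaustive-scan oracle test). Spearman correlation uses average ranks
and the t approximation, requiring ≥5 complete pairs.

## Panel procedures

Both multivariate procedures keep *all* sample-dependent choices —
standardization, feature selection, penalty level — strictly inside
training folds; a leak-probe diagnostic (`leak_probe_auc`, a feature equal
to the class label only at each fold's held-out sample) verifies that
held-out information cannot inflate the pooled CV AUC.

**Nested-LOOCV logistic discovery.** Outer loop leave-one-out; per
training fold: standardize (fold statistics only), drop zero-variance
features, then an inner stratified 5-fold CV grid search over selection
method (F-score filter or recursive feature elimination), panel size
(1..p), penalty type (L1/L2) and regularization level (C over six decades,
1e-3..1e2), scored by pooled inner AUC. The published procedure names
these grid dimensions but not their values; the values here are declared
defaults. Feature importance is the mean |coefficient| over outer folds
(zero when unselected), normalized to sum to 1. The inner scheme is
stratified 5-fold — the outer loop is what the procedure specifies as
leave-one-out. All fits use class-balancing observation weights; without
them, pooled leave-one-out AUC is systematically pessimistic under class
imbalance, because each held-out sample's training fold is depleted of its
own class (the same artifact that makes null CV AUCs scatter widely, e.g.
0.31–0.50, in published runs of such procedures).

**Elastic-net panel pipeline.** Outer leave-one-out; per fold, a weighted
elastic-net logistic regression (mixing α = 0.5 — "equal weighting" of
LASSO and Ridge in the standard penalty parameterization; class-balancing
weights; glmnet-style λ path of 20 values from λ_max down 3 decades) with
λ chosen by inner stratified 5-fold CV minimizing weighted binomial
deviance. A predictor is excluded iff its coefficient is exactly zero in
>50% ("the majority") of outer folds; an empty kept set is a legitimate,
flagged outcome, not an error. The surviving panel is refit by ordinary
(unpenalized, unweighted) logistic regression; its CV AUC pools the
held-out probabilities of leave-one-out refits into a single ROC, and the
95% CI is a bias-corrected and accelerated (BCa) bootstrap of that AUC
with 10,000 resamples (bias correction from the midrank fraction of
bootstrap statistics below the estimate; acceleration from jackknife
skewness). Perfect separation in the refit flags the coefficients
non-finite but the CV AUC is still computed. Whether the original refit
was weighted is unstated; unweighted is the default here.

The penalized fits use an internal IRLS + coordinate-descent solver (the
glmnet algorithm: working-response quadratic approximation, soft
thresholding, warm starts down the λ path, internal standardization,
unpenalized intercept), compiled with numba. It is validated against
sklearn's saga elastic-net solver in the test suite; the hand-rolled
solver exists because the procedures above need on the order of 10⁵–10⁶
small penalized fits for calibration studies, which is far below the
per-fit overhead of the general-purpose implementations.

## Lesion metrics

The normal-T2 band is the [2.5th, 97.5th] percentile interval (linear
interpolation between order statistics) of all masked voxels of all
control volumes pooled across timepoints; band endpoints classify as
normal, exactly as the inequality "45 ms ≤ T2 ≤ 55 ms" reads. Lesion
volume is abnormal-voxel count × voxel volume, with short-T2
(hemorrhage-like) and long-T2 (edema-like) counts reported separately.
Ipsilateral restriction is expressed through the cortical mask; no
registration is performed. Marker/lesion association is Spearman per
miRNA × metric with pairwise deletion of missing samples and a flagged
minimum of 5 pairs.

## Pipeline and configuration

`run_pipeline` executes qc → de → select → pcr → stats → panel → lesion in
dependency order, halting with a stage-named error when a required
upstream stage is disabled. Thresholds live in one flat block (a414 0.25,
log2fc 1.0, cpm_up 30, cpm_down 100, fdr 0.05, prevalence 0.8, alpha 0.5,
n_boot 10000) so the mapping to the published defaults is auditable. Each
filter logs its in/out counts as JSON lines; the manifest records every
output file, the seed and a configuration hash. Reruns with the same
config and seed are byte-identical.

## Problem sizes used in validation

Null calibration runs 200 simulated null cohorts (n = 90, 7 features,
21/69 class split, labels independent) for both panel procedures — with a
reduced inner grid for the nested procedure (C ∈ {0.01, 1, 100}, F-score
selection, k ∈ {1, 4, 7}, L2), since null calibration is invariant to grid
size — and 1000 null miRNAs at n = 20/20 for the DE test. Signal recovery
uses 40 replicates of one planted predictor at binormal AUC 0.9 (shift
√2·Φ⁻¹(0.9) ≈ 1.81) among 6 noise features at n = 90. These sizes are the
package's declared validation conditions.

## Known limitations

- The DE stand-in will not numerically reproduce DESeq2 output; shrinkage
  and filtering differences matter most at small n and low counts.
- Pooled leave-one-out CV AUC remains slightly pessimistic (null means
  ≈0.48, not exactly 0.50) even with class weighting; this is a property
  of pooling predictions from different fold models, shared with the
  published procedure.
- Method-of-moments dispersion is noisy below ~10 samples per group; the
  Wald test is mildly anti-conservative there (null raw-p rate ≈0.06 at
  n = 20/20).
- geNorm input transform for sequencing-based reference selection is
  unstated in the original analysis; any positive expression matrix is
  accepted and the choice is the caller's.
- The generator's abundance spectrum and effect sizes are calibrated to
  qualitative reported structure, not to the deposited count data.
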