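# Methods

`episcan` implements a biomarker-discovery analysis for a longitudinal
multi-omic infant cohort: serum proteins, serum metabolites, blood RNA,
serum miRNA, binary-encoded SNP genotypes and clinical indicators measured
serially from birth to 104 weeks in infants with tuberous sclerosis complex
(TSC) plus age-matched controls. The scientific question is twofold:
(1) which analytes are associated with diagnosis, seizures, or outcome once
batch, drug-exposure and developmental confounding are removed, and
(2) can a small combination of enrollment-time analytes predict which
infants will develop epilepsy by age two.

## Confound corrections

Corrections are applied in a fixed order — batch, then vigabatrin (VGB),
then age — because each later contrast is estimated on data already cleaned
of the earlier, larger effects.

**Z/un-Z correction.** Within each confound group an analyte is standardized
by the group's center and SD, then rescaled with the center and SD of all
samples computed before correction. Group-level distributional differences
are equalized while the analyte keeps its overall location and scale. We use
the population SD (ddof 0): with that estimator the correction is exactly
idempotent under mean-centering (the post-correction global variance equals
the weighted mean of the group variances once the group centers agree);
with sample SD a second pass would shrink values by a factor
√((N−G)/(N−1)). Median-centering is available for the age-stratum path as a
config switch (the two centering conventions both appear in practice for
this family of corrections); it is only approximately idempotent because
median-centered groups retain unequal means. Within-group rank order is
always preserved, since the map is affine per group with positive slope.
Analyte/group combinations with fewer than two observed values or SD below
1e−12 pass through unchanged with a warning.

**VGB correction.** Exposure to vigabatrin has large multiplicative effects
on a subset of metabolites (the generator's default panel spans 1.5× to
52×). Affected metabolites are identified by a two-sided Wilcoxon rank-sum
test between exposed and unexposed samples, restricted to samples older
than 40 weeks (where developmental effects are minimal) and
Benjamini-Hochberg controlled at FDR 0.05; only the selected analytes are
then Z/un-Z corrected with exposure as the grouping. The correction applies
to the metabolite type only.

**Age correction** is run by two independent methods whose outputs are both
kept:

1. *Age-stratum Z/un-Z*: the same scheme within three fixed postnatal-age
   strata — 0–10, 11–40 and >40 weeks. Integer-week boundaries are closed
   above (10.0 weeks belongs to the first stratum, 40.0 to the second).
2. *Linear mixed model*: per analyte, `value ~ age_weeks + (1 | subject)`
   fitted by REML (statsmodels `MixedLM`, up to 200 iterations;
   non-converged analytes are flagged and excluded from the corrected
   output). The corrected value subtracts the fitted age term and the
   subject's predicted random intercept:
   `corrected = value − age · â − b̂_subject`. The global intercept is
   deliberately not subtracted, so corrected values stay on the original
   scale. On noiseless linear-in-age input the correction is exact (the
   residual age slope is below 1e−6). Subjects observed once receive shrunk
   intercept predictions from the fitted variance components; constant
   analytes short-circuit to a zero slope and zero intercepts.

A property worth knowing: the predicted random intercepts absorb part of
*any* between-subject difference, including a genuine subject-constant group
effect. The absorbed fraction grows as the within-subject residual variance
shrinks relative to the between-subject variance. The LMM-corrected branch
therefore attenuates group signals, and the dual-method intersection rule
(below) is conservative by construction — a group difference must be large
enough to survive the attenuation and still clear the fold-change gate.

## Univariate association analysis

Analytes are first filtered on observedness: non-missing, non-zero values
in ≥70% of samples for proteins and ≥50% for metabolites, RNA and miRNA
(zeros count as unobserved even when unmasked).

*Two-group comparisons* are assumption-gated. Each group is checked for
normality (Shapiro-Wilk, per group) and the pair for variance homogeneity
(two-sided F-test), all at a 0.05 gate. If all three pass, a two-sided
pooled-variance t-test is used, otherwise a two-sided Wilcoxon rank-sum
test; the branch taken is recorded. Groups smaller than three observations
fall back to the rank test (two observations minimum).

*Three-group comparisons* use Kruskal-Wallis; when significant, Dunn's
post-hoc pairwise z-tests on pooled ranks with tie correction, BH-adjusted
across the three pairs. A pair is flagged only when its adjusted p is below
0.05 *and* the pairwise median fold change exceeds 1.5.

P-values are BH-adjusted across analytes within each comparison. The median
fold change is `2^(median(x) − median(y))` on log2-scale data and the ratio
of medians on linear data; it is antisymmetric under group swap. The final
call requires FDR < 0.05 and fold > 1.5 under **both** age-correction
methods (set intersection over a shared analyte universe).

Clinical comparisons implemented: diagnosis (affected vs control, untreated
samples without seizure history), seizures at draw, abnormal EEG at draw,
drug-resistant epilepsy at 24 months, and seizure history vs none at
24 months or at enrollment. The enrollment three-group contrast
(control / affected-without-epilepsy / affected-with-epilepsy) has a
stringent variant that excludes presymptomatically treated subjects from
the no-epilepsy group and subjects with abnormal EEG at enrollment from
both affected groups. Samples (not subjects) are the test units, matching
the pooled "any age" design of the diagnosis comparison.

Pathway enrichment of a hit set against user-supplied pathway memberships
is an upper-tail hypergeometric test with BH adjustment across pathways;
no database retrieval is performed.

## Developmental trajectories

Age association is measured two ways on batch/drug-corrected (but
age-uncorrected) data: Spearman rank correlation with age as a continuous
variable, and Kruskal-Wallis across the three age strata, each BH-adjusted
across analytes. Correcting age first would erase the signal being
profiled. Analytes significant in the stratum test are clustered: values
are Z-scored per analyte, collapsed to per-stratum medians, and the
three-dimensional profiles are grouped by complete-linkage hierarchical
clustering on Euclidean distances, cut at a configurable k (defaults 6 for
proteins, 6 for metabolites, 8 for RNA). Analytes are sorted by id before
linkage so the dendrogram does not depend on input order; dendrograms are
exported as newick text.

## Classifier search

The predictive experiment uses one enrollment sample per affected subject.
Subjects are excluded when (a) subclinical seizures were already present at
entry, (b) they were treated presymptomatically with VGB and never
developed seizures (their outcome is uninformative about natural history),
or (c) no enrollment sample exists; exclusions are a union. At the default
study structure (93 affected subjects; 7, 14 and 7 in the exclusion
groups), 65 subjects remain, 54 who developed seizures by 24 months and 11
who did not.

RNA enters after a two-step prefilter (detected in >3 reads in ≥75% of
samples; ≥2-fold median change between outcome groups). Features from every
type are then pooled by univariate rank AUC (Mann-Whitney with midranks,
oriented as max(AUC, 1−AUC)): a feature must exceed AUC 0.6, at most 30 per
data type are kept by descending AUC (ties broken by id), and constant
features are dropped. At the study's scale this pooling yielded 126
variables, for which the 1-, 2- and 3-variable model space has
C(126,1)+C(126,2)+C(126,3) = 333,501 members; every subset is enumerated
exactly once.

Each candidate model is a logistic regression on its (1–3) variables, fit
on complete cases (rows missing any variable are dropped and the retained n
reported). Validation is Monte-Carlo cross-validation: 100 stratified
2/3–1/3 train/test splits; per split the variables are standardized on the
training rows (refitting the scaler inside the split is the leak-free
default; an all-data variant is available), the model is fit by a batched
Newton solver with an L2 penalty of 1e−4 on the slopes (not the intercept)
to keep optima finite under complete separation, and the decision threshold
is tuned on the training set by scanning the observed training
probabilities for the maximum training MCC, cutting mid-way between the
winning probability and the next one below it. The held-out third yields a
confusion table scored by MCC (defined 0 when a marginal is empty),
misclassification error, PPV and NPV (PPV/NPV averaged over the splits
where they are defined; NPV is frequently undefined with 11 negatives —
with so few negatives a tuned classifier sometimes predicts no negatives at
all). Models are ranked by mean test MCC.

Randomness is reproducible and order-independent: the master seed plus a
CRC32 of the model's sorted variable ids seeds each model's split
generator, so any evaluation order (or parallel execution) gives identical
results.

## Permutation significance

Because no independent validation cohort is assumed, significance is
assessed by a whole-experiment permutation test: outcome labels are
permuted and *everything* — feature pooling (with its AUC threshold and
per-type cap applied to the permuted labels, so selection optimism is
reproduced under the null) and the exhaustive search — is re-run, by
default 30 times with 50 subsamples per model (half the real experiment's
subsampling, trading null precision for time).

Two null summaries are kept:

- the **pooled null** — every permuted model's mean test MCC in one
  distribution. `p_pooled(m)` is the fraction of pooled null MCCs ≥ m. This
  is the right p-value for a model specified independently of the search
  ranking, and the (1−α) pooled-null quantile is reported as the
  significance threshold on mean test MCC.
- the **per-permutation maxima** — the best MCC of each permutation.
  `p_fwe(m)` is the fraction of permutation maxima ≥ m, the family-wise
  quantity appropriate for the search's own best model. The distinction
  matters: under a true null the best of K real models sits near the top of
  the pooled distribution by construction (its pooled p concentrates near
  1/K), while its family-wise p is uniform. Both are reported per model.

## Synthetic cohort generator

The generator is first-class, tested code; it produces the study structure
the pipeline assumes, with every planted effect recorded in a ground-truth
ledger for recovery tests.

- **Design**: 93 affected subjects with 2–5 serial samples (enrollment with
  log-normal ages matching a 4.7-week median and 2.1–8.0 interquartile
  range; an EEG- or seizure-triggered draw; a 26- or 52-week draw when no
  event occurred; a 104-week draw), 58 controls with one sample each at
  ages uniform over 0–104 weeks. Outcome split 54/11 after the three
  exclusion groups (7/14/7 by default). Around 40% of seizure subjects are
  labelled drug-resistant at 24 months.
- **Values**: per analyte, baseline N(10, 2²) on the log2 scale + an age
  trajectory for a type-specific fraction of analytes (defaults 0.84
  protein, 0.69 metabolite, 0.51 RNA) + a subject random intercept
  (SD 0.5) + a batch offset for metabolites (4 batches, offset SD 0.5) + a
  log2 VGB effect on exposed samples of a default 8-metabolite panel
  (folds 1.5–52) + optional group effects + Gaussian noise (SD 0.2).
  RNA is converted through negative-binomial counts (dispersion 0.05) to
  log2(CPM+1), so its noise is count-like rather than Gaussian.
- **Trajectories**: four archetypes (monotone rise, monotone fall, early
  peak at ~20 weeks, late plateau rising at ~35 weeks), each essentially
  flat past ~45 weeks — emulating developmental effects that are strong in
  infancy and minimal in the oldest stratum, which is what makes the
  >40-week window usable for the drug-effect contrast. Amplitudes are
  |N(1.0, 0.3²)| log2 units with random sign. A falling trajectory with
  negative sign aliases a rising one, so six trajectory classes are
  distinguishable, not eight.
- **Predictive signal**: a planted predictor shifts the enrollment samples
  of seizure-developing subjects by δ = √2·Φ⁻¹(AUC)·σ, the closed-form
  normal-theory shift for a target univariate AUC at per-class SD σ
  (σ = √(subject SD² + noise SD²)).
- **Missingness**: values below a per-type detection-limit quantile
  (default 5% for proteins and metabolites) are masked — missing not at
  random, emulating analytes dropping below instrument sensitivity. Two
  knock-on effects are faithful to real data and worth remembering when
  reading results: low-baseline analytes lose many values (the missingness
  filter exists to remove them), and for an analyte with a planted
  *upward* class shift the *unshifted* class is censored preferentially,
  biasing fold estimates downward.

What the generator does **not** emulate: correlation structure between
analytes (they are independent given the design), linkage disequilibrium
between SNPs, cell-type composition effects on RNA, assay-specific
peak-shape or amplification artifacts, and real biological pathway
structure. Passing tests therefore demonstrate that the statistical
machinery recovers what it assumes, not that the biology of any real cohort
behaves this way.

## Problem sizes used in tests

The packaged test and acceptance runs use the full study design constants
(93/58 subjects, 54/11 outcome, all exclusion groups) but scaled-down
analyte budgets — tens of features per type rather than 20,579 RNAs — and
correspondingly smaller search pools (up to ~40 features, ~1,500–12,000
models) and permutation counts (10 permutations × 50 subsamples). These
sizes exercise every code path at the study's sample-size regime; the
engine itself handles the full 126-variable, 333,501-model space (the
enumeration is verified exactly, and the per-model cost is a few
milliseconds).

## Known limitations

- The rank-correlation view of age association has no power against
  non-monotone (early-peak) trajectories; the stratum Kruskal-Wallis view
  covers them.
- With 11 negatives, per-split test sets contain ~4 negatives: MCC
  estimates per model are noisy, NPV is often undefined, and complete-case
  filtering can reduce the negative class further for analytes with
  detection-limit missingness.
- The mixed model assumes a linear age trend; nonlinear trajectories leave
  structure in the LMM-corrected branch (the stratum branch absorbs any
  shape). Spline age models are out of scope.
- Permutation p-values at 10–30 permutations have granularity 1/N_perm for
  the family-wise variant; zero values mean "below 1/N_null".
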