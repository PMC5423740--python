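# Methods

This note records the statistical model behind `pathpin`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Pipeline model

**Standardization.** Every gene is z-scored across *all* samples pooled
(`Z_mn = (g_mn − mean_m)/SD_m`, SD with the n−1 denominator). Pooling both
groups preserves the disease/control mean difference on the z scale —
standardizing within groups would erase the very signal being sought.
Zero-variance genes carry no contrast and are dropped with a logged count.

**Pathway activity.** For each pathway the samples × member-genes block of
`Z` is column-centred and decomposed by SVD; the activity is the sample
coordinate on the first right singular vector (unit-norm loading). Because
a principal component's sign is arbitrary, the loading is oriented so its
largest-magnitude coefficient is positive (ties: the alphabetically first
gene). The orientation affects nothing downstream — the seed statistic and
the SVM are sign-invariant — but makes artifacts byte-reproducible. Genes
are processed in sorted order, so activity is invariant to the order a GMT
file lists members. A single-gene pathway is well defined (activity = the
gene's z-row) but rejected by default (`min_genes=2`) since a one-gene
"component" is no summary.

**Seed statistic.** The absolute pooled-variance two-sample t of activity,
disease vs control. Pooled rather than Welch because group sizes are small
and the generator's groups share variance; `welch_t` is available via
`seed_statistic`. Ties break to the lowest pathway ID.

**Differential expression.** Per-gene two-sided pooled t on the
standardized values (the t statistic is invariant to per-gene affine
transforms, so this equals the raw-scale test). Raw p < 0.05 defines a
DEG; no multiplicity correction by design — the DEG set feeds a network
qualification rule, not an inference claim. `fdr=True` switches the flag
to Benjamini–Hochberg q < alpha for users who want control. A gene
constant in both groups yields t = 0, p = 1.

**Network construction.** For every unordered pathway pair, two
qualification criteria:

* *shared_deg* — the intersection contains ≥ 1 DEG;
* *coexpressed_ppi* — some protein interaction with one endpoint in each
  pathway has max(|r_disease|, |r_control|) > 0.8 (the threshold condition
  is switchable via `criterion2_condition`).

Edge weight is the sum of |PCC| over *all* crossing interactions, each
unordered interaction counted once even when both endpoints lie in both
pathways (avoids double-counting shared-gene interactions). The weighting
condition defaults to the disease-group correlation
(`weight_condition ∈ {disease, control, all_samples, max_abs}`). A
per-condition correlation with a zero-variance endpoint is defined as 0
with a warning. The difference of absolute correlations between conditions
is exported as a diagnostic column only; it drives no decision.

**Reduction.** `reduce_top_fraction` keeps `floor(fraction · |E|)` edges
(heaviest first; ties at the cut break on ascending ID pairs; isolated
nodes stay). The floor uses a 1e-9 epsilon so binary-float products like
0.29 × 100 = 28.999… floor to their mathematical value. Criterion-1-only
edges with no crossing interactions have weight 0 and sort last, so they
effectively never survive reduction.

**Selection.** Linear SVM (C = 1) on activity features standardized within
each training fold; stratified 5-fold splits, repeated (default 100×, seed
r = base_seed + r); candidates at a step share fold splits (common random
numbers), so comparisons are paired. With 8 controls a fold holds 1–2
control samples, so per-repeat AUC is computed on the pooled out-of-fold
decision values rather than per fold, then averaged over repeats. A
candidate joins when it beats the current mean AUC by more than
`min_improvement` (default 1e-6, i.e. any strict improvement); the trace
is therefore strictly increasing and the stopping point is the first step
where no neighbour helps. The candidate frontier is every pathway adjacent
to *any* selected member, so the set grows as a connected subnetwork
around the seed. `no_leakage=True` re-derives PC1 loadings inside each
training fold (`make_fold_refitter`) for users who want activity scores
untouched by test samples; the default fits PCA once on all samples, as
seed selection precedes cross-validation anyway.

## Synthetic-data generator

The generator emulates a small two-group microarray-style cohort with
known ground truth. Defaults (the package's reference scenario): 600
genes, 15 disease vs 8 control samples, 50 pathways of 8–14 genes with
adjacent pathways sharing ⌈0.25 · size⌉ genes, an interaction network with
edge probability 0.35 inside pathways and 0.02 elsewhere (confidences
uniform on (0.2, 1]), partner co-expression 0.8, and 5 planted pathways
shifted by 2 SD on half of their member genes.

**Co-expression** is induced by shared latent factors under
variance-preserving mixing, so every marginal stays N(0, 1):

* each pathway contributes one co-regulation factor; a gene in *m*
  pathways is `x = √(1−ρ)·ε + √(ρ/m)·ΣF`. Two partners whose single
  membership is one common pathway correlate at exactly ρ; genes sitting
  in several pathways are attenuated by `1/√(m_a m_b)`;
* interactions between pathway-free genes carry per-edge latents with the
  same normalization (degree-1 pairs reach ρ);
* interactions crossing two independent pathway programs share no factor —
  their co-expression is background-level.

A per-interaction-edge latent model was considered and rejected: with unit
marginals it attenuates partner correlation by `1/√(d_a d_b)`, which makes
a target of ρ ≈ 0.8 unreachable at any realistic interaction density. The
factor model reads co-expression as what it biologically is here —
pathway-level co-regulation.

**Planted signal.** A contiguous block of pathway IDs is planted; in each,
⌈fraction · size⌉ genes are shifted in disease samples only. The shift is
a per-(pathway, sample) dysregulation dose
`D ~ N(effect_size, (dose_cv · effect_size)²)` shared by the pathway's
affected genes — cohorts are heterogeneous in how strongly each sample
expresses each aberration, and it is exactly this heterogeneity that makes
*combining* pathways more informative than the single best one. A gene
affected by several planted pathways receives the mean of their doses.
`dose_cv = 0` recovers a constant shift; `effect_size = 0` is an exact
null (no dose noise, calibrated type-I error).

**What the generator does not emulate:** microarray noise models (probe
effects, batch structure, normalization artifacts), hub-dominated
scale-free interaction topology, hierarchical pathway ontologies with
genome-wide membership overlap, or correlated dysregulation severity
across pathways. Passing tests therefore demonstrate the pipeline's
mechanics and statistical calibration, not robustness to those real-data
features.

## Scaled-down evaluation protocol

The test suite and `scripts/acceptance.py` exercise the pipeline at desk
scale (50 pathways, ~100–170 qualified network edges, 23 samples), with
two protocol adaptations, both stated here as the package's own choices:

* **Reduction fraction 0.5** in the planted-recovery scenario. The top-5%
  rule presumes a full-scale network (hundreds of thousands of qualified
  edges over ~1,200 pathways, keeping ~10 edges per pathway). At 50
  pathways, 5% keeps ~5 edges total — about 0.1 per pathway — which
  annihilates the network instead of reducing it. Keeping the top half
  preserves roughly one edge per pathway and still halves the network.
  The pipeline default remains 0.05.
* **20 CV repeats** instead of 100 in replicated simulations, for speed;
  the estimator is the same mean over repeats.

Problem sizes used by the acceptance script: the reduction rule is checked
on a 239,216-edge network (kept count 11,960), DEG calibration on 2,000
null genes, recovery and null-guard rates on 20 replicates each, and the
permutation null on 200 CV repeats.

## Known limitations

* **Greedy growth at 23 samples rarely exceeds a handful of pathways.**
  The seed, being the strongest single pathway, typically classifies at
  AUC ≳ 0.9 by itself; a cross-validated AUC estimate at n = 23 cannot
  reliably resolve the ~0.01–0.05 improvements further pathways offer, so
  the strict-improvement rule stops after one to three additions. An
  exhaustive-search probe over all improvement-monotone addition orders
  shows this is a property of the estimator at this sample size, not of
  the greedy heuristic. Larger cohorts (or a lower, pre-registered
  improvement floor) are needed for long selection traces like those seen
  on full-scale data.
* Seed selection precedes cross-validation, so the default final AUC is
  optimistically biased; use `no_leakage=True` and external validation for
  honest error estimates.
* PC1 captures only the dominant co-variation axis; pathways whose
  dysregulation is multi-modal are summarized poorly.
* The PIN qualification thresholds (p < 0.05, |r| > 0.8, top 5%) are
  conventions inherited from the method, not optimized quantities.
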