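# Methods

## Overview

`tmehot` transfers a single-cell picture of the tumor immune
microenvironment onto bulk expression cohorts. The pipeline has four
stages: (1) marker detection and signature curation from a clustered,
annotated single-cell matrix; (2) per-sample single-sample GSEA (ssGSEA)
enrichment of those signatures in bulk samples; (3) composite TME scores
(TAM, T, TME-hot); (4) a two-arm screen of candidate cancer cell-intrinsic
genes — correlation with the TME-hot score and univariate Cox survival
association — followed by Kaplan–Meier / log-rank and rank-sum validation
statistics. A synthetic-data module generates every input with known
ground truth so each stage's recovery behavior is testable.

## QC and marker detection

Cells are retained when their detected-gene count lies in [200, 7000] and
their mitochondrial count fraction is at most 15%. All three boundaries are
inclusive: the filter removes cells with *fewer than* 200 genes, *more
than* 7000 genes, or *more than* 15% mitochondrial counts, so a cell at
exactly a bound stays. QC only drops columns; retained values are never
altered.

Log-normalization divides each cell by its total counts, multiplies by
`scale_total` (default 10⁴) and applies log1p. A zero-total cell is an
error naming the cell.

Markers come from one-vs-rest two-sided Wilcoxon rank-sum tests per
(cluster, gene) on log-normalized data, computed with the asymptotic
tie-corrected normal approximation. Two pre-filters limit testing to
plausibly informative genes: detection in at least `min_frac` (default
0.1) of either the in- or out-group, and
`log2(mean(expm1 in) + 1) − log2(mean(expm1 out) + 1) ≥ min_log2fc`
(default 0.25). The +1 pseudocount keeps the fold change defined at zero
expression. By default only positive markers are reported, since
signatures are built from genes *up*-regulated in a cluster. P values are
Bonferroni-corrected over the genes actually tested within each cluster.
"Top n" ranking is by descending fold change, ties broken by ascending
p value then lexicographic gene id, making top lists fully deterministic.

## Signature curation

Each cluster's signature starts as its top-15 markers. Three rules remove
genes shared across related clusters, so each signature captures what is
specific to its cluster:

- **T-cluster rule.** "General T" genes (top-10 markers of the T lineage
  as a whole) that occur in both the Treg cluster's list and at least one
  other T-cluster list are removed. The removal target is ambiguous in
  principle (the Treg list only, or every T list); the default removes from
  all T-cluster lists, with `t_rule_scope="treg_only"` as the alternative.
- **TAM rule.** "General myeloid" genes (top-10 of the myeloid lineage)
  occurring in more than two TAM-cluster lists are removed from the TAM
  lists where they occur.
- **cDC rule.** Genes present in all three cDC lists are deleted from all
  three. The rule is defined for exactly three cDC clusters and the code
  enforces that.

Curation only removes genes; lists outside the three groups pass through
unchanged. A list that empties under curation is a hard error by default,
because an empty gene set makes ssGSEA undefined; `allow_empty=True`
instead drops the set and reports it. Every removal is recorded in a
curation report (gene, rule, affected clusters) for provenance.

## ssGSEA

For one sample, genes are ranked 1..N ascending in expression (N = the
highest; ties get average ranks). Walking genes in decreasing rank order
(ties keep input order, so results are deterministic), the enrichment
score of gene set S is

    ES(S) = Σᵢ [ P_in(i) − P_out(i) ]
    P_in(i)  = Σ_{j≤i, j∈S} r_jᵅ / Σ_{j∈S} r_jᵅ
    P_out(i) = #{j≤i, j∉S} / (N − |S|)

with exponent α = 0.25 by default. Because the score depends on expression
only through within-sample ranks, it is invariant to any strictly
increasing per-sample transform — the property that lets one signature set
score heterogeneous bulk platforms. Matrix-level normalization divides all
scores by the global (max − min) of the matrix, so all signatures share one
scale. Genes of a set absent from the matrix are ignored with a logged
count; a set missing more than half its genes (or all of them) is an
error, downgradable to drop-with-warning. A set that is empty, or covers
the whole universe (P_out undefined), is always an error.

## Composite scores

All composites are computed from one enrichment matrix (a single
normalization pass), so they are comparable across samples.

- **TAM score** — the ratio of the anti-tumor `TAM_CXCL9` score to the
  pro-tumor `TAM_SPP1/TREM2` score. Normalized enrichment scores can be
  zero or negative, so both rows are first min-max rescaled across samples
  into a positive interval. The rescale target is [0.5, 1] by default,
  bounding the ratio in [0.5, 2], symmetric around 1 on the log scale.
  This bound matters: rescaling into [ε, 1] with a small ε makes the ratio
  heavy-tailed up to 1/ε at the sample where the denominator hits its
  floor, and that tail's variance then swamps every other term of the
  TME-hot sum (with ε = 0.01 the correlation between the ratio and a
  ground-truth hot fraction is capped near 0.53 even without noise). With
  the [0.5, 1] target the ratio is near-linear and lives on the same scale
  as the summed enrichment terms. The general utility
  `rescale_positive` keeps ε = 0.01 as its own default (its purpose is
  merely positivity); `tam_score(..., epsilon=...)` exposes the choice,
  and `rescale=False` skips rescaling for data already positive.
- **T score** — the sum of the `CD8_Ttr_CXCL13`, `CD8_Teff_GZMB` and
  `Tact_IFI6` cluster scores.
- **TME-hot score** — TAM score + T score + NK + cDC1 enrichment. The NK
  term reads the cell-type-level `NK` signature row by default;
  `nk_mode="cluster_sum"` sums the `NK_GNLY` and `NK_FCGR3A` cluster rows
  instead. The composite is monotone non-decreasing in each component.

## Gene screen and survival statistics

A candidate gene is **TME-associated** when its two-sided Pearson test
against the TME-hot score has p < 0.05, **survival-associated** when its
univariate Cox Wald p < 0.05, and **selected** when both hold. Thresholds
are configurable; Benjamini–Hochberg adjustment within each arm is
available by flag but off by default — the screen is a candidate filter,
not a confirmatory test, and correlation direction is reported but not
filtered on (both protective and harmful TME-tracking genes are of
interest). The Cox arm uses continuous expression; dichotomization
(strictly-above-median = "high", so the median element of an odd-length
vector is "low") is reserved for Kaplan–Meier display. Constant genes get
an explicit `undefined` flag instead of being dropped.

Cox models are partial-likelihood fits with Efron tie handling
(lifelines); Wald confidence intervals and p values are reported
per covariate. Collinear designs and zero-event tables are rejected up
front with clear errors. Kaplan–Meier curves use the product-limit
estimator; the two-group comparison is the standard log-rank chi-square.
With no events anywhere the test is flagged undefined rather than
fabricated. Group comparisons of a continuous quantity (e.g. candidate
expression in responders vs non-responders) use the two-sided Wilcoxon
rank-sum test.

## Synthetic data

The generators emulate the study design the pipeline targets, with ground
truth attached (`SimTruth`). All are pure functions of (parameters, seed);
no global random state is used.

- **Cell atlas.** Counts are negative binomial with dispersion 0.5
  (variance μ + 0.5 μ²), a realistic overdispersion for UMI-free single
  cell counts. Baseline gene means are log-normal (median 1 count/cell,
  σ_log = 0.5). Each cluster gets `markers_per_cluster` disjoint planted
  markers whose mean is multiplied by `marker_fold` inside that cluster
  only. Marker genes are drawn from genes with baseline mean ≥ 0.5
  counts/cell: a marker must be detectably expressed for a fold change to
  be meaningful. The default cluster grid is the 22-population immune
  landscape the scoring stage expects (12 T/NK clusters, 9 myeloid
  clusters, one cancer cluster).
- **Bulk cohort.** Each sample draws a hot fraction f ~ Uniform(0, 1)
  (maximally informative for correlation-recovery experiments) and mixes
  the mean log-normalized profiles of the "hot" clusters (tumor-reactive/
  effector/activated T, NK, TAM_CXCL9, cDC1 by default) and the remaining
  "cold" clusters as f·hot + (1−f)·cold, plus Gaussian noise (sd
  `noise_sd`, truncated at zero). One planted cancer-intrinsic gene with
  mean `baseline + slope·f` is appended, together with `n_decoys` null
  candidate genes (constant mean plus noise, independent of f) — the
  decoys give the screen a measurable specificity.
- **Survival.** Event times are exponential with hazard
  `baseline_rate · exp(log_hr · x)`. Censoring is independent exponential
  with its rate solved (Brent's method) so the expected censored
  proportion equals `censor_rate`; at `censor_rate = 0` follow-up is
  complete.

What the generators do **not** emulate: doublets, ambient RNA, batch
effects, UMI-level sampling, platform-specific bulk biases, or non-convex
mixing. Passing recovery tests therefore demonstrates the estimators'
correctness and calibration under the stated generative model, not
robustness to every real-data artifact.

## Validation experiments and problem sizes

The test suite checks, among others: exact agreement (< 1e-9) of the
ssGSEA score with an independently coded brute-force ECDF summation over
random instances; invariance under random strictly increasing per-sample
transforms; an exhaustive toy table exercising every curation rule branch;
TME-hot recovery of the true hot fraction (r ≥ 0.8, 100 samples, 5 seeds);
Cox recovery of a planted log-HR of −0.5 (±0.15 at n = 500; bias < 0.05
over 100 replicates at n = 2000) and Wald type-I error calibration
(5% ± 2%, 500 replicates at n = 1000); log-rank null calibration
(5% ± 2%, 1000 random splits) and exact agreement with a hand-tabulated
log-rank oracle; ≥ 95% planted-marker top-15 recovery over 10 atlas seeds;
and the end-to-end screen over 50 replicates (atlas → signatures → 150
bulk samples → scores → screen; planted slope 2, log-HR −0.5), requiring
the planted gene selected in ≥ 90% of replicates with ≥ 90% of the 29
decoys rejected in every replicate. The screen replicates run with
complete follow-up (censor rate 0) to isolate screen power from censoring,
whose calibration is tested separately; the demo configuration uses a 10%
censor rate. The bundled demo run (seed 42) is verified bit-identical
across runs. `scripts/acceptance.py` recomputes scaled versions of these
quantities (fewer replicates where the full count adds runtime but no
information) and writes them as JSON.

## Numerical and design notes

- Ranks use scipy's average-tie convention; the ssGSEA walk breaks rank
  ties by input gene order (stable sort), so scores are deterministic.
- The Wilcoxon marker test uses the asymptotic method uniformly rather
  than letting the backend switch to exact enumeration at small n, so
  p values are continuous in the data and identical across group sizes.
- Bonferroni within cluster (not across clusters) mirrors per-cluster
  marker reporting; the screen deliberately applies no multiplicity
  correction by default (see above).
- Stage seeds in the pipeline are fixed offsets of the run seed, recorded
  in the manifest; every output file gets a SHA-256 checksum, and resuming
  into a directory re-verifies all checksums before reuse.
- The pipeline writes only plain-text formats (TSV/CSV/GMT/JSON/MTX); a
  `tmehot` CLI subcommand exists per stage plus `run` for the whole
  workflow.

## Known limitations

- Signature row names (`TAM_CXCL9`, `CD8_Ttr_CXCL13`, ...) are the
  contract between the signature and scoring stages; atlases annotated
  with different cluster names must be mapped to this nomenclature (or the
  scoring constants overridden) before composite scoring.
- The TAM ratio's bounded rescaling makes it rank-preserving but not
  scale-free: comparisons are within-cohort, not across cohorts.
- Real-mode screening fits one Cox model per candidate gene; with
  genome-wide candidate lists this is slow by design (supply a candidate
  list, as the intended use is the top markers of cancer cells).
- The log-rank implementation reports the unstratified two-group test;
  stratified or weighted variants are out of scope.
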