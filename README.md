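# tmehot

Quantify how immunologically "hot" a tumor's microenvironment (TME) is from
bulk expression data, using cell-type and cell-cluster signatures derived
from single-cell RNA-seq, and screen cancer cell-intrinsic genes for joint
association with the TME and with survival.

## Who this is for

Computational biologists who have (a) a clustered, annotated single-cell
atlas of the tumor immune microenvironment and (b) bulk expression cohorts
with clinical follow-up, and who want to transfer the single-cell view onto
the bulk cohorts: score each bulk sample's immune profile, then find genes
expressed by cancer cells whose levels track that profile *and* predict
outcome.

## The method

1. **Markers and signatures.** Cells pass QC (200–7000 detected genes,
   ≤ 15% mitochondrial counts), are library-size log-normalized, and each
   cluster's markers come from one-vs-rest two-sided Wilcoxon rank-sum tests
   (Bonferroni within cluster). Each cluster's top-15 markers form its
   signature, then three curation rules remove genes shared across related
   clusters: general T-lineage genes found in both the Treg list and another
   T-cluster list; general myeloid genes found in more than two TAM lists;
   genes common to all three cDC lists.

2. **Per-sample enrichment (ssGSEA).** For a sample with genes ranked
   r(1..N) (N = highest), the enrichment score of a set S is the summed
   difference between the rank-weighted in-set ECDF and the unweighted
   out-of-set ECDF:

   ES(S) = Σᵢ [ Σ_{j≤i, j∈S} r_jᵅ / Σ_{j∈S} r_jᵅ − #{j≤i, j∉S}/(N−|S|) ],

   with α = 0.25, walked in decreasing rank order; the matrix is normalized
   by its global max−min range.

3. **Composite scores.**
   - TAM score = ES(TAM_CXCL9) / ES(TAM_SPP1/TREM2), after min-max
     rescaling both rows to [0.5, 1] so the ratio is positive, bounded and
     rank-preserving;
   - T score = ES(CD8_Ttr_CXCL13) + ES(CD8_Teff_GZMB) + ES(Tact_IFI6);
   - TME-hot = TAM score + T score + ES(NK) + ES(cDC1).

4. **Gene screen.** Each candidate gene is tested for Pearson correlation
   with the TME-hot score and, separately, in a univariate Cox
   proportional-hazards model (Efron ties) on overall survival. Genes
   significant in both arms (p < 0.05 each, by default) are selected.
   Kaplan–Meier curves with the log-rank test (median-split groups) and a
   rank-sum comparison between sample groups support validation of
   individual hits.

Because real cohorts are large and external, the package ships a
first-class synthetic-data module with known ground truth: a clustered
single-cell atlas with planted fold-change markers, bulk cohorts that are
convex hot/cold mixtures with a known per-sample hot fraction plus one
planted cancer-intrinsic gene and null decoys, and survival times with a
log-linear planted hazard.

## Worked example

```sh
tmehot run --demo --out demo_out
```

runs the fully synthetic demo (seed 42): simulate a 22-cluster atlas
(40 cells/cluster, 800 genes, fold-4 markers), derive and curate signatures,
simulate 150 bulk samples with one planted TME-tracking gene and 29 null
decoys, score, and screen. It prints (abridged):

```json
{
  "n_candidates": 30,
  "n_selected": 1,
  "selected_genes": ["CI_PLANTED"],
  "planted_gene": {
    "gene": "CI_PLANTED",
    "pearson_r": 0.9424667515210785,
    "p_correlation": 2.591852585057606e-72,
    "hazard_ratio": 0.6691507130218654,
    "p_cox": 0.017184627530474825,
    "selected": true
  },
  "hot_vs_cold_rank_sum_p": 1.842138023469783e-22
}
```

Reading this: of the 30 candidate genes, exactly one — the planted
cancer-intrinsic gene — passed both screen arms. Its expression correlates
r = 0.94 with the TME-hot score, and its fitted hazard ratio of 0.67 per
expression unit recovers the planted protective effect (true log-HR −0.5,
i.e. HR 0.61). All 29 null decoys were rejected. The rank-sum p confirms
the gene is strongly enriched in TME-hot ("hot") versus cold samples.
`demo_out/` holds every intermediate (marker tables, curated GMT
signatures, enrichment matrix, composite scores, screen table, KM curves)
plus `manifest.json` with per-file SHA-256 checksums; re-running with the
same seed reproduces every file byte-for-byte.

The same stages are available individually (`tmehot simulate`, `qc`,
`markers`, `signatures`, `score`, `screen`, `cox`, `survival`) and as
library functions (`tmehot.ssgsea_matrix`, `tmehot.tme_hot_score`,
`tmehot.cox_fit`, ...). Real data enters through TSV/CSV/MTX expression
matrices, GMT signature files and a TSV clinical table (see
`tmehot run --config cfg.yaml` with `mode: real`).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generators and their defaults, numerical choices, and known limitations.
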