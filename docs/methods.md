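# Methods

This note documents the models and procedures implemented in `ulcermap`,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical choices that matter for reproducing results.

## Study design being modeled

Single-cell RNA-seq of foot skin across four clinical groups — healthy,
diabetic without ulcer (DM), healing diabetic foot ulcer (DFU) and
non-healing DFU — plus matched bulk RNA-seq (TPM). The scientific questions
are (1) which cell types populate each condition and in what proportion,
(2) whether stem-cell populations in ulcers retain stem-like transcriptional
programs (the "dryness"/stemness index), and (3) which drugs are closest, in
a drug–gene network, to the genes up-regulated in ulcers.

## Single-cell preprocessing

* **QC**: cells with fewer than 200 expressed genes are removed
  (`min_genes=200`, inclusive). The filter is idempotent and the gene set
  is never altered.
* **Normalization**: LogNormalize, `x = ln(1 + c/C · s)` with scale factor
  `s = 10⁴` (the upstream tool's default; the choice cancels out of any
  rank-based downstream step). Computed in float64 directly on the sparse
  matrix so that zeros stay exactly zero.
* **HVG selection** (`n_hvg=2000`): VST-style standardized variance. The
  mean–variance trend is a quadratic fit of log10(variance) on log10(mean)
  over raw counts (a parametric stand-in for a loess trend; adequate for the
  gamma–Poisson counts generated here), standardized values are clipped at
  √n_cells, and genes are ranked by the variance of the clipped values.
  Ties and constant genes fall back to stable input order.
* **Embedding/clustering** (`n_pcs=30`, `resolution=0.8`): z-scored HVG
  submatrix (clip ±10), exact PCA, exact k-nearest neighbors (k=15), a
  shared-nearest-neighbor graph with Jaccard edge weights pruned below 1/15,
  and Leiden (RBConfiguration) at the given resolution with a fixed seed.
  Everything is deterministic under the seed; externally computed labels can
  be passed through unchanged (bypass mode).
* **Marker detection** (`log2FC ≥ 1`, `p ≤ 0.01`): one-vs-rest Wilcoxon
  rank-sum per cluster. Fold change is computed on de-logged means,
  `log2((mean(expm1 x_in)+ε)/(mean(expm1 x_out)+ε))`, ε = 10⁻⁹. Genes are
  pre-filtered by the fold-change threshold before testing (as the standard
  tool does), so the Benjamini–Hochberg adjusted p-values reported alongside
  are computed over the tested genes per cluster; the adjusted values do not
  enter the filter. The test uses the exact null distribution for small
  tie-free groups and the tie-corrected normal approximation otherwise.
* **Merging marker-less clusters**: community detection at a fixed
  resolution can split one transcriptional state into sub-clusters; a pure
  sub-cluster then has no genes passing the one-vs-rest thresholds and
  cannot be annotated. The pipeline therefore merges any marker-less cluster
  into the nearest marker-bearing cluster (PCA centroid distance) and
  recomputes markers, iterating until every cluster has markers or two
  clusters remain. On heterogeneous real data this step is usually a no-op.

Batch integration is intentionally out of scope: the synthetic cohorts are
batch-free, and real-data use should integrate upstream if needed.

## Annotation by marker overlap

For a cluster marker set *A* and a reference type set *B* in universe *N*
(the reference universe intersected with the expressed genes), the
enrichment p-value is the one-sided hypergeometric upper tail P(X ≥ |A∩B|).
One-sided, because annotation asks for over-representation only. The cluster
is assigned the candidate with the smallest p at `alpha=0.05`; ties on p are
broken by the larger Jaccard coefficient, then by name order; with no
candidate at p ≤ alpha the cluster is `unknown`.

Composition is reported in both orientations — each group's cell-type
fractions, and each cell type's per-group share — and group differences are
tested on **per-patient** fractions (Wilcoxon rank-sum per group pair), not
pooled cells, to avoid pseudoreplication. Significance tiers: `*` p < 0.1,
`**` p < 0.05, `***` p < 0.001.

## Stemness (OCLR / mRNAsi)

Pseudobulk: for each patient and cell type, the arithmetic per-gene mean of
log-normalized expression over that patient's cells of that type.

The one-class model minimizes
`L(w) = Σᵢ ln(1 + exp(−w·xᵢ)) + (λ/2)‖w‖²` over stem-cell training profiles
only (`λ=1`, no intercept), by full-batch gradient descent with an Armijo
backtracking line search, stopping when the objective decreases by less
than `tol=10⁻⁸`.

**Centering matters.** If each gene is centered on the mean of the training
samples themselves, `Σᵢ xᵢ = 0` and `w = 0` is the global minimum of the
(strictly convex) objective — the fit is degenerate. The package therefore
centers training profiles against an explicit **baseline** profile (the
mean of a non-stem background population in the synthetic workflow; any
reference profile in real use). Self-centering remains available for
completeness and emits a degeneracy warning.

Scoring: raw score = Spearman ρ between `w` and a profile's expression over
shared genes (genes missing from a profile are dropped pairwise, not
imputed); ≥3 shared genes and non-constant inputs required. The mRNAsi is
the min–max scaling of raw scores **within a scored cohort**; single-cell
pseudobulks and bulk samples are scaled separately, so indices are
comparable within but not across cohorts. Because the score is rank-based,
bulk samples can be scored on any monotone transform of TPM.

## Bulk differential expression and target nomination

Welch's t-test per gene on log2(TPM+1); fold change
`log2((mean(TPM_a)+1)/(mean(TPM_b)+1))` with pseudocount 1. A gene is
dysregulated when raw p < 0.05 and |log2FC| > 1 — deliberately no
multiple-testing correction in the flag (BH-adjusted values are reported
alongside). The screen is a transparent, well-calibrated replacement for an
empirical-Bayes moderated fit; moderation is pluggable later and matters
mostly at very small n. Candidate targets = up-regulated genes ∩ the union
of marker sets of the configured populations (default monocytes and the
pluripotent stem population). `2^-ΔΔCt` is provided for qPCR follow-up.

## Drug–gene network and restart walk

Gene–gene edges: Spearman co-expression across bulk samples among the genes
of the interaction table (≥4 samples; constant genes excluded), kept at
ρ > 0.70 and p ≤ 0.05. The threshold is one-sided positive by default
(`absolute=True` switches to |ρ|). Drug–gene edges come from a DGIdb-style
table (`drug_claim_name`, `gene_name`; duplicates collapsed; name
collisions namespaced `drug:`/`gene:`). Edges are unweighted.

Random walk with restart: `v ← (1−r)Wv + re`, with `W` the column-normalized
adjacency, `e` uniform over the seed genes present, `v₀ = e`, restart
`r = 0.1`; convergence when the L1 change drops below `10⁻¹⁰` (power
iteration; verified in tests against the direct solve of
`(I−(1−r)W)v = re`). Mass reaching a dangling (degree-0) node restarts at
the seeds, which keeps Σv = 1 and gives an isolated seed weight 1. Drugs
are ranked by steady-state weight, ties by name.

## Synthetic cohorts

The generator plants exactly the structure the chain is meant to detect:

* **Counts**: gamma–Poisson (negative binomial) with shared dispersion 0.3;
  library sizes log-normal with mean 5000 and CV 0.3, so the 200-gene QC
  filter has nontrivial effect at small libraries.
* **Identity programs**: each of 5 cell types (last = "Pluripotent stem
  cell") has 30 marker genes whose mean is multiplied by `2^marker_log2fc`
  (default 2) in its own type.
* **Stemness**: a separate 100-gene signature block, scaled by
  `2^(stem_log2fc · activity)` in stem-type cells, with per-group activity
  declining from 1.0 (healthy) to 0.35 (non-healing) — identity and
  stemness are separable by construction.
* **Composition**: per-group probability vectors; by default the immune
  compartment expands with disease severity and the stem fraction stays
  small.
* **Bulk**: composition-weighted mixtures of the same type programs,
  TPM-normalized, with planted DE genes (log2FC ±2, dispersion 0.05)
  between the first and last group. The planted up-set includes a few
  immune-marker and stem-signature genes, recorded as the true drug-target
  genes, so the target screen has a non-empty planted answer.
* **Drug table**: half the drugs attach to ≥2 true target genes; decoy
  drugs attach only to unprogrammed background genes (genes with any
  planted program co-vary with the targets and would not be decoys).
* **Reproducibility**: one RNG stream per patient/sample derived from the
  master seed, so enlarging a cohort never reshuffles existing patients;
  same seed ⇒ byte-identical outputs.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, cell-cycle structure, within-type substructure or gene–gene
correlation beyond the planted programs, and gene-length effects in TPM.
Passing tests therefore demonstrate correctness of the statistical chain on
its stated assumptions, not robustness to those artifacts.

## Problem sizes in the shipped checks

The default end-to-end run uses 4 groups × 3 patients × 300 cells × 2000
genes with 24 bulk samples; the verification script uses 5 activity groups
× 5 patients for the stemness grid, 3 types × 500 cells/patient at marker
log2FC 3 for annotation recovery, 2000 genes × 50 replicate cohorts at
n=10/group for DE calibration, and 20 simulated networks for drug ranking —
sizes at which every planted effect is comfortably identifiable while a
full run stays in the minutes range on one CPU.

## Known limitations

* The annotation universe defaults to reference ∩ expressed genes; with a
  very small reference the hypergeometric p loses resolution.
* The "lowest p AND highest Jaccard" rule can conflict; the implemented
  order (p first, Jaccard as tie-break) is one of two defensible readings.
* mRNAsi values depend on the min–max cohort; a single scored sample is
  degenerate (index 0, warned).
* The DE screen's raw-p flag is intentionally uncorrected; interpret gene
  lists accordingly.
* Unweighted network edges treat a ρ = 0.71 co-expression edge and a
  curated drug–target edge identically; weighting is a natural extension.
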