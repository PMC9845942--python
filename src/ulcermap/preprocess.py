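"""Single-cell QC, normalization, HVG selection, clustering and markers.

The stage mirrors a standard droplet scRNA-seq workflow: cells expressing
fewer than 200 genes are removed; counts are log-normalized
(ln(1 + count / cell_total * 1e4)); 2000 highly variable genes are picked by
standardized variance under a fitted mean–variance trend; cells are embedded
with PCA (30 components) and clustered with Leiden community detection on an
exact k-nearest-neighbor graph at resolution 0.8; cluster markers are called
one-vs-rest with the Wilcoxon rank-sum test at log2FC >= 1 and p <= 0.01.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

import igraph
import leidenalg
import scanpy as sc
import anndata as ad

from .errors import DataError

COUNTS_LAYER = "counts"


def filter_cells(adata: ad.AnnData, min_genes: int = 200) -> ad.AnnData:
    """Retain cells expressing at least ``min_genes`` genes (count > 0)."""
    if min_genes < 0:
        raise DataError("min_genes must be >= 0")
    out = adata.copy()
    sc.pp.filter_cells(out, min_genes=min_genes)
    if out.n_obs == 0:
        warnings.warn(f"filter_cells(min_genes={min_genes}) removed every cell")
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """LogNormalize: value = ln(1 + count / cell_total * scale_factor).

    Computed in float64 on the sparse structure (zero counts stay exactly
    zero). Raw counts are preserved in ``layers['counts']``.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1), dtype=float).ravel()
    if np.any(totals <= 0):
        bad = adata.obs_names[np.where(totals <= 0)[0][:5]].tolist()
        raise DataError(f"cells with zero total counts (run QC first): {bad}")
    out = adata.copy()
    out.layers[COUNTS_LAYER] = out.X.copy()
    if sparse.issparse(X):
        norm = X.astype(np.float64).multiply(scale_factor / totals[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = sparse.csr_matrix(
            np.log1p(np.asarray(X, dtype=np.float64) * (scale_factor / totals[:, None]))
        )
    out.X = norm
    out.uns["scale_factor"] = scale_factor
    return out


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.layers[COUNTS_LAYER] if COUNTS_LAYER in adata.layers else adata.X
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def select_hvg(adata: ad.AnnData, n_top: int = 2000) -> list[str]:
    """Highly variable genes by VST-style standardized variance.

    A quadratic trend of log10(variance) on log10(mean) is fit over the raw
    counts; counts are standardized by the trend-expected standard deviation,
    clipped at sqrt(n_cells), and genes are ranked by the variance of the
    standardized values. Ties and zero-variance degeneracies fall back to the
    stable input gene order.
    """
    if n_top < 1:
        raise DataError("n_top must be >= 1")
    X = _dense_counts(adata)
    n_cells, n_genes = X.shape
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)

    not_const = var > 0
    std_var = np.zeros(n_genes)
    if not_const.sum() >= 3:
        lm, lv = np.log10(mean[not_const]), np.log10(var[not_const])
        coef = np.polyfit(lm, lv, deg=2)
        exp_sd = np.sqrt(10.0 ** np.polyval(coef, np.log10(mean[not_const])))
        clip = np.sqrt(n_cells)
        Z = (X[:, not_const] - mean[not_const]) / exp_sd
        np.clip(Z, -clip, clip, out=Z)
        std_var[not_const] = Z.var(axis=0, ddof=1)
    else:
        std_var[not_const] = var[not_const]

    # stable: sort by -std_var, input order breaks ties
    order = np.argsort(-std_var, kind="stable")
    keep = order[: min(n_top, n_genes)]
    keep_mask = np.zeros(n_genes, dtype=bool)
    keep_mask[keep] = True
    return [g for g, k in zip(adata.var_names, keep_mask) if k]


def embed_and_cluster(
    adata: ad.AnnData,
    hvgs: list[str],
    n_pcs: int = 30,
    resolution: float = 0.8,
    seed: int = 0,
    n_neighbors: int = 15,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """PCA on the scaled HVG submatrix, exact kNN graph, Leiden clustering.

    Deterministic under a fixed seed. ``labels`` bypasses clustering and is
    returned unchanged (externally computed clusters). The labels are also
    written to ``adata.obs['cluster']``.
    """
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != adata.n_obs:
            raise DataError("bypass labels length does not match cell count")
        adata.obs["cluster"] = pd.Categorical(labels.astype(str))
        return labels

    if adata.n_obs <= n_pcs:
        raise DataError(
            f"{adata.n_obs} cells <= n_pcs={n_pcs}; lower n_pcs or provide more cells"
        )
    sub = adata[:, hvgs]
    X = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10)
    n_pcs_eff = min(n_pcs, min(Z.shape) - 1)
    pcs = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed).fit_transform(Z)
    adata.obsm["X_pca"] = pcs

    # shared-nearest-neighbor graph with Jaccard edge weights, pruned at 1/15
    n = adata.n_obs
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    conn = sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    conn += sparse.eye(n, format="csr")  # each cell shares itself
    shared = (conn @ conn.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2.0 * (k + 1) - s)
    keep = jac >= 1.0 / 15.0
    g = igraph.Graph(
        n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=jac[keep].tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership, dtype=int)
    adata.obs["cluster"] = pd.Categorical(labels.astype(str))
    return labels


def find_markers(
    adata: ad.AnnData,
    labels: np.ndarray | None = None,
    logfc_threshold: float = 1.0,
    max_p: float = 0.01,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker detection per cluster.

    log2FC is computed on de-logged means:
    log2((mean(expm1(x_in)) + eps) / (mean(expm1(x_out)) + eps)), eps = 1e-9.
    Genes are pre-filtered by the fold-change threshold before testing (as
    the standard tool does), and only rows with log2fc >= threshold and
    p <= max_p are emitted; Benjamini–Hochberg adjusted p-values over the
    tested genes are reported alongside but not used for the filter.
    """
    if labels is None:
        if "cluster" not in adata.obs:
            raise DataError("no cluster labels: run embed_and_cluster or pass labels")
        labels = adata.obs["cluster"].to_numpy()
    labels = np.asarray(labels).astype(str)
    uniq = sorted(set(labels), key=lambda s: (len(s), s))
    if len(uniq) < 2:
        raise DataError("marker detection needs >= 2 clusters")

    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
    expm = np.expm1(X)
    eps = 1e-9
    rows = []
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {cl} has <{min_cells} cells; excluded from marker detection")
            continue
        mean_in = expm[mask].mean(axis=0)
        mean_out = expm[~mask].mean(axis=0)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        cand = np.where(log2fc >= logfc_threshold)[0]
        if cand.size == 0:
            continue
        pvals = np.ones(cand.size)
        for i, gi in enumerate(cand):
            x_in, x_out = X[mask, gi], X[~mask, gi]
            if np.all(x_in == x_in[0]) and np.all(x_out == x_in[0]):
                continue
            pvals[i] = stats.mannwhitneyu(
                x_in, x_out, alternative="two-sided", method="auto"
            ).pvalue
        adj = multipletests(pvals, method="fdr_bh")[1]
        for i, gi in enumerate(cand):
            if pvals[i] <= max_p:
                rows.append(
                    (cl, adata.var_names[gi], float(log2fc[gi]), float(pvals[i]), float(adj[i]))
                )
    return pd.DataFrame(rows, columns=["cluster", "gene", "log2fc", "p_value", "adj_p"])


def merge_markerless_clusters(
    adata: ad.AnnData,
    logfc_threshold: float = 1.0,
    max_p: float = 0.01,
    max_rounds: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Merge clusters that have no detectable markers into their nearest
    neighbor, then redo marker detection.

    Community detection at a fixed resolution can split one transcriptional
    state into sub-clusters; such a sub-cluster has no genes passing the
    one-vs-rest marker thresholds and therefore cannot be annotated. Each
    round reassigns every markerless cluster's cells to the closest
    marker-bearing cluster (centroid distance in the PCA embedding) and
    recomputes markers, until every remaining cluster has markers or only
    two clusters remain. Updates ``adata.obs['cluster']`` in place and
    returns the final labels and marker table.
    """
    if "cluster" not in adata.obs:
        raise DataError("no cluster labels: run embed_and_cluster first")
    if "X_pca" not in adata.obsm:
        raise DataError("no PCA embedding stored: run embed_and_cluster first")
    labels = adata.obs["cluster"].to_numpy().astype(str)
    pcs = adata.obsm["X_pca"]
    markers = find_markers(adata, labels=labels,
                           logfc_threshold=logfc_threshold, max_p=max_p)
    for _ in range(max_rounds):
        present = sorted(set(labels))
        with_markers = set(markers["cluster"].astype(str))
        orphans = [c for c in present if c not in with_markers]
        if not orphans or len(present) <= 2 or not with_markers:
            break
        centroids = {c: pcs[labels == c].mean(axis=0) for c in present}
        for orphan in orphans:
            anchors = sorted(with_markers)
            dists = [np.linalg.norm(centroids[orphan] - centroids[a]) for a in anchors]
            target = anchors[int(np.argmin(dists))]
            labels[labels == orphan] = target
        markers = find_markers(adata, labels=labels,
                               logfc_threshold=logfc_threshold, max_p=max_p)
    adata.obs["cluster"] = pd.Categorical(labels)
    return labels, markers


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small tie-free samples)."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)
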