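"""QC, normalization, HVG selection, clustering and marker detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ulcermap.errors import DataError
from ulcermap.preprocess import (
    embed_and_cluster,
    filter_cells,
    find_markers,
    lognormalize,
    select_hvg,
    wilcoxon_rank_sum,
)

from conftest import make_adata


def _adata_with_gene_counts(per_cell_genes, n_genes=600):
    rows = []
    for k in per_cell_genes:
        row = np.zeros(n_genes)
        row[:k] = 1
        rows.append(row)
    return make_adata(np.array(rows))


class TestFilterCells:
    def test_threshold_inclusive_at_min_genes(self):
        adata = _adata_with_gene_counts([150, 200, 500])
        out = filter_cells(adata, min_genes=200)
        assert list(out.obs_names) == ["cell1", "cell2"]

    def test_min_genes_zero_is_identity(self):
        adata = _adata_with_gene_counts([0, 3, 10], n_genes=20)
        out = filter_cells(adata, min_genes=0)
        assert out.n_obs == 3

    def test_idempotent(self, small_cohort):
        adata, _ = small_cohort
        once = filter_cells(adata, min_genes=200)
        twice = filter_cells(once, min_genes=200)
        assert list(once.obs_names) == list(twice.obs_names)

    def test_matches_bruteforce_nonzero_tally(self, small_cohort):
        adata, _ = small_cohort
        out = filter_cells(adata, min_genes=250)
        dense = adata.X.toarray()
        expected = [c for c, row in zip(adata.obs_names, dense) if (row > 0).sum() >= 250]
        assert list(out.obs_names) == expected

    def test_empty_result_warns_not_raises(self):
        adata = _adata_with_gene_counts([3, 5], n_genes=20)
        with pytest.warns(UserWarning, match="removed every cell"):
            out = filter_cells(adata, min_genes=10)
        assert out.n_obs == 0


class TestLogNormalize:
    def test_formula(self):
        adata = make_adata(np.array([[0, 10], [5, 5]]))
        norm = lognormalize(adata, scale_factor=1e4)
        X = norm.X.toarray()
        assert X[0, 0] == 0.0
        # a cell whose entire mass is one gene
        assert X[0, 1] == pytest.approx(np.log1p(1e4), abs=1e-9)
        assert X[1, 0] == pytest.approx(np.log1p(0.5 * 1e4), rel=1e-12)

    def test_composition_invariance(self):
        a = make_adata(np.array([[2, 3, 5]]))
        b = make_adata(np.array([[4, 6, 10]]))
        np.testing.assert_allclose(
            lognormalize(a).X.toarray(), lognormalize(b).X.toarray(), rtol=1e-12
        )

    def test_zero_total_cell_named_in_error(self):
        adata = make_adata(np.array([[0, 0], [1, 2]]), cell_ids=["deadcell", "ok"])
        with pytest.raises(DataError, match="deadcell"):
            lognormalize(adata)


class TestSelectHVG:
    def test_planted_variance_inflation_recovered(self):
        rng = np.random.default_rng(0)
        n_cells, n_genes, n_hv = 300, 500, 50
        counts = rng.poisson(5.0, size=(n_cells, n_genes)).astype(float)
        # same mean, ~4x the variance: 50/50 mixture of 0 and 10
        counts[:, :n_hv] = 10.0 * rng.integers(0, 2, size=(n_cells, n_hv))
        adata = make_adata(counts)
        top = select_hvg(adata, n_top=n_hv)
        planted = set(adata.var_names[:n_hv])
        assert len(planted & set(top)) >= 0.9 * n_hv

    def test_n_at_least_n_genes_returns_all(self):
        adata = make_adata(np.random.default_rng(1).poisson(3, size=(20, 30)))
        assert set(select_hvg(adata, n_top=100)) == set(adata.var_names)

    def test_constant_genes_stable_tiebreak(self):
        adata = make_adata(np.ones((10, 8)))
        assert select_hvg(adata, n_top=3) == list(adata.var_names[:3])


@pytest.fixture(scope="module")
def two_pop():
    """Two well-separated planted populations (strong markers, low noise)."""
    from ulcermap.synthetic import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_patients_per_group=2, groups=("healthy",), cells_per_patient=150,
        n_cell_types=2, n_genes=400, markers_per_type=25, marker_log2fc=4.0,
        n_stem_genes=20, n_de_genes=20, stem_log2fc=0.0, nb_dispersion=0.1,
        seed=21,
    )
    adata, truth = simulate_cohort(cfg)
    return lognormalize(filter_cells(adata, 50)), truth


class TestEmbedAndCluster:
    def test_two_planted_populations_recovered(self, two_pop):
        adata, truth = two_pop
        hvgs = select_hvg(adata, n_top=200)
        labels = embed_and_cluster(adata, hvgs, n_pcs=10, resolution=0.8, seed=0)
        assert len(set(labels)) == 2
        # each cluster is pure in one true type
        truth_types = truth.cell_types.loc[adata.obs_names]
        purity = pd.crosstab(labels, truth_types).max(axis=1).sum() / len(labels)
        assert purity == 1.0

    def test_same_seed_identical_labels(self, two_pop):
        adata, _ = two_pop
        hvgs = select_hvg(adata, n_top=200)
        l1 = embed_and_cluster(adata, hvgs, n_pcs=10, seed=7)
        l2 = embed_and_cluster(adata, hvgs, n_pcs=10, seed=7)
        assert np.array_equal(l1, l2)

    def test_bypass_labels_returned_unchanged(self, two_pop):
        adata, truth = two_pop
        ext = truth.cell_types.loc[adata.obs_names].to_numpy()
        out = embed_and_cluster(adata, [], labels=ext)
        assert np.array_equal(out, ext)

    def test_too_few_cells_actionable_error(self):
        adata = make_adata(np.random.default_rng(0).poisson(3, size=(10, 40)).astype(float))
        with pytest.raises(DataError, match="n_pcs"):
            embed_and_cluster(adata, list(adata.var_names), n_pcs=30)


class TestMergeMarkerlessClusters:
    def test_artificial_subsplit_merged_back(self, two_pop):
        """A pure sub-cluster of one population has no one-vs-rest markers
        and is merged into its sibling; both surviving clusters keep theirs."""
        from ulcermap.preprocess import merge_markerless_clusters

        adata, truth = two_pop
        adata = adata.copy()
        hvgs = select_hvg(adata, n_top=200)
        embed_and_cluster(adata, hvgs, n_pcs=10, seed=0)
        # force a split of the larger type into two labels
        tt = truth.cell_types.loc[adata.obs_names].to_numpy()
        big = pd.Series(tt).mode().iloc[0]
        labels = np.where(tt == big, "0", "1")
        idx = np.where(labels == "0")[0]
        labels[idx[: len(idx) // 3]] = "2"
        adata.obs["cluster"] = pd.Categorical(labels)
        merged, markers = merge_markerless_clusters(adata)
        assert set(merged) == {"0", "1"}
        assert (merged == "0").sum() == (tt == big).sum()
        assert set(markers["cluster"]) == {"0", "1"}

    def test_noop_when_all_clusters_have_markers(self, two_pop):
        from ulcermap.preprocess import merge_markerless_clusters

        adata, truth = two_pop
        adata = adata.copy()
        hvgs = select_hvg(adata, n_top=200)
        embed_and_cluster(adata, hvgs, n_pcs=10, seed=0)
        before = adata.obs["cluster"].to_numpy().astype(str)
        after, _ = merge_markerless_clusters(adata)
        assert np.array_equal(before, after)


class TestFindMarkers:
    def test_planted_markers_detected_and_null_genes_absent(self, small_cohort):
        adata, truth = small_cohort
        norm = lognormalize(filter_cells(adata, 50))
        table = find_markers(norm, labels=truth.cell_types.loc[norm.obs_names].to_numpy())
        by_cluster = {c: set(sub["gene"]) for c, sub in table.groupby("cluster")}
        for ctype, markers in truth.marker_genes.items():
            found = by_cluster.get(ctype, set())
            assert len(found & set(markers)) >= 0.9 * len(markers)
        # genes with no planted program never appear
        programmed = {g for gs in truth.marker_genes.values() for g in gs}
        programmed |= set(truth.stem_genes)
        for genes in by_cluster.values():
            assert not (genes - programmed)

    def test_emitted_rows_respect_thresholds(self, small_cohort):
        adata, truth = small_cohort
        norm = lognormalize(filter_cells(adata, 50))
        table = find_markers(
            norm, labels=truth.cell_types.loc[norm.obs_names].to_numpy(),
            logfc_threshold=1.0, max_p=0.01,
        )
        assert (table["log2fc"] >= 1.0).all()
        assert (table["p_value"] <= 0.01).all()

    def test_wilcoxon_matches_exact_enumeration(self):
        """5-vs-5 p-value equals the brute-force rank permutation tail."""
        x = np.array([1.2, 3.4, 5.1, 7.8, 9.0])
        y = np.array([0.5, 2.2, 4.4, 6.1, 6.5])
        p = wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1.0
        obs = ranks[:5].sum()
        n = 0
        total = 0
        mu = 5 * 11 / 2.0
        for combo in itertools.combinations(range(10), 5):
            s = ranks[list(combo)].sum()
            total += 1
            if abs(s - mu) >= abs(obs - mu) - 1e-12:
                n += 1
        assert p == pytest.approx(n / total, abs=1e-12)

    def test_tiny_cluster_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(20, 30)).astype(float)
        adata = make_adata(counts)
        norm = lognormalize(adata)
        labels = np.array(["a"] * 18 + ["b"] * 2)
        with pytest.warns(UserWarning, match="excluded"):
            table = find_markers(norm, labels=labels)
        assert "b" not in set(table["cluster"])

    def test_label_permutation_invariance(self, small_cohort):
        adata, truth = small_cohort
        norm = lognormalize(filter_cells(adata, 50))
        labels = truth.cell_types.loc[norm.obs_names].to_numpy()
        table1 = find_markers(norm, labels=labels)
        renamed = np.array(["X_" + l for l in labels])
        table2 = find_markers(norm, labels=renamed)
        pairs1 = {(c, frozenset(sub["gene"])) for c, sub in table1.groupby("cluster")}
        pairs2 = {(c[2:], frozenset(sub["gene"])) for c, sub in table2.groupby("cluster")}
        assert pairs1 == pairs2
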