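"""Fisher/Jaccard cluster annotation and composition comparisons."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ulcermap.annotation import (
    MarkerReference,
    UNKNOWN,
    annotate_clusters,
    assign_cell_type,
    compare_proportions,
    compose_by_group,
    fisher_overlap,
    jaccard,
    patient_fractions,
    score_cluster,
    significance_tier,
)
from ulcermap.errors import DataError


def _universe(n):
    return {f"g{i}" for i in range(n)}


def brute_force_tail(k, n_a, n_b, n_universe):
    """P(overlap >= k) by direct hypergeometric pmf summation."""
    total = comb(n_universe, n_a)
    acc = 0
    for j in range(k, min(n_a, n_b) + 1):
        acc += comb(n_b, j) * comb(n_universe - n_b, n_a - j)
    return acc / total


class TestFisherOverlap:
    def test_worked_example_full_overlap(self):
        """|A|=|B|=k=5, N=20: p = 1/C(20,5) = 1/15504."""
        uni = _universe(20)
        a = {f"g{i}" for i in range(5)}
        k, p = fisher_overlap(a, set(a), uni)
        assert k == 5
        assert p == pytest.approx(1.0 / 15504, abs=1e-12)

    def test_disjoint_sets_give_p_one(self):
        uni = _universe(30)
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(5, 10)}
        k, p = fisher_overlap(a, b, uni)
        assert k == 0
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_tail_sum_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_uni = int(rng.integers(10, 40))
            uni_list = sorted(_universe(n_uni))
            n_a = int(rng.integers(1, n_uni))
            n_b = int(rng.integers(1, n_uni))
            a = set(rng.choice(uni_list, n_a, replace=False))
            b = set(rng.choice(uni_list, n_b, replace=False))
            k, p = fisher_overlap(a, b, set(uni_list))
            assert p == pytest.approx(brute_force_tail(k, n_a, n_b, n_uni), abs=1e-12)

    def test_adding_shared_gene_never_increases_p(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_uni = int(rng.integers(15, 40))
            uni_list = sorted(_universe(n_uni))
            a = set(rng.choice(uni_list, int(rng.integers(2, 8)), replace=False))
            b = set(rng.choice(uni_list, int(rng.integers(2, 8)), replace=False))
            outside = [g for g in uni_list if g not in a | b]
            if not outside:
                continue
            _, p0 = fisher_overlap(a, b, set(uni_list))
            g = outside[0]
            _, p1 = fisher_overlap(a | {g}, b | {g}, set(uni_list))
            assert p1 <= p0 + 1e-15

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(DataError, match="alien"):
            fisher_overlap({"alien"}, {"g0"}, _universe(5))

    @given(
        a=st.sets(st.integers(0, 14), min_size=1, max_size=10),
        b=st.sets(st.integers(0, 14), min_size=1, max_size=10),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_p_in_unit_interval(self, a, b):
        uni = set(range(15))
        _, p = fisher_overlap(a, b, uni)
        assert 0.0 < p <= 1.0


class TestJaccard:
    def test_identical_disjoint_and_half(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"g1", "g2", "g3"}, {"g2", "g3", "g4"}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(DataError):
            jaccard(set(), set())

    @given(
        a=st.sets(st.integers(0, 20), max_size=12),
        b=st.sets(st.integers(0, 20), min_size=1, max_size=12),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)


class TestAssignCellType:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["cell_type", "overlap", "p_value", "jaccard"])

    def test_no_significant_candidate_is_unknown(self):
        scores = self._scores([("T cell", 2, 0.2, 0.5), ("B cell", 1, 0.6, 0.9)])
        assert assign_cell_type(scores, alpha=0.05) == UNKNOWN

    def test_single_passing_candidate(self):
        scores = self._scores([("T cell", 5, 0.01, 0.3), ("B cell", 1, 0.6, 0.9)])
        assert assign_cell_type(scores) == "T cell"

    def test_p_tie_broken_by_jaccard(self):
        scores = self._scores([("A", 3, 0.01, 0.3), ("B", 3, 0.01, 0.6)])
        assert assign_cell_type(scores) == "B"

    def test_invariant_to_candidate_order(self):
        rows = [("A", 3, 0.01, 0.3), ("B", 3, 0.01, 0.6), ("C", 2, 0.04, 0.9)]
        for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            scores = self._scores([rows[i] for i in perm])
            assert assign_cell_type(scores) == "B"


class TestAnnotateClusters:
    def test_perfect_reference_annotates_all_clusters(self, small_cohort):
        from ulcermap.preprocess import filter_cells, find_markers, lognormalize
        from ulcermap.synthetic import simulate_marker_reference

        adata, truth = small_cohort
        norm = lognormalize(filter_cells(adata, 50))
        markers = find_markers(
            norm, labels=truth.cell_types.loc[norm.obs_names].to_numpy()
        )
        ref = simulate_marker_reference(truth, noise_frac=0.0)
        out = annotate_clusters(markers, ref, expressed_genes=set(norm.var_names))
        assert (out["cluster"] == out["cell_type"]).all()


class TestComposition:
    @pytest.fixture()
    def meta(self):
        rng = np.random.default_rng(0)
        n = 400
        return pd.DataFrame(
            {
                "patient": rng.choice([f"p{i}" for i in range(8)], n),
                "group": rng.choice(["healthy", "DM"], n),
                "cell_type": rng.choice(["T cell", "B cell", "Monocyte"], n),
            }
        )

    def test_matches_bruteforce_crosstab(self, meta):
        out = compose_by_group(meta)
        for _, row in out.iterrows():
            sub = meta[(meta["group"] == row["group"]) & (meta["cell_type"] == row["cell_type"])]
            n_group = (meta["group"] == row["group"]).sum()
            n_type = (meta["cell_type"] == row["cell_type"]).sum()
            assert row["n_cells"] == len(sub)
            assert row["fraction"] == pytest.approx(len(sub) / n_group, abs=1e-12)
            assert row["group_share"] == pytest.approx(len(sub) / n_type, abs=1e-12)
        sums = out.groupby("group")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_single_group_share_is_one(self, meta):
        solo = meta.assign(group="healthy")
        out = compose_by_group(solo)
        assert np.allclose(out["group_share"], 1.0)

    def test_cell_order_permutation_invariance(self, meta):
        shuffled = meta.sample(frac=1.0, random_state=1)
        a = compose_by_group(meta).sort_values(["group", "cell_type"]).reset_index(drop=True)
        b = compose_by_group(shuffled).sort_values(["group", "cell_type"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_group_rejected(self, meta):
        with pytest.raises(DataError, match="unknown group"):
            compose_by_group(meta, known_groups=["healthy"])


class TestCompareProportions:
    def _per_patient(self, frac_a, frac_b, n=8):
        rows = []
        for i in range(n):
            rows.append((f"a{i}", "healthy", "Macrophage", frac_a[i]))
            rows.append((f"b{i}", "DFU", "Macrophage", frac_b[i]))
        return pd.DataFrame(rows, columns=["patient", "group", "cell_type", "fraction"])

    def test_identical_fractions_are_ns(self):
        pp = self._per_patient([0.2] * 8, [0.2] * 8)
        out = compare_proportions(pp)
        assert (out["tier"] == "ns").all()

    def test_planted_composition_shift_detected(self):
        rng = np.random.default_rng(3)
        a = np.clip(rng.normal(0.10, 0.02, 8), 0, 1)
        b = np.clip(rng.normal(0.40, 0.02, 8), 0, 1)
        out = compare_proportions(self._per_patient(a, b))
        assert out.iloc[0]["tier"] in ("**", "***")

    def test_tiers_monotone_in_p(self):
        cuts = [(0.0005, "***"), (0.01, "**"), (0.07, "*"), (0.5, "ns")]
        for p, tier in cuts:
            assert significance_tier(p) == tier
        ps = np.linspace(0, 1, 101)
        order = {"***": 0, "**": 1, "*": 2, "ns": 3}
        tiers = [order[significance_tier(p)] for p in ps]
        assert tiers == sorted(tiers)

    def test_underpowered_group_marked_ns_with_warning(self):
        full = self._per_patient([0.1] * 8, [0.4] * 8)
        pp = pd.concat(
            [full[full["group"] == "healthy"], full[full["group"] == "DFU"].iloc[:1]]
        )
        with pytest.warns(UserWarning, match="<2 patients"):
            out = compare_proportions(pp)
        assert (out["tier"] == "ns").all()


def test_patient_fractions_sum_to_one(small_cohort):
    adata, truth = small_cohort
    meta = adata.obs.assign(cell_type=truth.cell_types.loc[adata.obs_names])
    pp = patient_fractions(meta)
    sums = pp.groupby("patient")["fraction"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
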