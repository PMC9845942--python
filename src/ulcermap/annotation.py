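"""Cluster annotation by marker-set overlap, and group composition analysis.

Clusters are labeled by comparing their detected marker genes against a
curated reference of cell-type marker sets (e.g. a CellMarker-style catalog):
for every candidate type we compute a one-sided Fisher exact (hypergeometric
enrichment) p-value and the Jaccard coefficient of the two sets, then assign
the type with the lowest p-value at significance level alpha, breaking ties
by the higher Jaccard coefficient; a cluster with no significant candidate is
labeled ``unknown``.

Cell-type composition is tabulated per clinical group in both orientations
(fraction of a group's cells per type, and each type's share contributed by
each group), and group differences in per-patient fractions are tested with
the Wilcoxon rank-sum test, reported on the significance tiers
``*`` p<0.1, ``**`` p<0.05, ``***`` p<0.001.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

UNKNOWN = "unknown"


@dataclass
class MarkerReference:
    """Mapping cell-type name -> marker gene set, with a gene universe."""

    type_sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.type_sets = {t: set(g) for t, g in self.type_sets.items()}
        self.universe = set(self.universe)
        for t, genes in self.type_sets.items():
            if not genes:
                raise DataError(f"marker reference: empty gene set for '{t}'")
            extra = genes - self.universe
            if extra:
                raise DataError(
                    f"marker reference: genes of '{t}' outside universe: "
                    f"{sorted(extra)[:5]}"
                )

    def restricted(self, genes: set[str]) -> "MarkerReference":
        """Intersect the universe (and every set) with an expression gene set;
        types whose set becomes empty are dropped."""
        uni = self.universe & set(genes)
        sets = {t: g & uni for t, g in self.type_sets.items()}
        sets = {t: g for t, g in sets.items() if g}
        return MarkerReference(type_sets=sets, universe=uni)


def fisher_overlap(
    cluster_genes: set[str], type_genes: set[str], universe: set[str]
) -> tuple[int, float]:
    """One-sided enrichment p-value for the overlap of two gene sets.

    The p-value is the hypergeometric upper tail P(X >= k) of drawing
    ``|cluster_genes|`` genes from a universe of size N containing
    ``|type_genes|`` successes.
    """
    a, b, uni = set(cluster_genes), set(type_genes), set(universe)
    if not uni:
        raise DataError("empty gene universe")
    bad = (a | b) - uni
    if bad:
        raise DataError(f"genes outside universe: {sorted(bad)[:10]}")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(b), len(a)))
    return k, min(p, 1.0)


def jaccard(a: set[str], b: set[str]) -> float:
    """|a ∩ b| / |a ∪ b|."""
    a, b = set(a), set(b)
    if not a and not b:
        raise DataError("Jaccard coefficient undefined for two empty sets")
    return len(a & b) / len(a | b)


def score_cluster(
    cluster_genes: set[str], reference: MarkerReference
) -> pd.DataFrame:
    """Fisher p-value and Jaccard coefficient of one cluster's marker set
    against every reference cell type."""
    rows = []
    for ctype in sorted(reference.type_sets):
        tset = reference.type_sets[ctype]
        k, p = fisher_overlap(cluster_genes, tset, reference.universe)
        rows.append((ctype, k, p, jaccard(cluster_genes, tset) if cluster_genes or tset else 0.0))
    return pd.DataFrame(rows, columns=["cell_type", "overlap", "p_value", "jaccard"])


def assign_cell_type(scores: pd.DataFrame, alpha: float = 0.05) -> str:
    """Lowest p-value wins among candidates with p <= alpha; ties on p are
    broken by the highest Jaccard, then by name order; otherwise ``unknown``."""
    if scores.empty:
        raise DataError("no candidate cell types scored")
    passing = scores[scores["p_value"] <= alpha]
    if passing.empty:
        return UNKNOWN
    ranked = passing.sort_values(
        ["p_value", "jaccard", "cell_type"], ascending=[True, False, True]
    )
    return str(ranked.iloc[0]["cell_type"])


def annotate_clusters(
    markers: pd.DataFrame,
    reference: MarkerReference,
    expressed_genes: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotate every cluster in a marker table (columns cluster, gene).

    The test universe is the reference universe, optionally intersected with
    the genes present in the expression matrix; cluster marker sets are
    restricted to that universe before testing.
    """
    ref = reference if expressed_genes is None else reference.restricted(expressed_genes)
    if not ref.type_sets:
        raise DataError("no reference cell type overlaps the expressed genes")
    rows = []
    for cluster, sub in markers.groupby("cluster", sort=True):
        cset = set(sub["gene"]) & ref.universe
        scores = score_cluster(cset, ref)
        label = assign_cell_type(scores, alpha=alpha)
        if label == UNKNOWN:
            best = scores.sort_values(["p_value", "cell_type"]).iloc[0]
        else:
            best = scores[scores["cell_type"] == label].iloc[0]
        rows.append(
            (cluster, label, float(best["p_value"]), float(best["jaccard"]),
             int(best["overlap"]), len(cset))
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", "cell_type", "p_value", "jaccard", "overlap", "n_cluster_genes"],
    )


def compose_by_group(meta: pd.DataFrame, known_groups: list[str] | None = None) -> pd.DataFrame:
    """Cell-type composition per clinical group, in both orientations.

    ``fraction`` is the share of a group's cells belonging to the type
    (sums to 1 within each group); ``group_share`` is the share of the
    type's cells contributed by the group (sums to 1 within each type).
    """
    for col in ("group", "cell_type"):
        if col not in meta.columns:
            raise DataError(f"cell metadata lacks a '{col}' column")
    if known_groups is not None:
        bad = set(meta["group"]) - set(known_groups)
        if bad:
            raise DataError(f"unknown group labels: {sorted(bad)}")
    tab = pd.crosstab(meta["group"], meta["cell_type"])
    frac = tab.div(tab.sum(axis=1), axis=0)
    share = tab.div(tab.sum(axis=0), axis=1)
    out = (
        tab.stack().rename("n_cells").reset_index()
        .merge(frac.stack().rename("fraction").reset_index())
        .merge(share.stack().rename("group_share").reset_index())
    )
    return out[["group", "cell_type", "n_cells", "fraction", "group_share"]]


def patient_fractions(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-patient cell-type fractions (tidy: patient, group, cell_type, fraction)."""
    tab = pd.crosstab([meta["patient"], meta["group"]], meta["cell_type"])
    frac = tab.div(tab.sum(axis=1), axis=0)
    out = frac.stack().rename("fraction").reset_index()
    return out


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return "ns"


def compare_proportions(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Pairwise group comparison of per-patient cell-type fractions.

    Wilcoxon rank-sum test per cell type and group pair; patient-level
    fractions (not pooled cells) are the sampling unit. Groups with fewer
    than two patients are reported as ``ns`` with a warning.
    """
    required = {"patient", "group", "cell_type", "fraction"}
    if not required <= set(per_patient.columns):
        raise DataError(f"per-patient table needs columns {sorted(required)}")
    groups = list(pd.unique(per_patient["group"]))
    rows = []
    for ctype, sub in per_patient.groupby("cell_type", sort=True):
        by_group = {g: sub.loc[sub["group"] == g, "fraction"].to_numpy() for g in groups}
        for g1, g2 in itertools.combinations(groups, 2):
            x, y = by_group.get(g1, []), by_group.get(g2, [])
            if len(x) < 2 or len(y) < 2:
                warnings.warn(
                    f"{ctype}: group pair ({g1}, {g2}) has <2 patients; marked ns"
                )
                rows.append((ctype, g1, g2, np.nan, "ns"))
                continue
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            rows.append((ctype, g1, g2, p, significance_tier(p)))
    return pd.DataFrame(rows, columns=["cell_type", "group_a", "group_b", "p_value", "tier"])
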