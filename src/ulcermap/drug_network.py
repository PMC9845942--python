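"""Drug–gene network construction and random-walk-with-restart drug ranking.

The network is a heterogeneous undirected graph: drug–gene edges come from
an interaction table (DGIdb export dialect: columns ``drug_claim_name``,
``gene_name``), and gene–gene edges from a Spearman co-expression screen on
bulk expression (p <= 0.05 and rho > 0.70, one-sided positive by default).

Drugs are prioritized by a random walk with restart (RWR) from candidate
target genes: iterate v <- (1 - r) W v + r e with W the column-normalized
adjacency matrix, e uniform over the present seed genes and restart
probability r = 0.1, until the L1 change between iterations falls below
1e-10. Drug nodes are ranked by their steady-state visiting probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import ConvergenceError, DataError

DRUG = "drug"
GENE = "gene"


def spearman_edges(
    tpm: pd.DataFrame,
    genes: set[str],
    min_rho: float = 0.70,
    max_p: float = 0.05,
    absolute: bool = False,
) -> pd.DataFrame:
    """Significant co-expression edges among ``genes`` across bulk samples.

    Spearman rho with the t-approximation p-value; an edge is emitted when
    p <= max_p and rho > min_rho (or |rho| > min_rho when ``absolute``).
    Constant genes are excluded with a warning (ranks undefined). Pairs are
    returned in canonical order (gene_a < gene_b).
    """
    present = sorted(set(genes) & set(tpm.index))
    if tpm.shape[1] < 4:
        raise DataError("Spearman screen needs >= 4 samples")
    X = tpm.loc[present].to_numpy(dtype=float)
    const = np.all(X == X[:, :1], axis=1)
    if const.any():
        dropped = [g for g, c in zip(present, const) if c]
        warnings.warn(f"excluding {len(dropped)} constant gene(s) from co-expression")
        present = [g for g, c in zip(present, const) if not c]
        X = X[~const]
    if len(present) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "rho", "p_value"])
    res = stats.spearmanr(X, axis=1)
    if len(present) == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        pval = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        rho, pval = res.statistic, res.pvalue
    rows = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            r, p = float(rho[i, j]), float(pval[i, j])
            passes = (abs(r) if absolute else r) > min_rho and p <= max_p
            if passes:
                a, b = sorted((present[i], present[j]))
                rows.append((a, b, r, p))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p_value"])


def build_network(
    interactions: pd.DataFrame, coexpr: pd.DataFrame | None = None
) -> nx.Graph:
    """Union of drug–gene interaction edges and gene–gene co-expression edges.

    Duplicate records collapse to a single edge; a drug whose name collides
    with a gene symbol is namespaced (``drug:``/``gene:`` prefixes) with a
    warning. Node attribute ``kind`` is ``drug`` or ``gene``; edge attribute
    ``kind`` is ``interaction`` or ``coexpression``.
    """
    for col in ("drug_claim_name", "gene_name"):
        if len(interactions) and col not in interactions.columns:
            raise DataError(f"interaction table lacks column '{col}'")
    drugs = set(interactions["drug_claim_name"]) if len(interactions) else set()
    genes = set(interactions["gene_name"]) if len(interactions) else set()
    if coexpr is not None and len(coexpr):
        genes |= set(coexpr["gene_a"]) | set(coexpr["gene_b"])
    collisions = drugs & genes
    if collisions:
        warnings.warn(
            f"{len(collisions)} drug name(s) collide with gene symbols; "
            f"namespacing with 'drug:'/'gene:' prefixes"
        )

    def drug_node(d: str) -> str:
        return f"drug:{d}" if d in collisions else d

    def gene_node(g: str) -> str:
        return f"gene:{g}" if g in collisions else g

    g_net = nx.Graph()
    if len(interactions):
        for d, gn in interactions[["drug_claim_name", "gene_name"]].itertuples(index=False):
            dn, gnn = drug_node(d), gene_node(gn)
            g_net.add_node(dn, kind=DRUG, name=d)
            g_net.add_node(gnn, kind=GENE, name=gn)
            g_net.add_edge(dn, gnn, kind="interaction")
    if coexpr is not None and len(coexpr):
        for a, b in coexpr[["gene_a", "gene_b"]].itertuples(index=False):
            if a == b:
                continue
            an, bn = gene_node(a), gene_node(b)
            g_net.add_node(an, kind=GENE, name=a)
            g_net.add_node(bn, kind=GENE, name=b)
            g_net.add_edge(an, bn, kind="coexpression")
    isolated = [n for n in g_net.nodes if g_net.degree(n) == 0]
    if isolated:
        g_net.remove_nodes_from(isolated)
        warnings.warn(f"dropped {len(isolated)} isolated node(s)")
    return g_net


@dataclass
class WalkResult:
    """Steady-state node weights of a restart walk."""

    weights: pd.Series  # node -> weight, sums to 1
    restart: float
    n_iter: int
    final_delta: float
    seeds_used: list[str]


def _seed_nodes(network: nx.Graph, seeds: set[str]) -> list[str]:
    """Map seed gene symbols to node names (handling namespaced collisions)."""
    present = []
    for s in seeds:
        if s in network and network.nodes[s].get("kind") == GENE:
            present.append(s)
        elif f"gene:{s}" in network:
            present.append(f"gene:{s}")
    return sorted(present)


def rwr(
    network: nx.Graph,
    seeds: set[str],
    restart: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> WalkResult:
    """Random walk with restart from seed gene nodes.

    Power iteration of v <- (1 - r) W v + r e, W column-normalized, e uniform
    over the seeds present in the network, v0 = e; stops when the L1 change
    drops below ``tol``.
    """
    if not 0.0 < restart < 1.0:
        raise DataError("restart probability must lie in (0, 1)")
    if network.number_of_nodes() == 0:
        raise DataError("empty network")
    present = _seed_nodes(network, set(seeds))
    if not present:
        raise DataError(f"no seed present in the network; missing: {sorted(seeds)[:10]}")

    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    A = nx.to_scipy_sparse_array(network, nodelist=nodes, format="csc", dtype=float)
    deg = np.asarray(A.sum(axis=0)).ravel()
    dangling = deg == 0
    safe_deg = np.where(dangling, 1.0, deg)
    W = A @ sparse.diags(1.0 / safe_deg)

    e = np.zeros(len(nodes))
    e[[index[s] for s in present]] = 1.0 / len(present)
    v = e.copy()
    delta = np.inf
    for it in range(1, max_iter + 1):
        # mass on dangling nodes restarts at the seeds (keeps sum(v) = 1)
        v_new = (1.0 - restart) * (W @ v + float(v[dangling].sum()) * e) + restart * e
        delta = float(np.abs(v_new - v).sum())
        v = v_new
        if delta < tol:
            return WalkResult(
                weights=pd.Series(v, index=nodes, name="weight"),
                restart=restart,
                n_iter=it,
                final_delta=delta,
                seeds_used=present,
            )
    raise ConvergenceError(
        f"restart walk did not converge in {max_iter} iterations "
        f"(final L1 delta {delta:.3e})"
    )


def rank_drugs(result: WalkResult, network: nx.Graph) -> pd.DataFrame:
    """Drug nodes ordered by steady-state weight (descending, ties by name)."""
    rows = []
    for n, w in result.weights.items():
        if n in network and network.nodes[n].get("kind") == DRUG:
            rows.append((network.nodes[n].get("name", n), float(w)))
    out = pd.DataFrame(rows, columns=["drug", "weight"])
    out = out.sort_values(["weight", "drug"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def read_interactions(path: str) -> pd.DataFrame:
    """Read a DGIdb-style interaction TSV (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("drug_claim_name", "gene_name"):
        if col not in df.columns:
            raise DataError(f"interaction file lacks column '{col}': {path}")
    return df[[c for c in df.columns]]
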