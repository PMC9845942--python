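"""Bulk differential expression screen, target nomination, and qPCR utility.

Differential expression between two clinical groups is screened per gene
with Welch's t-test on log2(TPM + 1); a gene is flagged dysregulated when
the raw p-value is below 0.05 and |log2 fold change| exceeds 1 (fold change
of group means with a pseudocount of 1). Benjamini–Hochberg adjusted
p-values are reported alongside but do not enter the flag.

Candidate drug targets are the genes up-regulated in ulcers that also
belong to the marker programs of the cell populations of interest
(monocytes and stem populations in the DFU setting).

``ddct`` implements the qPCR 2^-ΔΔCt relative-expression formula against a
reference gene (e.g. GAPDH) and a control condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError


def check_tpm(tpm: pd.DataFrame, tol: float = 1e-3) -> None:
    """Warn if sample columns do not sum to 1e6 (real-world files drift)."""
    sums = tpm.sum(axis=0)
    off = sums[(sums - 1e6).abs() > tol]
    if len(off):
        warnings.warn(
            f"{len(off)} sample column(s) do not sum to 1e6 (first: "
            f"{off.index[0]} = {off.iloc[0]:.3f})"
        )
    if (tpm.to_numpy() < 0).any():
        raise DataError("negative TPM values")


def de_screen(
    tpm: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    max_p: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test screen of group_a vs group_b on log2(TPM + 1).

    Returns one row per gene with log2fc (a relative to b), p_value, adj_p
    (BH) and the dysregulated flag p < max_p AND |log2fc| > min_abs_log2fc.
    """
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DataError(
            f"need >= 2 samples per group (got {len(a_cols)} in '{group_a}', "
            f"{len(b_cols)} in '{group_b}')"
        )
    missing = [c for c in list(a_cols) + list(b_cols) if c not in tpm.columns]
    if missing:
        raise DataError(f"samples missing from TPM table: {missing[:5]}")
    A = tpm[a_cols].to_numpy(dtype=float)
    B = tpm[b_cols].to_numpy(dtype=float)
    log2fc = np.log2((A.mean(axis=1) + 1.0) / (B.mean(axis=1) + 1.0))
    with np.errstate(invalid="ignore"):
        t = stats.ttest_ind(np.log2(A + 1.0), np.log2(B + 1.0), axis=1, equal_var=False)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": tpm.index,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
        }
    )
    out["dysregulated"] = (out["p_value"] < max_p) & (out["log2fc"].abs() > min_abs_log2fc)
    return out


def nominate_targets(
    dfu_up: set[str], population_markers: dict[str, set[str]]
) -> list[str]:
    """Genes up-regulated in ulcers that are also markers of the cell
    populations of interest; sorted, deterministic."""
    if not dfu_up:
        raise DataError("empty up-regulated gene set")
    if not population_markers:
        raise DataError("no population marker sets supplied")
    union: set[str] = set()
    for genes in population_markers.values():
        union |= set(genes)
    return sorted(set(dfu_up) & union)


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """2^-ΔΔCt relative expression (case vs control, against a reference gene)."""
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise DataError("CT values must be finite")
    ddct_val = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_val))
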