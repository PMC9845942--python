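"""One-class logistic regression (OCLR) stemness scoring — the mRNAsi index.

The stemness ("dryness") of a sample is quantified in three steps:

1. **Pseudobulk**: for every patient, the log-normalized expression of all
   cells of a given type is averaged into one profile, so each patient
   contributes one sample per cell type.
2. **One-class fit**: a weight vector ``w`` is learned from stem-cell
   training profiles only, minimizing

       L(w) = sum_i ln(1 + exp(-w . x_i)) + (lambda/2) ||w||^2

   by full-batch gradient descent with backtracking line search. The
   training profiles are centered per gene against a baseline profile (for
   example the mean of non-stem cells). Centering against the training
   mean itself is supported for completeness but makes the one-class
   objective degenerate (sum_i x_i = 0 puts the global minimum at w = 0),
   so a baseline is the recommended and default pipeline behavior.
3. **Scoring**: a sample's raw score is the Spearman rank correlation of
   ``w`` with the sample's expression over the shared genes; within a
   scored cohort the raw scores are min–max scaled to the mRNAsi in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

import anndata as ad

from .errors import ConvergenceError, DataError


def pseudobulk(
    adata: ad.AnnData,
    cell_type: str,
    type_key: str = "cell_type",
    patient_key: str = "patient",
) -> pd.DataFrame:
    """Per-patient mean expression profile of one cell type.

    Returns a patients x genes frame; ``attrs['n_cells']`` maps patient ->
    number of contributing cells. Patients without cells of the type are
    omitted; a type absent everywhere yields an empty frame with a warning.
    """
    for key in (type_key, patient_key):
        if key not in adata.obs:
            raise DataError(f"cell metadata lacks '{key}'")
    mask = (adata.obs[type_key] == cell_type).to_numpy()
    if not mask.any():
        warnings.warn(f"cell type '{cell_type}' absent from metadata; empty pseudobulk")
        out = pd.DataFrame(columns=adata.var_names)
        out.attrs["n_cells"] = {}
        return out
    sub = adata[mask]
    X = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X)
    patients = sub.obs[patient_key].to_numpy()
    rows, index, n_cells = [], [], {}
    for p in pd.unique(patients):
        pm = patients == p
        rows.append(X[pm].mean(axis=0))
        index.append(p)
        n_cells[p] = int(pm.sum())
    out = pd.DataFrame(np.vstack(rows), index=index, columns=adata.var_names)
    out.attrs["n_cells"] = n_cells
    return out


@dataclass
class StemnessModel:
    """Per-gene weights of the one-class stemness signature."""

    weights: pd.Series
    lam: float
    converged: bool
    n_iter: int
    objective: float

    @property
    def training_gene_ids(self) -> list[str]:
        return list(self.weights.index)


def train_oclr(
    training: pd.DataFrame,
    lam: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 5000,
    baseline: pd.Series | None = None,
    center: bool = True,
) -> StemnessModel:
    """Fit the one-class logistic stemness model on positive-class profiles.

    Parameters
    ----------
    training
        samples x genes matrix of stem-cell expression profiles (>= 2 rows).
    baseline
        Per-gene reference profile subtracted before fitting (recommended:
        the mean profile of a non-stem background population). When omitted
        and ``center`` is true, genes are centered on the training mean —
        note this self-centered variant has its optimum at w = 0.
    """
    if training.shape[0] < 2:
        raise DataError("need >= 2 training profiles")
    X = training.to_numpy(dtype=float)
    if baseline is not None:
        base = baseline.reindex(training.columns)
        if base.isna().any():
            missing = base.index[base.isna()][:5].tolist()
            raise DataError(f"baseline lacks training genes: {missing}")
        X = X - base.to_numpy(dtype=float)
    elif center:
        X = X - X.mean(axis=0)

    def objective(w: np.ndarray) -> float:
        return float(np.logaddexp(0.0, -X @ w).sum() + 0.5 * lam * w @ w)

    def gradient(w: np.ndarray) -> np.ndarray:
        s = X @ w
        return -X.T @ (1.0 / (1.0 + np.exp(s))) + lam * w

    w = np.zeros(X.shape[1])
    obj = objective(w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = gradient(w)
        step = 1.0 / max(1.0, np.linalg.norm(g))
        # backtracking line search (Armijo)
        new_obj = np.inf
        for _ in range(60):
            w_new = w - step * g
            new_obj = objective(w_new)
            if not np.isfinite(new_obj):
                raise ConvergenceError(f"non-finite objective at iteration {it}")
            if new_obj <= obj - 1e-4 * step * float(g @ g):
                break
            step *= 0.5
        if new_obj > obj:  # no descent step found
            converged = True
            break
        delta = obj - new_obj
        w, obj = w_new, new_obj
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"OCLR did not converge in {max_iter} iterations")
    model = StemnessModel(
        weights=pd.Series(w, index=training.columns, name="weight"),
        lam=lam,
        converged=converged,
        n_iter=it,
        objective=obj,
    )
    if np.allclose(w, 0.0):
        warnings.warn(
            "OCLR weights are all ~0 (degenerate fit; self-centered training data?)"
        )
    return model


def score_stemness(model: StemnessModel, profile: pd.Series) -> float:
    """Raw stemness score: Spearman correlation of the model weights with the
    profile's expression over the genes shared by both."""
    shared = model.weights.index.intersection(profile.index)
    if len(shared) < 3:
        raise DataError(f"only {len(shared)} genes shared between model and profile")
    x = profile.loc[shared].to_numpy(dtype=float)
    w = model.weights.loc[shared].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise DataError("constant expression profile: Spearman ranks undefined")
    if np.all(w == w[0]):
        raise DataError("constant model weights: Spearman ranks undefined")
    return float(stats.spearmanr(w, x).statistic)


def scale_mrnasi(raw: list[float] | np.ndarray) -> np.ndarray:
    """Min–max scale raw scores to the mRNAsi in [0, 1] within a cohort."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise DataError("no scores to scale")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("all raw scores equal; mRNAsi set to 0")
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def score_cohort(
    model: StemnessModel,
    profiles: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score a cohort of profiles (samples x genes) and min–max scale within it.

    ``meta`` (indexed like ``profiles``) may carry patient / cell_type /
    group columns that are copied into the output.
    """
    if profiles.empty:
        raise DataError("no profiles to score")
    raw = np.array([score_stemness(model, profiles.loc[s]) for s in profiles.index])
    out = pd.DataFrame({"sample": profiles.index, "raw_score": raw})
    out["mrnasi"] = scale_mrnasi(raw)
    if meta is not None:
        for col in meta.columns:
            out[col] = meta.loc[profiles.index, col].to_numpy()
    return out


def stemness_by_group(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean mRNAsi per clinical group (and per cell type when present)."""
    if "group" not in scores.columns:
        raise DataError("scores lack a 'group' column")
    keys = ["group"] + (["cell_type"] if "cell_type" in scores.columns else [])
    out = (
        scores.groupby(keys, sort=True)["mrnasi"]
        .agg(mean_mrnasi="mean", n="size")
        .reset_index()
    )
    return out
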