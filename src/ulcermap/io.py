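"""Readers and writers for the pipeline's on-disk formats.

Single-cell cohorts travel as MatrixMarket sparse counts plus TSV sidecars
(genes.tsv, barcodes.tsv, metadata.tsv); marker references as GMT or
two-column TSV; bulk expression as a genes x samples TSV with a separate
sample -> group TSV; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio, sparse

import anndata as ad

from .annotation import MarkerReference
from .errors import DataError


def write_cohort(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as matrix.mtx (+ genes.tsv, barcodes.tsv, metadata.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", X.astype(np.int64))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs.copy()
    meta.insert(0, "cell_id", meta.index)
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_cohort(indir: str | Path) -> ad.AnnData:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    for fname in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (indir / fname).exists():
            raise DataError(f"missing {fname} in {indir}")
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if X.shape != (len(cells), len(genes)):
        raise DataError(
            f"matrix shape {X.shape} inconsistent with {len(cells)} barcodes "
            f"x {len(genes)} genes"
        )
    if genes.duplicated().any() or cells.duplicated().any():
        raise DataError("duplicate gene or cell identifiers")
    obs = pd.DataFrame(index=cells)
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        obs = meta.reindex(cells)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))


def write_gmt(reference: MarkerReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ctype in sorted(reference.type_sets):
            genes = "\t".join(sorted(reference.type_sets[ctype]))
            fh.write(f"{ctype}\tna\t{genes}\n")


def read_marker_reference(path: str | Path, universe: set[str] | None = None) -> MarkerReference:
    """Read a marker reference from GMT (name, description, genes...) or a
    two-column TSV (cell_type, gene). The universe defaults to the union of
    all sets (extend with the expression gene list downstream)."""
    path = Path(path)
    type_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if path.suffix == ".gmt" or (first and len(first.rstrip("\n").split("\t")) > 2):
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                type_sets.setdefault(parts[0], set()).update(g for g in parts[2:] if g)
        else:
            df = pd.read_csv(fh, sep="\t", header=None, names=["cell_type", "gene"])
            if df.iloc[0, 0] in ("cell_type", "celltype"):
                df = df.iloc[1:]
            for ctype, sub in df.groupby("cell_type"):
                type_sets[str(ctype)] = set(sub["gene"].astype(str))
    if not type_sets:
        raise DataError(f"no marker sets parsed from {path}")
    uni = set().union(*type_sets.values())
    if universe is not None:
        uni |= set(universe)
    return MarkerReference(type_sets=type_sets, universe=uni)


def read_bulk(tpm_path: str | Path, groups_path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Bulk TSV (first column gene, rest samples) + sample->group TSV."""
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    groups.name = "group"
    missing = [s for s in groups.index if s not in tpm.columns]
    if missing:
        raise DataError(f"samples in groups file missing from TPM table: {missing[:5]}")
    return tpm, groups


def write_truth(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1)


def read_training(path: str | Path) -> pd.DataFrame:
    """Training matrix TSV, genes x samples; returned as samples x genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T
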