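"""End-to-end orchestration: simulate → preprocess → annotate → stemness →
bulk DE → drug network, with a machine- and human-readable run report.

Each stage reads/writes plain-text files under the run directory, so stages
can also be re-run individually from intermediate outputs via the CLI.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import annotation as ann
from . import bulk_de, drug_network, io, preprocess, stemness
from . import synthetic
from .errors import ConfigurationError, DataError

STAGES = ("simulate", "preprocess", "annotate", "stemness", "de", "drugnet")


class PipelineConfig(BaseModel):
    """All stage parameters with the study defaults; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "ulcermap_run"
    seed: int = 0
    simulate: bool = True

    # synthetic-data stage
    sim: dict[str, Any] = Field(default_factory=dict)
    bulk_reps: int = Field(default=6, ge=2)
    noise_frac: float = Field(default=0.0, ge=0.0, le=1.0)
    n_drugs: int = Field(default=20, ge=0)
    n_stem_training: int = Field(default=20, ge=2)

    # real-data inputs (required when simulate is false)
    counts_dir: Optional[str] = None
    markers_path: Optional[str] = None
    bulk_tpm_path: Optional[str] = None
    bulk_groups_path: Optional[str] = None
    interactions_path: Optional[str] = None
    training_path: Optional[str] = None

    # preprocessing
    min_genes: int = Field(default=200, ge=0)
    scale_factor: float = Field(default=1e4, gt=0)
    n_hvg: int = Field(default=2000, ge=1)
    n_pcs: int = Field(default=30, ge=2)
    resolution: float = Field(default=0.8, gt=0)
    marker_logfc: float = Field(default=1.0, ge=0)
    marker_max_p: float = Field(default=0.01, gt=0, le=1)

    # annotation
    alpha: float = Field(default=0.05, gt=0, le=1)

    # stemness
    stem_cell_types: list[str] = Field(default_factory=lambda: [synthetic.STEM_TYPE])
    oclr_lambda: float = Field(default=1.0, gt=0)
    oclr_tol: float = Field(default=1e-8, gt=0)
    oclr_max_iter: int = Field(default=5000, ge=1)

    # bulk DE / target nomination
    de_max_p: float = Field(default=0.05, gt=0, le=1)
    de_min_abs_log2fc: float = Field(default=1.0, ge=0)
    target_cell_types: list[str] = Field(
        default_factory=lambda: ["Monocyte", synthetic.STEM_TYPE]
    )

    # drug network
    min_rho: float = Field(default=0.70, ge=0, lt=1)
    coexpr_max_p: float = Field(default=0.05, gt=0, le=1)
    coexpr_absolute: bool = False
    restart: float = Field(default=0.1, gt=0, lt=1)
    rwr_tol: float = Field(default=1e-10, gt=0)
    rwr_max_iter: int = Field(default=10000, ge=1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc

    def validate_inputs(self) -> None:
        """Dry validation pass: fail before any stage runs."""
        if self.simulate:
            return
        required = {
            "counts_dir": self.counts_dir,
            "markers_path": self.markers_path,
            "bulk_tpm_path": self.bulk_tpm_path,
            "bulk_groups_path": self.bulk_groups_path,
            "interactions_path": self.interactions_path,
            "training_path": self.training_path,
        }
        missing = [k for k, v in required.items() if v is None or not Path(v).exists()]
        if missing:
            raise ConfigurationError(
                f"simulate=false but inputs missing or nonexistent: {missing}"
            )


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = outdir / "data"
    report: dict[str, Any] = {
        "seed": config.seed,
        "parameters": json.loads(config.model_dump_json()),
        "stages": [],
    }
    t_run = time.time()

    def record(stage: str, t0: float, counts: dict[str, int]) -> None:
        report["stages"].append(
            {"stage": stage, "seconds": round(time.time() - t0, 3), "records": counts}
        )

    current = "simulate"
    try:
        # --- simulate ----------------------------------------------------
        t0 = time.time()
        if config.simulate:
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", config.seed)
            sim_cfg = synthetic.SimConfig(**sim_kwargs)
            adata, truth = synthetic.simulate_cohort(sim_cfg)
            tpm, bulk_groups, _ = synthetic.simulate_bulk(sim_cfg, config.bulk_reps)
            reference = synthetic.simulate_marker_reference(
                truth, noise_frac=config.noise_frac, seed=config.seed
            )
            interactions = synthetic.simulate_drug_table(
                truth, n_drugs=config.n_drugs, seed=config.seed
            )
            training, baseline = synthetic.simulate_stem_training(
                sim_cfg, n_profiles=config.n_stem_training
            )
            io.write_cohort(adata, data_dir)
            io.write_gmt(reference, data_dir / "markers.gmt")
            tpm.to_csv(data_dir / "bulk_tpm.tsv", sep="\t")
            bulk_groups.to_frame().to_csv(data_dir / "bulk_groups.tsv", sep="\t")
            interactions.to_csv(data_dir / "interactions.tsv", sep="\t", index=False)
            training.T.to_csv(data_dir / "stem_training.tsv", sep="\t")
            baseline.to_frame().to_csv(data_dir / "stem_baseline.tsv", sep="\t")
            io.write_truth(truth.to_dict(), data_dir / "truth.json")
        else:
            adata = io.read_cohort(config.counts_dir)
            reference = io.read_marker_reference(config.markers_path)
            tpm, bulk_groups = io.read_bulk(config.bulk_tpm_path, config.bulk_groups_path)
            interactions = drug_network.read_interactions(config.interactions_path)
            training = io.read_training(config.training_path)
            baseline = None
        record("simulate", t0, {
            "cells": int(adata.n_obs), "genes": int(adata.n_vars),
            "bulk_samples": int(tpm.shape[1]), "drug_interactions": int(len(interactions)),
        })

        # --- preprocess --------------------------------------------------
        current = "preprocess"
        t0 = time.time()
        adata = preprocess.filter_cells(adata, min_genes=config.min_genes)
        if adata.n_obs == 0:
            raise DataError("QC removed every cell")
        adata = preprocess.lognormalize(adata, scale_factor=config.scale_factor)
        hvgs = preprocess.select_hvg(adata, n_top=config.n_hvg)
        preprocess.embed_and_cluster(
            adata, hvgs, n_pcs=config.n_pcs, resolution=config.resolution, seed=config.seed
        )
        labels, markers = preprocess.merge_markerless_clusters(
            adata, logfc_threshold=config.marker_logfc, max_p=config.marker_max_p
        )
        clusters_df = pd.DataFrame(
            {"cell_id": adata.obs_names, "cluster": labels.astype(str)}
        )
        _write(clusters_df, outdir / "clusters.tsv")
        _write(markers, outdir / "markers.tsv")
        record("preprocess", t0, {
            "cells_retained": int(adata.n_obs), "hvgs": len(hvgs),
            "clusters": int(len(set(labels))), "marker_rows": int(len(markers)),
        })

        # --- annotate ----------------------------------------------------
        current = "annotate"
        t0 = time.time()
        ann_df = ann.annotate_clusters(
            markers, reference, expressed_genes=set(adata.var_names), alpha=config.alpha
        )
        _write(ann_df, outdir / "annotation.tsv")
        type_of = dict(zip(ann_df["cluster"].astype(str), ann_df["cell_type"]))
        adata.obs["cell_type"] = [
            type_of.get(str(c), ann.UNKNOWN) for c in adata.obs["cluster"]
        ]
        composition = ann.compose_by_group(adata.obs)
        per_patient = ann.patient_fractions(adata.obs)
        prop_tests = ann.compare_proportions(per_patient)
        _write(composition, outdir / "composition.tsv")
        _write(prop_tests, outdir / "proportion_tests.tsv")
        record("annotate", t0, {
            "clusters_annotated": int(len(ann_df)),
            "unknown_clusters": int((ann_df["cell_type"] == ann.UNKNOWN).sum()),
            "proportion_tests": int(len(prop_tests)),
        })

        # --- stemness ----------------------------------------------------
        current = "stemness"
        t0 = time.time()
        model = stemness.train_oclr(
            training, lam=config.oclr_lambda, tol=config.oclr_tol,
            max_iter=config.oclr_max_iter, baseline=baseline,
        )
        group_of = dict(zip(adata.obs["patient"], adata.obs["group"]))
        profiles, meta_rows = [], []
        for ctype in config.stem_cell_types:
            pb = stemness.pseudobulk(adata, ctype)
            for patient in pb.index:
                profiles.append(pb.loc[patient].rename(f"{patient}|{ctype}"))
                meta_rows.append((f"{patient}|{ctype}", patient, ctype, group_of[patient]))
        sc_scores = pd.DataFrame(
            columns=["sample", "raw_score", "mrnasi", "patient", "cell_type", "group"]
        )
        if profiles:
            prof_df = pd.DataFrame(profiles)
            meta = pd.DataFrame(
                meta_rows, columns=["sample", "patient", "cell_type", "group"]
            ).set_index("sample")
            sc_scores = stemness.score_cohort(model, prof_df, meta)
            sc_scores.insert(1, "level", "single_cell")
        bulk_profiles = np.log1p(tpm).T
        bulk_meta = bulk_groups.to_frame()
        bulk_scores = stemness.score_cohort(model, bulk_profiles, bulk_meta)
        bulk_scores.insert(1, "level", "bulk")
        all_scores = pd.concat([sc_scores, bulk_scores], ignore_index=True)
        _write(all_scores, outdir / "stemness.tsv")
        group_means = pd.concat(
            [stemness.stemness_by_group(s) for s in (sc_scores, bulk_scores) if len(s)],
            ignore_index=True,
        )
        _write(group_means, outdir / "stemness_groups.tsv")
        record("stemness", t0, {
            "model_converged": int(model.converged), "oclr_iterations": model.n_iter,
            "sc_profiles_scored": int(len(sc_scores)),
            "bulk_samples_scored": int(len(bulk_scores)),
        })

        # --- bulk DE + target nomination ---------------------------------
        current = "de"
        t0 = time.time()
        bulk_de.check_tpm(tpm)
        group_order = list(pd.unique(bulk_groups))
        case, ctrl = group_order[-1], group_order[0]
        de = bulk_de.de_screen(
            tpm, bulk_groups, case, ctrl,
            max_p=config.de_max_p, min_abs_log2fc=config.de_min_abs_log2fc,
        )
        _write(de, outdir / "de_results.tsv")
        dfu_up = set(de.loc[de["dysregulated"] & (de["log2fc"] > 0), "gene"])
        pop_markers: dict[str, set[str]] = {}
        for ctype in config.target_cell_types:
            cl_ids = ann_df.loc[ann_df["cell_type"] == ctype, "cluster"].astype(str)
            genes = set(markers.loc[markers["cluster"].astype(str).isin(cl_ids), "gene"])
            if genes:
                pop_markers[ctype] = genes
        if not dfu_up or not pop_markers:
            raise DataError(
                f"target nomination impossible: {len(dfu_up)} up-regulated genes, "
                f"{len(pop_markers)} populations with markers"
            )
        targets = bulk_de.nominate_targets(dfu_up, pop_markers)
        if not targets:
            raise DataError("no up-regulated gene intersects the population markers")
        pd.Series(targets, name="gene").to_frame().to_csv(
            outdir / "targets.tsv", sep="\t", index=False
        )
        record("de", t0, {
            "dysregulated": int(de["dysregulated"].sum()),
            "up_in_case": int(len(dfu_up)), "targets": len(targets),
        })

        # --- drug network ------------------------------------------------
        current = "drugnet"
        t0 = time.time()
        drug_genes = set(interactions["gene_name"]) if len(interactions) else set()
        coexpr = drug_network.spearman_edges(
            tpm, drug_genes, min_rho=config.min_rho,
            max_p=config.coexpr_max_p, absolute=config.coexpr_absolute,
        )
        net = drug_network.build_network(interactions, coexpr)
        edges = pd.DataFrame(
            [(u, v, d.get("kind", "")) for u, v, d in net.edges(data=True)],
            columns=["source", "target", "kind"],
        )
        _write(edges, outdir / "network_edges.tsv")
        walk = drug_network.rwr(
            net, set(targets), restart=config.restart,
            tol=config.rwr_tol, max_iter=config.rwr_max_iter,
        )
        ranking = drug_network.rank_drugs(walk, net)
        _write(ranking, outdir / "drug_ranking.tsv")
        record("drugnet", t0, {
            "coexpression_edges": int(len(coexpr)), "network_nodes": net.number_of_nodes(),
            "network_edges": net.number_of_edges(), "rwr_iterations": walk.n_iter,
            "drugs_ranked": int(len(ranking)),
        })
    except Exception as exc:
        msg = f"[stage: {current}] {exc}"
        try:
            wrapped = type(exc)(msg)
        except Exception:  # exception classes with non-string constructors
            from .errors import UlcermapError

            wrapped = UlcermapError(msg)
        raise wrapped from exc

    report["total_seconds"] = round(time.time() - t_run, 3)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    lines = [f"ulcermap run report (seed {config.seed})"]
    for st in report["stages"]:
        counts = ", ".join(f"{k}={v}" for k, v in st["records"].items())
        lines.append(f"  {st['stage']:<11s} {st['seconds']:>8.2f}s  {counts}")
    lines.append(f"  total       {report['total_seconds']:>8.2f}s")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
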