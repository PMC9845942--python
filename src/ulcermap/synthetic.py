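"""Synthetic single-cell cohorts for the DFU skin-microenvironment pipeline.

Real studies of diabetic foot ulcers (DFU) profile foot-skin biopsies from
healthy donors, diabetic patients without ulcers (DM), and patients with
healing / non-healing ulcers. This module simulates such cohorts with known
ground truth so that every downstream stage — QC, clustering, marker-overlap
annotation, stemness scoring, bulk differential expression and drug-network
propagation — can be tested against planted structure:

* counts are negative binomial (gamma–Poisson) with a shared dispersion;
* each cell type carries a block of marker genes whose mean is multiplied by
  ``2**marker_log2fc`` in cells of that type;
* a dedicated stem-signature gene block (separate from identity markers) is
  scaled by a per-group "stemness activity" in stem-type cells, emulating
  stem-cell exhaustion in non-healing ulcers;
* library sizes are log-normal so the minimum-genes QC filter has bite;
* matched bulk TPM profiles are mixtures of the same cell-type programs with
  planted differentially expressed genes between the first and last group;
* mock marker references and drug–gene interaction tables round out the
  inputs of the annotation and drug-ranking stages.

Randomness is fully reproducible: one RNG stream per patient (and per bulk
sample) is derived from the master seed, so enlarging a cohort does not
reshuffle already-simulated patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

import anndata as ad

from .annotation import MarkerReference
from .errors import ConfigurationError

DEFAULT_GROUPS = ("healthy", "DM", "DFU_healing", "DFU_nonhealing")

_BASE_TYPE_NAMES = [
    "Keratinocyte",
    "Fibroblast",
    "Endothelial cell",
    "Monocyte",
    "Macrophage",
    "T cell",
    "B cell",
    "NK cell",
    "Mast cell",
    "Smooth muscle cell",
]

STEM_TYPE = "Pluripotent stem cell"


def default_cell_type_names(n_cell_types: int) -> list[str]:
    """The last type is always the stem population carrying the signature."""
    others = list(_BASE_TYPE_NAMES[: n_cell_types - 1])
    while len(others) < n_cell_types - 1:
        others.append(f"CellType{len(others) + 1:02d}")
    return others + [STEM_TYPE]


def _default_composition(groups: tuple[str, ...], n_cell_types: int) -> dict[str, list[float]]:
    """Composition shifts with disease severity: the immune compartment
    expands along the group order while the stem fraction stays small."""
    immune = min(n_cell_types - 2, 3) if n_cell_types > 2 else 0
    comps: dict[str, list[float]] = {}
    denom = max(1, len(groups) - 1)
    for gi, g in enumerate(groups):
        w = np.ones(n_cell_types)
        w[-1] = 0.4  # stem cells are rare
        w[immune] *= 1.0 + 1.5 * gi / denom
        comps[g] = (w / w.sum()).tolist()
    return comps


def _default_activity(groups: tuple[str, ...]) -> dict[str, float]:
    """Stemness activity declines from the first (healthy) to the last
    (non-healing) group."""
    vals = np.linspace(1.0, 0.35, len(groups))
    return {g: float(v) for g, v in zip(groups, vals)}


@dataclass
class SimConfig:
    """Parameters of a simulated cohort.

    Defaults describe a small but realistic desk-scale cohort: four clinical
    groups, three patients each, 300 cells per patient, 2000 genes with five
    cell types of 30 markers each, a 100-gene stem signature, and negative
    binomial dispersion 0.3 around log-normal library sizes of ~5000 counts.
    """

    n_patients_per_group: int = 3
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_cell_types: int = 5
    cells_per_patient: int = 300
    n_genes: int = 2000
    markers_per_type: int = 30
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    composition: dict[str, list[float]] | None = None
    stemness_activity: dict[str, float] | None = None
    seed: int = 0
    # stem signature block (identity-independent, activity-scaled)
    n_stem_genes: int = 100
    stem_log2fc: float = 2.0
    # bulk simulation
    n_de_genes: int = 100
    de_log2fc: float = 2.0
    bulk_dispersion: float = 0.05
    bulk_total_counts: float = 2e6
    # library-size model
    library_size: float = 5000.0
    library_cv: float = 0.3

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if self.composition is None:
            self.composition = _default_composition(self.groups, self.n_cell_types)
        if self.stemness_activity is None:
            self.stemness_activity = _default_activity(self.groups)
        self.validate()

    def validate(self) -> None:
        if self.n_patients_per_group < 1:
            raise ConfigurationError("n_patients_per_group must be >= 1")
        if self.n_cell_types < 2:
            raise ConfigurationError("n_cell_types must be >= 2")
        if self.marker_log2fc < 0:
            raise ConfigurationError("marker_log2fc must be >= 0")
        if self.nb_dispersion <= 0 or self.bulk_dispersion <= 0:
            raise ConfigurationError("dispersions must be > 0")
        needed = self.n_cell_types * self.markers_per_type + self.n_stem_genes + self.n_de_genes
        if self.n_genes < needed:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for "
                f"{self.n_cell_types}x{self.markers_per_type} markers + "
                f"{self.n_stem_genes} stem genes + {self.n_de_genes} DE genes "
                f"(need >= {needed})"
            )
        for g in self.groups:
            if g not in self.composition:
                raise ConfigurationError(f"composition missing for group '{g}'")
            v = np.asarray(self.composition[g], dtype=float)
            if v.shape != (self.n_cell_types,):
                raise ConfigurationError(
                    f"composition for group '{g}' has length {v.size}, "
                    f"expected {self.n_cell_types}"
                )
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"composition for group '{g}' must be a probability vector "
                    f"summing to 1 (got sum={v.sum():.12f})"
                )
            a = self.stemness_activity.get(g)
            if a is None or not (0.0 <= a <= 1.0):
                raise ConfigurationError(
                    f"stemness_activity for group '{g}' must lie in [0, 1]"
                )


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for evaluation only."""

    gene_ids: list[str]
    cell_type_names: list[str]
    stem_type: str
    immune_type: str
    marker_genes: dict[str, list[str]]
    stem_genes: list[str]
    composition: dict[str, list[float]]
    stemness_activity: dict[str, float]
    de_up_genes: list[str]
    de_down_genes: list[str]
    de_log2fc: float
    target_genes: list[str]
    cell_types: pd.Series | None = None  # per-cell true labels (cohort runs)
    drug_targets: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.cell_types is not None:
            d["cell_types"] = self.cell_types.to_dict()
        return d


class _Layout:
    """Deterministic gene layout shared by cohort and bulk simulators."""

    def __init__(self, config: SimConfig):
        c = config
        self.gene_ids = [f"G{i:05d}" for i in range(c.n_genes)]
        self.type_names = default_cell_type_names(c.n_cell_types)
        self.stem_idx = c.n_cell_types - 1
        self.immune_idx = min(c.n_cell_types - 2, 3) if c.n_cell_types > 2 else 0
        m = c.markers_per_type
        self.marker_cols = {
            t: np.arange(t * m, (t + 1) * m) for t in range(c.n_cell_types)
        }
        s0 = c.n_cell_types * m
        self.stem_cols = np.arange(s0, s0 + c.n_stem_genes)
        b0 = s0 + c.n_stem_genes
        half = c.n_de_genes // 2
        self.de_up_bg = np.arange(b0, b0 + half)
        self.de_down = np.arange(b0 + half, b0 + c.n_de_genes)
        # drug-target genes: a few immune markers + a few stem-signature
        # genes, also planted as bulk-up so the target screen can find them
        k = min(5, m, c.n_stem_genes)
        self.target_cols = np.concatenate(
            [self.marker_cols[self.immune_idx][:k], self.stem_cols[:k]]
        )
        self.de_up = np.concatenate([self.de_up_bg, self.target_cols])
        # baseline relative expression, fixed by the master seed
        rng = np.random.default_rng([c.seed, 0])
        base = rng.lognormal(mean=0.0, sigma=1.0, size=c.n_genes)
        self.rel = base / base.sum()

    def genes(self, cols: np.ndarray) -> list[str]:
        return [self.gene_ids[i] for i in cols]

    def truth(self, config: SimConfig) -> GroundTruth:
        return GroundTruth(
            gene_ids=list(self.gene_ids),
            cell_type_names=list(self.type_names),
            stem_type=self.type_names[self.stem_idx],
            immune_type=self.type_names[self.immune_idx],
            marker_genes={
                self.type_names[t]: self.genes(cols)
                for t, cols in self.marker_cols.items()
            },
            stem_genes=self.genes(self.stem_cols),
            composition={g: list(v) for g, v in config.composition.items()},
            stemness_activity=dict(config.stemness_activity),
            de_up_genes=self.genes(self.de_up),
            de_down_genes=self.genes(self.de_down),
            de_log2fc=config.de_log2fc,
            target_genes=self.genes(self.target_cols),
        )

    def type_profile(self, config: SimConfig, t: int, activity: float) -> np.ndarray:
        """Relative expression of one cell type (marker boost + stem program)."""
        prof = self.rel.copy()
        prof[self.marker_cols[t]] *= 2.0 ** config.marker_log2fc
        if t == self.stem_idx:
            prof[self.stem_cols] *= 2.0 ** (config.stem_log2fc * activity)
        return prof


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a single-cell cohort.

    Returns an AnnData of sparse integer counts (cells x genes) whose ``obs``
    records patient and clinical group, plus the :class:`GroundTruth` with
    per-cell true labels and all planted gene programs.
    """
    config.validate()
    lay = _Layout(config)
    sigma = math.sqrt(math.log(1.0 + config.library_cv**2))
    mu_log = math.log(config.library_size) - sigma**2 / 2.0

    blocks, cell_ids, patients, groups_col, true_types = [], [], [], [], []
    pat_idx = 0
    for group in config.groups:
        comp = np.asarray(config.composition[group], dtype=float)
        activity = config.stemness_activity[group]
        profiles = np.stack(
            [lay.type_profile(config, t, activity) for t in range(config.n_cell_types)]
        )
        for p in range(config.n_patients_per_group):
            rng = np.random.default_rng([config.seed, 100 + pat_idx])
            patient = f"{group}_p{p + 1}"
            n = config.cells_per_patient
            types = rng.choice(config.n_cell_types, size=n, p=comp)
            libs = rng.lognormal(mu_log, sigma, size=n)
            mean = libs[:, None] * profiles[types]
            counts = _nb_sample(rng, mean, config.nb_dispersion)
            blocks.append(sparse.csr_matrix(counts))
            cell_ids.extend(f"{patient}_c{i + 1}" for i in range(n))
            patients.extend([patient] * n)
            groups_col.extend([group] * n)
            true_types.extend(lay.type_names[t] for t in types)
            pat_idx += 1

    X = sparse.vstack(blocks).astype(np.int64)
    obs = pd.DataFrame({"patient": patients, "group": groups_col}, index=cell_ids)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=lay.gene_ids))
    truth = lay.truth(config)
    truth.cell_types = pd.Series(true_types, index=cell_ids, name="cell_type")
    return adata, truth


def simulate_bulk(
    config: SimConfig, n_reps: int
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate matched bulk TPM samples (genes x samples) with group labels.

    Each sample is a composition-weighted mixture of the group's cell-type
    programs; genes recorded in the ground truth are additionally shifted by
    ``2**±de_log2fc`` in the last group relative to the first. Columns are
    normalized to TPM (each sums to 1e6).
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2 (downstream tests need replication)")
    config.validate()
    lay = _Layout(config)
    truth = lay.truth(config)

    cols, names, labels = [], [], []
    s_idx = 0
    for group in config.groups:
        comp = np.asarray(config.composition[group], dtype=float)
        activity = config.stemness_activity[group]
        mix = np.zeros(config.n_genes)
        for t in range(config.n_cell_types):
            mix += comp[t] * lay.type_profile(config, t, activity)
        if group == config.groups[-1]:
            mix = mix.copy()
            mix[lay.de_up] *= 2.0 ** config.de_log2fc
            mix[lay.de_down] *= 2.0 ** -config.de_log2fc
        mean = mix / mix.sum() * config.bulk_total_counts
        for r in range(n_reps):
            rng = np.random.default_rng([config.seed, 500 + s_idx])
            counts = _nb_sample(rng, mean, config.bulk_dispersion).astype(float)
            tpm = counts / counts.sum() * 1e6
            cols.append(tpm)
            names.append(f"bulk_{group}_s{r + 1}")
            labels.append(group)
            s_idx += 1

    tpm_df = pd.DataFrame(np.column_stack(cols), index=lay.gene_ids, columns=names)
    return tpm_df, pd.Series(labels, index=names, name="group"), truth


def simulate_marker_reference(
    truth: GroundTruth, noise_frac: float = 0.0, seed: int = 0
) -> MarkerReference:
    """Mock curated marker reference: the planted programs with ``noise_frac``
    of each set replaced by random non-marker genes."""
    if not 0.0 <= noise_frac <= 1.0:
        raise ConfigurationError("noise_frac must lie in [0, 1]")
    rng = np.random.default_rng([seed, 900])
    all_markers = {g for gs in truth.marker_genes.values() for g in gs}
    non_markers = [g for g in truth.gene_ids if g not in all_markers]
    type_sets: dict[str, set[str]] = {}
    for ctype, genes in truth.marker_genes.items():
        genes = list(genes)
        n_rep = int(round(noise_frac * len(genes)))
        if n_rep:
            pos = rng.choice(len(genes), size=n_rep, replace=False)
            repl = rng.choice(len(non_markers), size=n_rep, replace=False)
            for i, j in zip(pos, repl):
                genes[i] = non_markers[j]
        type_sets[ctype] = set(genes)
    return MarkerReference(type_sets=type_sets, universe=set(truth.gene_ids))


def simulate_drug_table(
    truth: GroundTruth, n_drugs: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Mock drug–gene interaction table in the DGIdb export dialect.

    Half of the drugs attach to planted target genes, the rest to decoy
    genes drawn from the unprogrammed background (no marker, stem or DE
    program), so decoy drugs are genuinely unrelated to the disease module;
    the drug→gene map is recorded in ``truth.drug_targets``.
    """
    rng = np.random.default_rng([seed, 901])
    targets = list(truth.target_genes)
    programmed = {g for gs in truth.marker_genes.values() for g in gs}
    programmed |= set(truth.stem_genes) | set(truth.de_up_genes) | set(truth.de_down_genes)
    decoy_pool = [g for g in truth.gene_ids if g not in programmed]
    rows = []
    drug_targets: dict[str, list[str]] = {}
    n_hit = (n_drugs + 1) // 2
    for d in range(n_drugs):
        name = f"drug_{d + 1:02d}"
        if d < n_hit and targets:
            k = int(rng.integers(2, min(3, len(targets)) + 1))
            genes = list(rng.choice(targets, size=k, replace=False))
        else:
            k = int(rng.integers(1, 3))
            genes = list(rng.choice(len(decoy_pool), size=k, replace=False))
            genes = [decoy_pool[i] for i in genes]
        drug_targets[name] = sorted(genes)
        for g in genes:
            rows.append((name, g, "synthetic"))
    truth.drug_targets = drug_targets
    return pd.DataFrame(
        rows, columns=["drug_claim_name", "gene_name", "interaction_claim_source"]
    )


def simulate_stem_training(
    config: SimConfig,
    n_profiles: int = 20,
    cells_per_profile: int = 100,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic stem-cell training profiles for the one-class stemness model.

    Each profile is the log-normalized average of ``cells_per_profile``
    simulated stem-type cells at full signature activity; the returned
    baseline is the matching average over the non-stem cell types, used to
    center training profiles before the one-class fit.
    """
    config.validate()
    lay = _Layout(config)
    stem_profile = lay.type_profile(config, lay.stem_idx, activity=1.0)

    def _lognorm(mean_counts: np.ndarray) -> np.ndarray:
        return np.log1p(mean_counts / mean_counts.sum() * 1e4)

    rows = []
    for i in range(n_profiles):
        rng = np.random.default_rng([config.seed, 700 + i])
        mean = config.library_size * stem_profile[None, :].repeat(cells_per_profile, 0)
        counts = _nb_sample(rng, mean, config.nb_dispersion)
        rows.append(_lognorm(counts.mean(axis=0)))
    training = pd.DataFrame(
        rows,
        index=[f"stem_train_{i + 1}" for i in range(n_profiles)],
        columns=lay.gene_ids,
    )

    rng = np.random.default_rng([config.seed, 799])
    bg = np.zeros(config.n_genes)
    n_types = config.n_cell_types - 1
    for t in range(n_types):
        mean = config.library_size * lay.type_profile(config, t, 0.0)
        counts = _nb_sample(rng, mean[None, :].repeat(200, 0), config.nb_dispersion)
        bg += counts.mean(axis=0) / n_types
    baseline = pd.Series(_lognorm(bg), index=lay.gene_ids, name="baseline")
    return training, baseline
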