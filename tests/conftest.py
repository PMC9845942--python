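import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import anndata as ad

from ulcermap.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact cohort with a strong planted marker effect (3 types)."""
    return SimConfig(
        n_patients_per_group=2,
        cells_per_patient=150,
        n_cell_types=3,
        n_genes=800,
        markers_per_type=20,
        marker_log2fc=3.0,
        n_stem_genes=50,
        n_de_genes=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_adata(counts: np.ndarray, cell_ids=None, gene_ids=None, **obs_cols) -> ad.AnnData:
    counts = np.asarray(counts)
    n, g = counts.shape
    cell_ids = cell_ids or [f"cell{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(obs_cols, index=cell_ids) if obs_cols else pd.DataFrame(index=cell_ids)
    return ad.AnnData(
        X=sparse.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=gene_ids)
    )
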