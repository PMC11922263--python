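import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import anndata as ad

from tcrtrace import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """One modest seeded cohort shared by read-only tests."""
    cfg = sim.SimulationConfig(n_samples=4, cells_per_sample=300, shared_clone_count=30, seed=11)
    adata, meta, chains, truth = sim.generate_cohort(cfg)
    return cfg, adata, meta, chains, truth


def make_adata(counts, genes, barcodes=None):
    """Dense count array -> AnnData with named genes."""
    counts = np.asarray(counts)
    barcodes = barcodes or [f"cell{i}" for i in range(counts.shape[0])]
    return ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
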