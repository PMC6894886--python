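import numpy as np
import pytest
import scipy.sparse as sp

from crossimmune.droplet_qc import CountMatrix
from crossimmune.synthetic_data import DropletSimConfig, simulate_droplet_experiment


@pytest.fixture(scope="session")
def droplet_default():
    """One droplet experiment at generator defaults (shared across tests)."""
    cfg = DropletSimConfig(seed=42)
    return simulate_droplet_experiment(cfg)


@pytest.fixture(scope="session")
def small_clustered():
    """A small, QC-clean matrix with 4 planted clusters and its truth."""
    cfg = DropletSimConfig(
        n_cells=800, n_empty=10, n_genes=300, k_clusters=4, seed=7
    )
    m, truth = simulate_droplet_experiment(cfg)
    keep = truth.barcode_class == "cell"
    return m.subset_barcodes(keep), truth.cell_cluster[keep]


def toy_matrix(counts, genes=None, barcodes=None) -> CountMatrix:
    counts = np.asarray(counts)
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(counts.shape[1])]
    return CountMatrix(np.array(genes, dtype=object),
                       np.array(barcodes, dtype=object),
                       sp.csr_matrix(counts))
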