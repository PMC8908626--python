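import numpy as np
import pytest

from sigpop.preprocess import QCThresholds, run_preprocess
from sigpop.synthetic import SimConfig, simulate_counts

# QC cutoffs matched to the synthetic generator's scale (the dataclass
# defaults mirror a real experiment and would strip a 1000-gene simulation)
SIM_QC = QCThresholds(min_barcode_counts=500, min_genes_per_cell=200, max_mito_fraction=0.10)


@pytest.fixture(scope="session")
def sim_qc():
    return SIM_QC


@pytest.fixture(scope="session")
def default_sim():
    """Default-config simulation with a spread positive population."""
    config = SimConfig(seed=3)
    matrix, truth = simulate_counts(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def planted_run():
    """A full preprocess run on data with the signature concentrated in one
    cluster; shared by the fea / degs / correlation tests."""
    config = SimConfig(
        n_cells=800,
        n_genes=800,
        n_clusters=3,
        pos_fraction=0.3,
        pos_log2fc=1.5,
        pos_placement="concentrated",
        pos_cluster=1,
        seed=9,
    )
    matrix, truth = simulate_counts(config)
    result = run_preprocess(matrix, thresholds=SIM_QC, seed=9)
    keep = np.isin(truth.cell_ids, result.clustering.cell_ids)
    return config, matrix, truth, result, keep
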