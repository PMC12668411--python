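import warnings

import numpy as np
import pytest

from spatime import (
    SimConfig,
    generate_bead_array,
    generate_spatial_reads,
    generate_truth,
)

# scanpy and sklearn emit benign convergence/layout warnings on tiny data
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulation shared by read-parsing and placement tests."""
    cfg = SimConfig(
        n_beads=800,
        array_radius=400.0,
        n_cells=80,
        n_genes=100,
        reads_per_cell_mean=40.0,
        diffusion_sigma=20.0,
        seed=5,
    )
    truth = generate_truth(cfg)
    whitelist = generate_bead_array(cfg)
    reads = generate_spatial_reads(cfg, truth, whitelist)
    return cfg, truth, whitelist, reads


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
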