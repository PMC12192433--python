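import numpy as np
import pytest

from connmvpa.synth import SimConfig


@pytest.fixture
def small_cfg():
    """Desk-scale simulation config: 6 kept + 2 artifact nodes, 120 voxels."""
    return SimConfig(
        n_subjects=8,
        n_nodes_kept=6,
        n_nodes_artifact=2,
        n_timepoints=120,
        n_voxels=120,
        edge_effects=[(0, 1, 0.4, 0.1), (2, 3, -0.3, -0.3)],
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
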