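import numpy as np
import pytest

import scouter as sc


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated dataset shared across read-only tests."""
    cfg = sc.SimConfig(
        n_genes=30, n_perts=6, n_cells_per_pert=15, n_controls=40,
        embedding_dim=6, effect_scale=1.0, noise_sd=0.2, seed=11,
    )
    return sc.simulate_dataset(cfg)


@pytest.fixture()
def tiny_model_config():
    return sc.ScouterConfig(
        n_genes=30, embedding_dim=6, compressor_hidden=[16, 8], bottleneck=4,
        generator_hidden=[16], lr=0.01, batch_size=64, max_epochs=5, seed=3,
    )


@pytest.fixture()
def manual_dataset():
    """Hand-built 5-cell dataset: 2 controls, 2 cells of A, 1 cell of B."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=(5, 3))
    labels = [sc.parse_label(s) for s in ["ctrl", "ctrl", "A", "A", "B"]]
    return sc.PerturbDataset(x, ["g1", "g2", "g3"], labels)
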