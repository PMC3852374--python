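import numpy as np
import pandas as pd
import pytest

from noiseplast import synthetic as syn


SMALL_SIZES = {
    "essential": 20,
    "slow_growth": 40,
    "dosage_sensitive": 60,
    "H-NS": 20,
    "CRP": 40,
    "Sigma38": 30,
    "stress": 30,
}
SMALL_RHO = {
    "essential": 0.0,
    "slow_growth": 0.1,
    "dosage_sensitive": 0.1,
    "H-NS": 0.7,
    "CRP": 0.3,
    "Sigma38": 0.4,
    "stress": 0.4,
}


@pytest.fixture
def small_sim_cfg():
    """A reduced simulation for fast unit tests (300 genes, 60 conditions)."""
    return syn.SimulationConfig(n_genes=300, n_conditions=60,
                                class_sizes=dict(SMALL_SIZES),
                                class_rho=dict(SMALL_RHO), seed=11)


@pytest.fixture
def small_dataset(small_sim_cfg):
    expr, noise, annot, regulons, truth = syn.generate_dataset(small_sim_cfg)
    return {"expr": expr, "noise": noise, "annot": annot,
            "regulons": regulons, "truth": truth}


@pytest.fixture
def default_dataset():
    """One full-scale simulation (1456 genes x 466 conditions), shared."""
    expr, noise, annot, regulons, truth = syn.generate_dataset(seed=3)
    return {"expr": expr, "noise": noise, "annot": annot,
            "regulons": regulons, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
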