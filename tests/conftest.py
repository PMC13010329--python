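import numpy as np
import pandas as pd
import pytest

from treeflux import NoiseConfig, ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def oracle_scenario():
    """Noise-free 3-treatment scenario used for exact recovery checks."""
    cfg = ScenarioConfig(
        n_trees_per_treatment=2,
        dendro_interval_min=60,
        noise=NoiseConfig.zero(),
        seed=11,
    )
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def noisy_scenario():
    """Default-noise scenario (2 trees per treatment for speed)."""
    cfg = ScenarioConfig(n_trees_per_treatment=2, dendro_interval_min=60, seed=11)
    return generate_scenario(cfg)


def make_record(
    c_ref=445.6,
    c_sample=440.0,
    w_ref=8.0,
    w_sample=8.0,
    flow=0.1,
    t_air=23.0,
    p=94.0,
    compartment="shoot",
    tree_id="t1",
    timestamp="2023-06-06 12:00",
):
    """Single-row chamber table for unit tests."""
    return pd.DataFrame(
        {
            "timestamp": [pd.Timestamp(timestamp)],
            "tree_id": [tree_id],
            "compartment": [compartment],
            "c_ref_ppm": [c_ref],
            "c_sample_ppm": [c_sample],
            "w_ref_mmol": [w_ref],
            "w_sample_mmol": [w_sample],
            "flow_mol_s": [flow],
            "t_air_C": [t_air],
            "p_kpa": [p],
            "par_umol": [600.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
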