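import numpy as np
import pandas as pd
import pytest

from bathygap.synthetic_data import GeneratorConfig, generate_truth


@pytest.fixture(scope="session")
def small_truth():
    """A small, fixed synthetic species pool shared across tests."""
    cfg = GeneratorConfig(n_actinopterygii=60, n_chondrichthyes=15, seed=11)
    return cfg, generate_truth(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_range_frame(truth) -> pd.DataFrame:
    """Species table with the *true* depth ranges (bypasses estimation)."""
    return pd.DataFrame(
        {
            "species_id": [sp.species_id for sp in truth],
            "taxon_class": [sp.taxon_class for sp in truth],
            "habitat": [sp.habitat for sp in truth],
            "iucn_raw": [sp.iucn_raw for sp in truth],
            "iucn_group": [
                {"NT": "THR", "VU": "THR", "EN": "THR", "CR": "THR"}.get(sp.iucn_raw, sp.iucn_raw)
                for sp in truth
            ],
            "min_depth_m": [sp.true_min_depth_m for sp in truth],
            "max_depth_m": [sp.true_max_depth_m for sp in truth],
            "depth_source": "documented",
        }
    )
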