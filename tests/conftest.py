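import numpy as np
import pandas as pd
import pytest

from chillrhythm import synthdata


@pytest.fixture(scope="session")
def small_expression():
    """40-pair synthetic expression table with 25% planted DROs."""
    cfg = synthdata.ExpressionSimConfig(n_pairs=40, frac_dro=0.25,
                                        noise_sd=0.2, seed=11)
    expr, truth = synthdata.generate_expression(cfg)
    return expr, truth


@pytest.fixture(scope="session")
def small_lipids():
    """Default-composition synthetic lipid table, moderate noise."""
    cfg = synthdata.LipidSimConfig(seed=11)
    lipids, truth = synthdata.generate_lipids(cfg)
    return lipids, truth


def make_expression_frame(records):
    """Long expression frame from (gene, species, condition, t, rep, fpkm)."""
    return pd.DataFrame(records, columns=["gene", "species", "condition",
                                          "time_h", "replicate", "fpkm"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
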