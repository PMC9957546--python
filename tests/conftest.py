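import numpy as np
import pandas as pd
import pytest

import grninfer as g


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        [[10.0, 20.0], [20.0, 40.0], [40.0, 80.0]],
        index=["g1", "g2", "g3"],
        columns=["A", "B"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic GRN every scorer can run on in seconds."""
    grn = g.SyntheticGRN(
        n_tfs=8, n_tgs=20, regulators_per_tg=2, n_conditions=60, noise_sd=0.5, seed=11
    )
    expr, gold = g.simulate(grn)
    return grn, expr, gold


@pytest.fixture(scope="session")
def default_recovery():
    """Reference recovery benchmark: default synthetic GRN, Z-TG ensemble."""
    grn = g.SyntheticGRN()
    return g.recovery_experiment(
        grn,
        ["pr", "rfr", "brsr", "svmr", "tigress"],
        scheme="z-tg",
        ensemble_members=["brsr", "svmr", "rfr"],
    )
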