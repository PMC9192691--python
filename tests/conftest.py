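import numpy as np
import pandas as pd
import pytest

from fxiselect import synthetic


@pytest.fixture(scope="session")
def small_config():
    """Small but realistic config shared by several test modules."""
    return synthetic.SimulationConfig(
        n_acute=300,
        n_followup=150,
        n_overlap=150,
        n_proteins=60,
        block_size=6,
        block_rho=0.5,
        signal_r2=0.5,
        doac_shift=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_cohort_frame(n=20, seed=0, **overrides):
    """Hand-rolled minimal cohort frame for preprocess unit tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "timepoint": "acute",
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(60, 10, n).round(1),
            "bmi": rng.normal(28, 4, n).round(1),
            "active_malignancy": 0,
            "doac_user": 0,
            "fxi_c": rng.normal(120, 30, n).clip(25).round(1),
            "aptt": rng.normal(33, 3, n).round(1),
            "crp": np.exp(rng.normal(2.5, 1.0, n)).round(2),
        },
        index=pd.Index([f"S{i:03d}:acute" for i in range(n)], name="obs_id"),
    )
    for key, val in overrides.items():
        df[key] = val
    return df
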