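import numpy as np
import pandas as pd
import pytest

from impovmap import GeneratorConfig, generate, weights_from_edges


@pytest.fixture(scope="session")
def path3():
    """Three districts in a path A - B - C."""
    return weights_from_edges([("A", "B"), ("B", "C")], ["A", "B", "C"])


@pytest.fixture(scope="session")
def survey_small():
    """Expenditure-first survey on a small lattice, with generator truth."""
    cfg = GeneratorConfig(
        n_districts=9,
        households_per_district=60,
        island=False,
        mode="expenditure_first",
        seed=11,
    )
    df, weights, truth = generate(cfg)
    return df, weights, truth, cfg


def random_households(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Arbitrary valid household table for property checks."""
    return pd.DataFrame(
        {
            "household_id": [f"H{k}" for k in range(n)],
            "district_id": rng.choice(["A", "B", "C"], n),
            "total_expenditure": rng.lognormal(12.0, 1.0, n),
            "oop_payment": rng.lognormal(8.0, 1.5, n) * rng.binomial(1, 0.7, n),
            "household_size": rng.integers(1, 9, n),
            "survey_weight": rng.uniform(0.2, 3.0, n),
        }
    )
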