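import numpy as np
import pandas as pd
import pytest

import sromics as s


@pytest.fixture(scope="session")
def planted_small():
    """A small planted dataset: logreg(2*x1 + 3*x2 - 1) among 10 noise features."""
    tree, params = s.linear_logistic_formula({"x1": 2.0, "x2": 3.0}, intercept=-1.0)
    spec = s.PlantedSpec(
        formula=tree, parameters=params, n_samples=200, n_noise_features=10, seed=42
    )
    data, truth = s.generate_planted(spec)
    return data, truth


@pytest.fixture
def tiny_search_config():
    """A light search configuration for unit tests."""
    return s.SearchConfig(
        n_generations=8,
        population_size=40,
        n_elites=8,
        max_features=3,
        max_depth=3,
        seed=0,
        fit=s.FitConfig(max_iterations=60, learning_rate=0.1, method="adam"),
    )


@pytest.fixture
def binary_frame():
    rng = np.random.default_rng(3)
    n = 120
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    from scipy.special import expit

    y = rng.binomial(1, expit(2 * x)).astype(float)
    return s.Dataset(frame=pd.DataFrame({"x": x, "z": z, "y": y}), target="y")


def make_dataset(columns: dict, target: str = "y") -> s.Dataset:
    return s.Dataset(frame=pd.DataFrame(columns), target=target)
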