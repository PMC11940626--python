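import warnings

import numpy as np
import pandas as pd
import pytest

from somportrait import (ExpressionMatrix, SampleAnnotation, SOMGrid,
                         train_som)
from somportrait.simulate import SimulationDesign, simulate_cohort

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """Desk-drawer cohort: 600 genes, 84 samples, quick to portray."""
    return SimulationDesign(n_genes=600, n_samples=84, module_size=20,
                            n_batches=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def tiny_model():
    """A 4x4 SOM trained on two well-separated synthetic gene clusters."""
    rng = np.random.default_rng(5)
    n_samples = 24
    up = np.r_[np.ones(12), -np.ones(12)]
    a = up + rng.normal(0, 0.1, (30, n_samples))
    b = -up + rng.normal(0, 0.1, (30, n_samples))
    values = pd.DataFrame(
        np.vstack([a, b]),
        index=[f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(n_samples)])
    values -= values.mean(axis=1).to_numpy()[:, None]
    m = ExpressionMatrix(values, scale="normalized")
    return train_som(m, SOMGrid(4, 4), seed=5, epochs=10)


def make_matrix(arr, genes=None, samples=None, scale="tpm", strict=False):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            scale=scale, strict_tpm=strict)
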