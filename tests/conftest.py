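import numpy as np
import pandas as pd
import pytest

from refstab.cp_io import CpMatrix, QuantityMatrix, to_relative_quantities


def make_cp(values, genes=None, samples=None, groups=None, replicate_map=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(1, arr.shape[0] + 1)]
    samples = samples or [f"s{j}" for j in range(1, arr.shape[1] + 1)]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    df.index.name = "gene"
    return CpMatrix(df, replicate_map=replicate_map, groups=groups)


def make_q(values, genes=None, samples=None, groups=None):
    """QuantityMatrix straight from positive values (identity calibrator)."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(1, arr.shape[0] + 1)]
    samples = samples or [f"s{j}" for j in range(1, arr.shape[1] + 1)]
    df = pd.DataFrame(arr, index=genes, columns=samples)
    return QuantityMatrix(
        q_values=df,
        calibrator=pd.Series(0.0, index=genes),
        efficiencies=pd.Series(2.0, index=genes),
        groups=groups,
    )


def random_q(rng, n_genes, n_samples, groups=None):
    """Random positive quantity matrix (log-normal on the Cp scale)."""
    vals = np.exp2(rng.normal(0.0, 1.0, size=(n_genes, n_samples)))
    return make_q(vals, groups=groups)


def random_cp(rng, n_genes, n_samples, low=15.0, high=32.0, noise=0.5):
    base = rng.uniform(low, high, size=n_genes)
    vals = base[:, None] + rng.normal(0.0, noise, size=(n_genes, n_samples))
    return make_cp(np.clip(vals, 1.0, 44.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cp():
    return make_cp([[20.0, 21.0, 19.5], [25.0, 25.5, 24.0], [30.0, 31.0, 29.0]])


@pytest.fixture
def small_q(small_cp):
    return to_relative_quantities(small_cp)
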