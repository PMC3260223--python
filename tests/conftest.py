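import numpy as np
import pytest

import epiforest as ef


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_917)


@pytest.fixture(scope="session")
def xor_data():
    """8 individuals, cases exactly when the genotypes of SNP0/SNP1 differ.

    Neither SNP has any marginal signal; only the pair separates the classes.
    """
    X = np.array(
        [[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]] * 2, dtype=np.int8
    )
    y = np.array([0, 1, 1, 0] * 2, dtype=np.int8)
    return X, y


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic 12x4 dataset for I/O and plumbing tests."""
    g = np.random.default_rng(5).integers(0, 3, size=(12, 4)).astype(np.int8)
    y = np.array([1, 0] * 6, dtype=np.int8)
    return ef.Dataset(
        g, [f"rs{i}" for i in range(4)], [f"ind{i}" for i in range(12)], y
    )


@pytest.fixture(scope="session")
def epistasis_dataset():
    """Pure-epistasis panel: strong pair signal, 100 SNPs, 400 individuals."""
    gen = np.random.default_rng(99)
    table = ef.pure_epistasis_penetrance(0.4, 0.2, rng=gen)
    spec = ef.SimulationSpec(
        n_cases=200, n_controls=200, n_snps=100,
        models=[ef.ModelAssignment(table, (10, 60))], rng_seed=17,
    )
    return ef.sample_case_control(spec)


@pytest.fixture(scope="session")
def small_forest(epistasis_dataset):
    ds = epistasis_dataset
    est = ef.EpistasisForest(n_trees=60, mtry=500, random_state=101)
    return est.fit(ds.X, ds.y)
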