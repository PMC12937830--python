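import numpy as np
import pytest

from hirrm.simulate import (SimulationConfig, estimate_null_from_dataset,
                            simulate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_dataset():
    """A small Bertalanffy study reused across association/CLI tests."""
    cfg = SimulationConfig(
        n_individuals=150, n_markers=400, n_qtls=4,
        family="bertalanffy", population_coefficients=(220.0, 0.948, 0.234),
        qtl_variance_fraction=0.4, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_null_fit(small_dataset):
    """Stage-1 regressions + null REML for the shared dataset."""
    cc, reg, kept, kin = estimate_null_from_dataset(small_dataset)
    assert kept.all()
    return cc, reg, kin


def random_pd_pair(rng, d, scale=1.0):
    """A random positive-definite (Vg, Vpe) pair."""
    A = rng.standard_normal((d, d + 2))
    B = rng.standard_normal((d, d + 2))
    Vg = scale * (A @ A.T) / (d + 2)
    Vpe = scale * (B @ B.T) / (d + 2) + 0.1 * np.eye(d)
    return Vg, Vpe
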