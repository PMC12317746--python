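import numpy as np
import pytest

from spatialmnn import SRTSample, RunConfig, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_sample(rng, n_units=40, n_genes=25, sample_id="s1", grid=False):
    """Small random sample for unit tests."""
    counts = rng.poisson(3.0, size=(n_units, n_genes)).astype(float)
    counts[counts.sum(axis=1) == 0, 0] = 1.0  # avoid empty units
    if grid:
        side = int(np.ceil(np.sqrt(n_units)))
        rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        coords = np.stack([cc.ravel(), rr.ravel()], axis=1)[:n_units].astype(float)
    else:
        coords = rng.uniform(0, 100, size=(n_units, 2))
    return SRTSample(
        sample_id=sample_id, counts=counts, coords=coords,
        gene_ids=[f"g{j}" for j in range(n_genes)],
        unit_ids=[f"{sample_id}_u{i}" for i in range(n_units)])


@pytest.fixture
def small_sample(rng):
    return random_sample(rng)


@pytest.fixture
def small_config():
    """Config scaled for tiny fixtures."""
    return RunConfig(n_pcs=5, k_spatial=4, seed=0, k_mnn=3)


def small_sim(n_samples=3, seed=0, **kw):
    """Reduced-size simulation: 20x20 grid, 20 markers/type."""
    defaults = dict(n_samples=n_samples, grid_shape=(20, 20),
                    markers_per_type=20, seed=seed)
    defaults.update(kw)
    return simulate_dataset(SimConfig(**defaults))
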