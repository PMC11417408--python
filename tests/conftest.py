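import numpy as np
import pytest

from hetero3d import hicmatrix as hm
from hetero3d.genome import BinnedGenome
from hetero3d.simgenome import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_genome():
    return BinnedGenome.from_dict({"chrA": 500_000}, 50_000)  # 10 bins


@pytest.fixture(scope="session")
def default_dataset():
    """Paired WT/ddm1 simulation at the default study conditions, seed 1."""
    return simulate_dataset(SimulationConfig(seed=1))


def normalize(ds, genotype, min_frac=0.1):
    """Standard chain raw -> masked -> balanced -> O/E used across tests."""
    masked = hm.mask_low_coverage(ds.matrices[genotype], min_frac)
    bal = hm.balance_ice(masked)
    oe = hm.observed_over_expected(bal, hm.expected_by_distance(bal))
    return bal, oe


@pytest.fixture(scope="session")
def default_normalized(default_dataset):
    return {g: normalize(default_dataset, g) for g in ("wt", "ddm1")}


def symmetric_matrix(rng, n, base=1.0, jitter=0.5):
    """Random dense symmetric positive matrix with zero diagonal."""
    m = base + jitter * rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def as_contact_matrix(m, stage="raw", chrom="chrA", bin_size=50_000):
    n = m.shape[0]
    genome = BinnedGenome.from_dict({chrom: n * bin_size}, bin_size)
    return hm.ContactMatrix(genome=genome, data={chrom: m.astype(float)}, stage=stage)
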