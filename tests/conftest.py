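import numpy as np
import pytest

from enrichest import build_design, select, subpop_from_partitions


@pytest.fixture(scope="session")
def worked_design():
    """Depression trial: K=4 quartiles, sigma=7 HRSD points, b=2, 90+120/partition."""
    return build_design((0.25, 0.5, 0.75, 1.0), 7.0, 2.0, (90,) * 4, (120,) * 4)


@pytest.fixture(scope="session")
def worked_stage1(worked_design):
    return subpop_from_partitions((3.0, 2.0, 0.8, 0.0), worked_design, 1)


@pytest.fixture(scope="session")
def worked_outcome(worked_design, worked_stage1):
    return select(worked_stage1, worked_design)


@pytest.fixture(scope="session")
def worked_stage2(worked_design):
    return subpop_from_partitions((3.0, 2.4), worked_design, 2, s=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_design(rng, K=None, b=None):
    """A random valid design for property tests."""
    K = K or int(rng.integers(2, 6))
    cuts = np.sort(rng.uniform(0.05, 0.95, size=K - 1))
    prevalences = tuple(np.concatenate([cuts, [1.0]]))
    n1 = tuple(int(x) * 2 for x in rng.integers(10, 80, size=K))
    sigma = float(rng.uniform(0.5, 8.0))
    b = float(rng.normal(0, 0.5)) if b is None else b
    return build_design(prevalences, sigma, b, n1, tuple(int(x) * 2 for x in rng.integers(10, 80, size=K)))


def proportional_design(rng, K=None, b=None):
    """A design whose stage-1 sizes are proportional to prevalences.

    In this regime the prevalence-weighted subpopulation mean coincides
    with the pooled patient mean, so its variance is 4 sigma^2 / m_1i.
    """
    K = K or int(rng.integers(2, 6))
    counts = rng.integers(2, 20, size=K)
    prevalences = tuple(np.cumsum(counts) / counts.sum())
    mult = int(rng.integers(1, 6)) * 2
    n1 = tuple(int(c) * mult for c in counts)
    sigma = float(rng.uniform(0.5, 8.0))
    b = float(rng.normal(0, 0.5)) if b is None else b
    return build_design(prevalences, sigma, b, n1, n1)
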