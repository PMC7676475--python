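import numpy as np
import pytest

from vcdea.io_norm import CountMatrix, Design, NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    return CountMatrix(
        values=np.array([[0.0, 5.0, 3.0, 7.0], [10.0, 0.0, 2.0, 8.0], [1.0, 1.0, 1.0, 1.0]]),
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def two_group_design():
    return Design(
        X=np.empty((4, 0)),
        Phi=np.array([0.0, 0.0, 1.0, 1.0])[:, None],
        sample_ids=["s1", "s2", "s3", "s4"],
        phi_names=["group"],
    )


def make_gaussian_dataset(G, n, seed, sigma=1.0, group_effect=0.0):
    """Homoscedastic Gaussian expression with a balanced two-group design."""
    rng = np.random.default_rng(seed)
    group = np.repeat([0.0, 1.0], n // 2)
    base = rng.uniform(4.0, 12.0, size=G)
    y = base[:, None] + sigma * rng.normal(size=(G, n))
    y += group_effect * group[None, :]
    ym = NormalizedMatrix(
        values=y,
        gene_ids=[f"g{i}" for i in range(G)],
        sample_ids=[f"s{i}" for i in range(n)],
        transform_tag="synthetic",
    )
    design = Design(
        X=np.empty((n, 0)),
        Phi=group[:, None],
        sample_ids=ym.sample_ids,
        phi_names=["group"],
    )
    return ym, design


@pytest.fixture
def gaussian_dataset():
    return make_gaussian_dataset(G=200, n=40, seed=7)
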