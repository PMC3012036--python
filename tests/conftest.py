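import numpy as np
import pytest

from gelimpute import GroupDesign, SpotMatrix, SyntheticConfig, generate_complete_dataset


def make_design(n_a: int = 2, n_b: int = 2) -> GroupDesign:
    gels = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    return GroupDesign(tuple(gels), {g: g[0] for g in gels})


def make_matrix(values, n_a: int = None, n_b: int = None) -> SpotMatrix:
    """Wrap a 2-D array (NaN = missing) in a SpotMatrix with an even split."""
    values = np.asarray(values, dtype=float)
    n_gels = values.shape[1]
    if n_a is None:
        n_a = n_gels // 2
    if n_b is None:
        n_b = n_gels - n_a
    design = make_design(n_a, n_b)
    spot_ids = tuple(f"S{i+1:03d}" for i in range(values.shape[0]))
    return SpotMatrix(spot_ids, design, values)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-conditions dataset: 70 spots, 6+6 gels, 10 DE spots."""
    return generate_complete_dataset(SyntheticConfig(seed=2024))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    return default_dataset.matrix


@pytest.fixture
def small_matrix():
    """4 x 4 complete matrix with two gels per group."""
    rng = np.random.default_rng(5)
    return make_matrix(rng.uniform(1, 10, size=(4, 4)))
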