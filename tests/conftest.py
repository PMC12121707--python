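import numpy as np
import pytest

from helpnet.data_model import ActivityMatrix


def make_matrix(values, condition, subject_ids=None, region_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ActivityMatrix(
        values=values,
        subject_ids=subject_ids or [f"s{i}" for i in range(n)],
        region_ids=region_ids or [f"R{j}" for j in range(p)],
        condition=np.asarray(condition, dtype=object),
    )


@pytest.fixture
def two_group_matrix():
    """20 subjects x 8 regions, a planted mean shift in the first 3 regions."""
    rng = np.random.default_rng(42)
    mu = rng.uniform(5, 15, 8)
    shift = np.array([2.0, 2.0, 2.0, 0, 0, 0, 0, 0])
    x = np.vstack(
        [
            rng.normal(mu + shift, 1.0, size=(10, 8)),
            rng.normal(mu, 1.0, size=(10, 8)),
        ]
    )
    return make_matrix(x, ["opener"] * 10 + ["nonopener"] * 10)


@pytest.fixture
def three_group_matrix():
    rng = np.random.default_rng(7)
    x = rng.uniform(2, 20, size=(12, 6))
    return make_matrix(x, ["opener"] * 4 + ["nonopener"] * 4 + ["baseline"] * 4)
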