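import numpy as np
import pytest

from metofs import Dataset, FsConfig, SearchSpace
from metofs.optim_core import Objective
from metofs.synthdata import make_splits


@pytest.fixture
def unit3() -> SearchSpace:
    return SearchSpace.unit(3)


@pytest.fixture
def sphere() -> Objective:
    return Objective(lambda x: float(np.dot(x, x)), name="sphere", known_optimum=0.0)


@pytest.fixture
def separable_dataset() -> tuple[Dataset, list[int]]:
    """Two widely separated Gaussian blobs (delta = 8 sigma on 2 of 6 features).

    Any mask containing an informative feature classifies perfectly, which
    pins the wrapper fitness to the pure feature-count term.
    """
    rng = np.random.default_rng(42)
    n = 120
    informative = [0, 3]
    x = rng.standard_normal((n, 6))
    y = np.repeat([0, 1], n // 2)
    x[np.ix_(np.flatnonzero(y == 1), informative)] += 8.0
    split = make_splits(n, labels=y, seed=1)
    return Dataset(features=x, labels=y, split=split), informative


@pytest.fixture
def fs_cfg() -> FsConfig:
    return FsConfig()
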