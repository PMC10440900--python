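import numpy as np
import pytest

from nbblca.data_model import BinaryDataset, RunConfig
from nbblca.fixtures import make_toy


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def nb4():
    return make_toy("nb4")


@pytest.fixture
def sep2():
    """Well-separated 2-component mixture, N=200, M=6."""
    return make_toy("sep2")


@pytest.fixture
def quick_run():
    """Small-but-sufficient schedule for unit tests."""
    return RunConfig(seed=7, n_restarts=4, max_iter=300, gibbs_iters=600, burn_in=200, thin=2)


@pytest.fixture
def three_row_csv(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text("f1,f2,class\n0,1,a\n1,1,b\n0,0,a\n")
    return p
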