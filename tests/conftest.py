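import numpy as np
import pytest

from dcmnet import build_benchmark_network, integrate, to_sample_based


@pytest.fixture(scope="session")
def bench_net():
    return build_benchmark_network(seed=0)


@pytest.fixture(scope="session")
def bench_tc(bench_net):
    return integrate(bench_net)


@pytest.fixture(scope="session")
def bench_data(bench_tc):
    return to_sample_based(bench_tc, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
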