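import pytest

from nocgraph import benchmark_fixtures as bf


@pytest.fixture
def lin():
    return bf.g_lin()


@pytest.fixture
def lin3():
    return bf.g_lin3()


@pytest.fixture
def or_graph():
    return bf.g_or()


@pytest.fixture
def prod():
    return bf.g_prod()


@pytest.fixture
def cyc():
    return bf.g_cyc()


@pytest.fixture
def common():
    return bf.g_common()


@pytest.fixture
def bench27():
    return bf.benchmark27()
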