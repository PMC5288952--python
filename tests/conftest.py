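import pytest

from cubefed import (
    build_summary,
    clients_for,
    derive_indexes,
    running_example,
)


@pytest.fixture(scope="session")
def example():
    """The clinical running-example federation, policy and queries."""
    return running_example()


@pytest.fixture(scope="session")
def example_index(example):
    return derive_indexes(
        build_summary(ds) for ds in example.federation.datasets
    )


@pytest.fixture()
def example_clients(example):
    """Fresh instrumented clients (counters start at zero)."""
    return clients_for(example.federation)
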