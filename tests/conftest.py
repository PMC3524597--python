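import pytest

from greenwallcba import io, transfer
from greenwallcba.meta import to_weighted
from greenwallcba.synth import load_fixture


@pytest.fixture(scope="session")
def tables():
    return io.load_parameter_tables()


@pytest.fixture(scope="session")
def config(tables):
    return io.make_transfer_config(tables)


@pytest.fixture(scope="session")
def records():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def records_by_id(records):
    return {r.study_id: r for r in records}


@pytest.fixture(scope="session")
def estimates(records, config):
    return transfer.transfer_all(records, config)


@pytest.fixture(scope="session")
def weighted(estimates):
    return to_weighted(estimates)


@pytest.fixture(scope="session")
def demo_3m_high():
    return load_fixture("demo_3m")


@pytest.fixture(scope="session")
def demo_19m_high():
    return load_fixture("demo_19m")


@pytest.fixture(scope="session")
def demo_3m_low():
    return load_fixture("demo_3m_low")


@pytest.fixture(scope="session")
def demo_19m_low():
    return load_fixture("demo_19m_low")
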