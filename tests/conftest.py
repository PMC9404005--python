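import pytest

from chromlogd import dataset, qsrr


@pytest.fixture(scope="session")
def table1():
    """Packaged 73-compound reference table, values as published."""
    return dataset.load_reference_table()


@pytest.fixture(scope="session")
def repaired(table1):
    """Reference table with the N5/N6 log k_w transposition repaired."""
    return dataset.with_swapped_retention(table1)


@pytest.fixture(scope="session")
def cascade_result(table1):
    """Default two-stage cascade on the reference table (repair applied)."""
    return qsrr.run_cascade(table1)


@pytest.fixture(scope="session")
def software_logd():
    return dataset.load_software_logd()
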