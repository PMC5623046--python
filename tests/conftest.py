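import pytest

from pdzlie import datasets, lie


@pytest.fixture(scope="session")
def table1():
    return datasets.load_table1()


@pytest.fixture(scope="session")
def table2():
    return datasets.load_table2()


@pytest.fixture(scope="session")
def table5():
    return datasets.load_table5()


@pytest.fixture(scope="session")
def fitted(table1):
    """The LIE fit to the packaged fitting table."""
    return lie.fit_lie(table1)


@pytest.fixture(scope="session")
def caspr_reference(table1):
    refs = datasets.reference_records(table1)
    return {"caspr4": refs["caspr4"]}
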