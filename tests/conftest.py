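import pytest

import moleval as mv


@pytest.fixture(scope="session")
def toys():
    return mv.toy_molecule_set()


@pytest.fixture(scope="session")
def toy(toys):
    def get(name):
        return next(m for m in toys if m.name == name)
    return get


@pytest.fixture(scope="session")
def invalid_set():
    return mv.invalid_molecule_set()


@pytest.fixture(scope="session")
def corrected():
    return mv.load_shipped_table("corrected")


@pytest.fixture(scope="session")
def legacy():
    return mv.load_shipped_table("legacy")


@pytest.fixture(scope="session")
def aromatic_table():
    return mv.load_shipped_table("aromatic")


@pytest.fixture(scope="session")
def small_corpus():
    spec = mv.FixtureSpec(seed=7, n_molecules=200, fraction_invalid=0.2,
                          fraction_fragmented=0.1)
    return mv.corpus(spec)
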