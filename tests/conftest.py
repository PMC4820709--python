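import pytest

from repfam import build_catalogue, sequence_catalogue, toy_sequences


@pytest.fixture(scope="session")
def toys():
    return toy_sequences()


@pytest.fixture(scope="session")
def s1_catalogue(toys):
    return sequence_catalogue(toys["s1"])


@pytest.fixture(scope="session")
def t1_catalogue(toys):
    return build_catalogue(toys["t1"], family_id="t1")


def mrset_key(mrs):
    """Canonical comparable view of an MRSet: pattern -> (count, proteins, occurrences)."""
    return {
        m.pattern: (m.n_instances, m.n_proteins, tuple(sorted(m.occurrences)))
        for m in mrs
    }
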