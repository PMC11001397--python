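import numpy as np
import pytest

from altconf import (DihedralTrace, FixtureSpec, generate_fixture,
                     load_rotamer_library, two_state_fixture)


@pytest.fixture(scope="session")
def library():
    return load_rotamer_library()


@pytest.fixture(scope="session")
def two_state():
    """Noise-free Ala-Ser-Ala fixture, Ser 60% 'm' / 40% 'p'."""
    return generate_fixture(two_state_fixture())


@pytest.fixture(scope="session")
def three_state():
    """Noise-free fixture with Ser planted in 3 rotamers (0.5/0.3/0.2)."""
    spec = FixtureSpec(sequence=("ALA", "SER", "ALA"),
                       planted={2: [("m", 0.5), ("p", 0.3), ("t", 0.2)]})
    return generate_fixture(spec)


def make_trace(densities, step=5.0, chain="A", seqid="2", restype="SER", chi=1):
    return DihedralTrace(chain=chain, seqid=seqid, residue_type=restype,
                         chi=chi, step=step, densities=np.asarray(densities,
                                                                  dtype=float))


@pytest.fixture
def trace_factory():
    return make_trace
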