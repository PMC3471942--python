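import numpy as np
import pytest

from thermoforest import make_benchmark
from thermoforest.records import ProteinRecord, Pssm
from thermoforest.simulate import gen_pssm, gen_protein, gen_states


@pytest.fixture(scope="session")
def small_bench():
    """Small sequence-mode synthetic study shared across tests."""
    return make_benchmark(seed=7, n_single=60, n_double=20, n_proteins=8, length=60)


@pytest.fixture(scope="session")
def struct_bench():
    """Small structure-mode study (41 features, Delaunay tables)."""
    return make_benchmark(seed=11, n_single=40, n_double=10, n_proteins=6,
                          length=50, mode="structure")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_protein():
    p = gen_protein(30, seed=3, id="toy")
    ss, rsa = gen_states(30, seed=4)
    return p.attach(ss=ss, rsa=rsa, profile=gen_pssm(p, seed=5))


@pytest.fixture
def constant_pssm():
    """A 6-residue protein with every log-odds 2 and every weighted score 5."""
    p = ProteinRecord(id="c", sequence="MKVLAT")
    pssm = Pssm(np.full((6, 20), 2), np.full((6, 20), 5.0))
    return p.attach(profile=pssm)
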