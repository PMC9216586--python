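import numpy as np
import pytest

from ssforge.fixtures import FixtureSpec, make_disulphide_fixture, make_ideal_helix, make_toy_database


@pytest.fixture(scope="session")
def helix30():
    return make_ideal_helix(30, seed=11)


@pytest.fixture()
def bridged():
    """Fixture peptide with a planted ideal cystine (d_ss 2.04 Å, χss +90°)."""
    return make_disulphide_fixture(FixtureSpec(seed=5))


@pytest.fixture()
def bridged_stripped():
    """Same fixture with the planted side chains removed (SG and CB gone)."""
    st = make_disulphide_fixture(FixtureSpec(seed=5))
    p1, p2 = st.native_disulphides[0]
    for key in (p1, p2):
        res = st.residue(*key)
        res.atoms.pop("SG")
        res.atoms.pop("CB")
        res.cb_source = None
    return st


@pytest.fixture(scope="session")
def toy_db():
    structures, truth = make_toy_database(7)
    return structures, truth


def rigid_transform(rng: np.random.Generator):
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-30, 30, size=3)
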