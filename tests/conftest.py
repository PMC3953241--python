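import numpy as np
import pytest

from tripath.fixtures import FixtureSpec, make_chain, make_hinge_pair, \
    two_domain_spec


@pytest.fixture(scope="session")
def extended9():
    spec = FixtureSpec(n_residues=9, segments=[("extended", -1)],
                       hinge=(4, 0.1))
    return make_chain(spec)


@pytest.fixture(scope="session")
def helix30():
    spec = FixtureSpec(n_residues=30, segments=[("helix", -1)],
                       hinge=(15, 0.1))
    return make_chain(spec)


@pytest.fixture(scope="session")
def hinge_pair():
    """60-residue two-domain fixture, 30 degree hinge (the overlap fixture)."""
    return make_hinge_pair(two_domain_spec(60, np.deg2rad(30.0)))


@pytest.fixture(scope="session")
def transition_pair():
    """60-residue two-domain fixture, 60 degree hinge (~4 A C-alpha RMSD)."""
    return make_hinge_pair(two_domain_spec(60, np.deg2rad(60.0)))


@pytest.fixture(scope="session")
def glycine_chain():
    spec = FixtureSpec(n_residues=12, segments=[("helix", -1)],
                       hinge=(6, 0.1), glycine_every=4)
    return make_chain(spec)
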