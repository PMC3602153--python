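import numpy as np
import pytest

from pdzscan import fixtures, svm
from pdzscan.structure import Atom, DomainStructure


def build_structure(residue_specs, chain_id="A"):
    """Build a DomainStructure from [(resname, {atom: (x,y,z,element)})]."""
    atoms = []
    serial = 1
    for idx, (resname, atom_map) in enumerate(residue_specs):
        for name, value in atom_map.items():
            *coords, element = value
            atoms.append(Atom(serial, name, element, idx, resname, chain_id,
                              np.array(coords, float)))
            serial += 1
    return DomainStructure(atoms)


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def default_data(default_spec):
    """Records, planted PWMs, raw domain vectors and site sequences for the
    default fixture conditions (20 domains, 2 archetypes, 30+/60- each)."""
    records, planted = fixtures.make_interactions(default_spec)
    vectors, site_seqs = fixtures.encode_fixture_domains(default_spec)
    return {"records": records, "planted": planted, "vectors": vectors,
            "site_seqs": site_seqs}


@pytest.fixture(scope="session")
def small_spec():
    return fixtures.FixtureSpec(seed=0, n_domains=6, n_pos=12, n_neg=24,
                                proteome_size=80)


@pytest.fixture(scope="session")
def small_data(small_spec):
    records, planted = fixtures.make_interactions(small_spec)
    vectors, site_seqs = fixtures.encode_fixture_domains(small_spec)
    return {"records": records, "planted": planted, "vectors": vectors,
            "site_seqs": site_seqs}


@pytest.fixture(scope="session")
def small_model(small_data):
    return svm.train(small_data["records"], small_data["vectors"],
                     gamma=0.01, c_negative=4.0, seed=0)
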