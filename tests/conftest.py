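import numpy as np
import pytest

from dfgflip.fixtures import ToyKinaseSpec, make_toy_cavity, make_toy_kinase


@pytest.fixture(scope="session")
def toy_in():
    s, ann = make_toy_kinase(ToyKinaseSpec(target_distance_sum=31.0,
                                           dfg_state="in", seed=1))
    return s


@pytest.fixture(scope="session")
def toy_out():
    s, _ = make_toy_kinase(ToyKinaseSpec(target_distance_sum=31.0,
                                         dfg_state="out", seed=1))
    return s


@pytest.fixture(scope="session")
def toy_intermediate():
    s, _ = make_toy_kinase(ToyKinaseSpec(target_distance_sum=31.0,
                                         dfg_state="intermediate", seed=1))
    return s


@pytest.fixture(scope="session")
def toy_annotation(toy_in):
    return toy_in.annotation


@pytest.fixture(scope="session")
def cube_cavity():
    return make_toy_cavity("cube", 10.0, seed=0)


@pytest.fixture(scope="session")
def sphere_cavity():
    return make_toy_cavity("sphere", 8.0, seed=0)


@pytest.fixture(scope="session")
def three_chamber_cavity():
    return make_toy_cavity("three_chamber", 8.0, seed=0)


def displace_loop(structure, delta, start=48, end=63, source_id=None):
    """Copy of a structure with residues start..end rigidly translated."""
    delta = np.asarray(delta, dtype=float)
    atoms = []
    for a in structure.atoms:
        if start <= a.res_seq <= end:
            a = a.moved_to(np.asarray(a.coord) + delta)
        atoms.append(a)
    out = structure.with_atoms(atoms)
    if source_id:
        out.source_id = source_id
    return out
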