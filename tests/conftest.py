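import numpy as np
import pytest

from epimatch import (
    BindingSite,
    ParameterSet,
    PrecisionScoreMatrix,
    compute_relative_accessibility,
    surface_residues,
)
from epimatch.fixtures import ToyComplexSpec, make_decoys, make_toy_complex
from epimatch.structure import Atom, Residue, ResidueID, StructureUnit


def make_residue(rid, positions, aa="ALA", names=None, elements=None):
    """Build a residue from raw coordinates (first atom is the Cα)."""
    positions = np.atleast_2d(np.asarray(positions, float))
    names = names or ["CA"] + [f"CB{i}" for i in range(1, len(positions))]
    elements = elements or ["C"] * len(positions)
    atoms = [Atom(n, e, p) for n, e, p in zip(names, elements, positions)]
    return Residue(ResidueID(*rid) if isinstance(rid, tuple) else rid, aa, atoms)


def random_unit(rng, n_residues, role="antigen", chain="A", spread=20.0,
                atoms_per_res=5):
    residues = []
    for i in range(n_residues):
        base = rng.uniform(-spread, spread, size=3)
        pts = base + rng.normal(scale=1.5, size=(atoms_per_res, 3))
        residues.append(make_residue((chain, i + 1, ""), pts))
    return StructureUnit(role, residues)


@pytest.fixture(scope="session")
def toy():
    """A deterministic planted-epitope complex shared across tests."""
    spec = ToyComplexSpec(n_antigen_residues=40, n_antibody_residues=8,
                          epitope_size=6, seed=1)
    pose, planted, site = make_toy_complex(spec)
    return {"spec": spec, "pose": pose, "planted": planted, "site": site}


@pytest.fixture(scope="session")
def toy_surface(toy):
    smap = compute_relative_accessibility(toy["pose"].ag)
    return smap, surface_residues(smap)


@pytest.fixture(scope="session")
def informative_ps(toy):
    """PS = 1 on (site type, planted-epitope type) pairs, 0 elsewhere."""
    pose, planted = toy["pose"], toy["planted"]
    ab_types = {r.aa1 for r in pose.ab}
    epi_types = {pose.ag[r].aa1 for r in planted}
    return PrecisionScoreMatrix.from_dict(
        {(a, g): 1.0 for a in ab_types for g in epi_types}, default=0.0)


@pytest.fixture(scope="session")
def toy_decoys(toy):
    return make_decoys(toy["pose"], n_near=3, n_far=7, seed=7)


@pytest.fixture
def params():
    return ParameterSet()
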