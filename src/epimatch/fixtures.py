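"""Deterministic toy antibody–antigen complexes, decoy sets and training data.

The generator builds simplified complexes sufficient for every distance-,
accessibility- and type-based computation in the pipeline: antigen residues
sit on a spherical shell (hence all surface-exposed), each modelled as a Cα
plus one to three pseudo side-chain heavy atoms pointing radially outward.
The antibody hovers over a contiguous surface cap — the planted epitope — so
that exactly the planted residues are in heavy-atom contact (< 4.5 Å) with
the binding site.  Decoy sets mix near-native poses (small rigid
perturbations of the antibody, interface RMSD < 10 Å by construction) with
far poses (antibody relocated to the opposite side of the antigen).

Everything is reproducible bit-for-bit from the spec and seed.  The shell
geometry has none of the ruggedness, flexibility or sequence statistics of
real antigens; it exercises the pipeline's logic, not its biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .docksorter import Pose
from .evaluation import irmsd
from .potential import TrainingCase
from .structure import (
    AA1_TO_3,
    CANONICAL_AA1,
    Atom,
    BindingSite,
    Residue,
    ResidueID,
    StructureUnit,
)

__all__ = [
    "ToyComplexSpec",
    "GenerationError",
    "make_toy_complex",
    "make_decoys",
    "make_training_set",
    "write_fixture_files",
]


class GenerationError(RuntimeError):
    """Raised when the requested toy geometry is infeasible."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of one toy complex.

    contact_geometry is the heavy-atom gap (Å) between each planted epitope
    residue's outermost atom and the antibody atom placed above it; the
    default 3.5 Å sits comfortably inside the 4.5 Å contact cutoff.
    lattice_spacing is the Cα nearest-neighbour distance on the antigen
    shell; 4.0 Å keeps adjacent residues within the contact cutoff so
    patches grow over the surface.
    """

    n_antigen_residues: int = 40
    n_antibody_residues: int = 8
    epitope_size: int = 6
    contact_geometry: float = 3.5
    seed: int = 0
    lattice_spacing: float = 4.0
    antigen_aa: str | None = None   # 1-letter sequence, cycled over residues
    antibody_aa: str | None = None
    epitope_aa: str | None = None   # overrides antigen_aa on the planted cap

    def __post_init__(self) -> None:
        if self.epitope_size > self.n_antigen_residues:
            raise ValueError("epitope cannot exceed the antigen size")
        if self.contact_geometry <= 0 or self.lattice_spacing <= 0:
            raise ValueError("geometric parameters must be positive")


def _shell_points(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _cycle_aa(seq: str | None, n: int, default: str = CANONICAL_AA1) -> list[str]:
    src = seq or default
    return [AA1_TO_3[src[i % len(src)].upper()] for i in range(n)]


def _min_heavy_distance(res_a: Residue, res_b: Residue) -> float:
    return float(cdist(res_a.heavy_coords(), res_b.heavy_coords()).min())


def make_toy_complex(spec: ToyComplexSpec
                     ) -> tuple[Pose, set[ResidueID], BindingSite]:
    """Build a native pose with a planted epitope.

    Returns the pose, the planted epitope residue IDs and the antibody
    binding site (all antibody residues).  Raises :class:`GenerationError`
    if any non-planted antigen residue ends up in contact with the antibody.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_antigen_residues
    # shell radius so that nearest-neighbour Cα spacing ≈ lattice_spacing
    radius = spec.lattice_spacing * np.sqrt(n / (4 * np.pi)) / 1.05
    units = _shell_points(n)
    ag_aa = _cycle_aa(spec.antigen_aa, n)
    # planted epitope: the cap of residues closest (by angle) to the first
    # lattice direction
    center = units[0]
    order = np.argsort(-units @ center)
    epitope_idx = sorted(order[: spec.epitope_size].tolist())
    if spec.epitope_aa is not None:
        epi_types = _cycle_aa(spec.epitope_aa, spec.epitope_size)
        for k, idx in enumerate(epitope_idx):
            ag_aa[idx] = epi_types[k]

    side_names = ("CB", "CG", "CD")
    ag_residues: list[Residue] = []
    outer_atom_pos: list[np.ndarray] = []
    for i in range(n):
        u = units[i]
        n_side = int(rng.integers(1, 4))
        atoms = [Atom("CA", "C", radius * u)]
        for k in range(n_side):
            atoms.append(Atom(side_names[k], "C", (radius + 1.5 * (k + 1)) * u))
        ag_residues.append(Residue(ResidueID("A", i + 1), ag_aa[i], atoms))
        outer_atom_pos.append(atoms[-1].position)
    antigen = StructureUnit("antigen", ag_residues)

    n_ab = spec.n_antibody_residues
    ab_aa = _cycle_aa(spec.antibody_aa, n_ab)
    ab_atoms: list[list[Atom]] = [[] for _ in range(n_ab)]
    gap = spec.contact_geometry
    for k, idx in enumerate(epitope_idx):
        j = k % n_ab
        u = units[idx]
        contact = outer_atom_pos[idx] + gap * u
        ab_atoms[j].append(Atom(side_names[len(ab_atoms[j]) % 3], "C", contact))
    # Cα for every antibody residue, placed well above the cap centre
    apex = (radius + 6.0 * gap) * center
    ring = _shell_points(max(n_ab, 4))[:n_ab]
    for j in range(n_ab):
        ca = apex + 2.0 * spec.lattice_spacing * ring[j]
        ab_atoms[j].insert(0, Atom("CA", "C", ca))
    ab_residues = [
        Residue(ResidueID("H", j + 1), ab_aa[j], ab_atoms[j]) for j in range(n_ab)
    ]
    antibody = StructureUnit("antibody", ab_residues)
    pose = Pose(antibody, antigen, source_rank=0)
    planted = {ResidueID("A", idx + 1) for idx in epitope_idx}

    # the generated geometry must realize exactly the planted contacts
    contacts = {
        rg.id
        for rg in antigen
        for ra in antibody
        if _min_heavy_distance(ra, rg) < 4.5
    }
    if spec.epitope_size and contacts != planted:
        raise GenerationError(
            f"infeasible geometry: contacts {sorted(map(str, contacts))} != "
            f"planted {sorted(map(str, planted))}"
        )
    if spec.epitope_size == 0 and contacts:
        raise GenerationError("empty epitope requested but contacts present")
    site = BindingSite(antibody, frozenset(antibody.residue_ids))
    return pose, planted, site


def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * rng.uniform(0, max_angle)).as_matrix()


def _perturbed_ab(native: Pose, rot: np.ndarray, shift: np.ndarray) -> Pose:
    """New pose with the antibody rotated about its centroid then shifted."""
    centroid = native.ab.heavy_coords().mean(axis=0)
    ab = native.ab.transformed(rot, centroid - rot @ centroid + shift)
    return Pose(ab, native.ag)


def make_decoys(native: Pose, n_near: int, n_far: int,
                near_perturbation: float = 1.5, seed: int = 0,
                near_native_cutoff: float = 10.0) -> list[Pose]:
    """A seeded decoy set: near-native poses plus far poses, ranks shuffled.

    Near decoys are small rigid perturbations of the antibody (verified
    I_rmsd < cutoff); far decoys relocate the antibody to the antigen's far
    side (verified I_rmsd ≥ cutoff).
    """
    if near_perturbation <= 0:
        raise ValueError("near_perturbation must be positive")
    rng = np.random.default_rng(seed)
    ag_centroid = native.ag.heavy_coords().mean(axis=0)
    ab_centroid = native.ab.heavy_coords().mean(axis=0)
    poses: list[Pose] = []
    for _ in range(n_near):
        for _attempt in range(100):
            rot = _random_rotation(rng, near_perturbation / 10.0)
            shift = rng.normal(scale=near_perturbation / np.sqrt(3), size=3)
            cand = _perturbed_ab(native, rot, shift)
            if irmsd(cand, native).value < near_native_cutoff:
                poses.append(cand)
                break
        else:
            raise GenerationError("could not generate a near-native decoy")
    # proper rotation by pi about an axis through the antigen centroid,
    # perpendicular to the antibody direction: sends the antibody to the
    # far side without mirroring
    direction = ab_centroid - ag_centroid
    direction /= np.linalg.norm(direction)
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    flip = Rotation.from_rotvec(np.pi * perp).as_matrix()
    offset = float(np.linalg.norm(ab_centroid - ag_centroid))
    for _ in range(n_far):
        for attempt in range(100):
            jitter = _random_rotation(rng, 0.3)
            rot = jitter @ flip
            # push the antibody centroid past the far side by a margin large
            # enough that no superposition of the pooled interface can bring
            # the decoy within the near-native cutoff
            margin = 3.0 * near_native_cutoff + 10.0 * attempt
            target = ag_centroid - (offset + margin) * (jitter @ direction)
            cand = Pose(native.ab.transformed(
                rot, target - rot @ ab_centroid), native.ag)
            if irmsd(cand, native).value >= near_native_cutoff:
                poses.append(cand)
                break
        else:
            raise GenerationError("could not generate a far decoy")
    order = rng.permutation(len(poses))
    out = [Pose(poses[i].ab, poses[i].ag, source_rank=rank + 1)
           for rank, i in enumerate(order)]
    return out


def make_training_set(pair_rates: dict[tuple[str, str], float],
                      n_cases: int = 1, decoys_per_case: int = 100,
                      seed: int = 0) -> list[TrainingCase]:
    """Training cases whose decoys reproduce each native contact of a given
    type pair with the specified probability.

    Each case is a toy complex with a one-to-one contact per requested
    (antibody type, antigen type) pair.  In each decoy a native contact is
    kept with its pair's probability; otherwise the contacting atom is
    relocated over a random non-epitope antigen residue of the SAME type,
    producing an incorrect contact that still tallies in the same
    (T_ab, T_ag) cell — so the cell's estimated score converges to the
    planted correctness rate.
    """
    for pair, p in pair_rates.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"rate for {pair} outside [0,1]")
    pairs = sorted(pair_rates)
    k = len(pairs)
    cases: list[TrainingCase] = []
    master = np.random.default_rng(seed)
    for case_idx in range(n_cases):
        spec = ToyComplexSpec(
            n_antigen_residues=max(6 * k, 30),
            n_antibody_residues=k,
            epitope_size=k,
            seed=int(master.integers(2 ** 31)),
            antigen_aa="".join(ag for _, ag in pairs),
            antibody_aa="".join(ab for ab, _ in pairs),
            epitope_aa="".join(ag for _, ag in pairs),
        )
        native, planted, site = make_toy_complex(spec)
        rng = np.random.default_rng(int(master.integers(2 ** 31)))
        planted_sorted = sorted(planted)
        non_epitope = [r for r in native.ag.residues if r.id not in planted]
        decoys = []
        for d in range(decoys_per_case):
            new_ab_res = []
            for j, res in enumerate(native.ab.residues):
                atoms = [res.atoms[0]]  # Cα stays put
                for contact_atom, epi_id in zip(res.atoms[1:],
                                                planted_sorted[j::k]):
                    tag = native.ag[epi_id].aa1
                    keep = rng.uniform() < pair_rates[(res.aa1, tag)]
                    if keep:
                        atoms.append(contact_atom)
                    else:
                        choices = [r for r in non_epitope if r.aa1 == tag]
                        if not choices:
                            raise GenerationError(
                                f"no non-epitope residue of type {tag} to relocate onto")
                        target = choices[int(rng.integers(len(choices)))]
                        outer = target.atoms[-1].position
                        u = outer / np.linalg.norm(outer)
                        atoms.append(Atom(contact_atom.name, "C",
                                          outer + spec.contact_geometry * u))
                new_ab_res.append(Residue(res.id, res.aa_type, atoms))
            decoys.append(Pose(StructureUnit("antibody", new_ab_res),
                               native.ag, source_rank=d + 1))
        cases.append(TrainingCase(native, decoys, site=site))
    return cases


def write_fixture_files(outdir: str | Path, spec: ToyComplexSpec,
                        n_near: int = 3, n_far: int = 7,
                        decoy_seed: int | None = None) -> dict[str, Path]:
    """Materialize a toy complex and its decoys as plain files.

    Writes native.pdb, decoys.pdb (multi-model), cdr.txt (binding-site
    residue list, one "chain seqnum icode" per line) and epitope_truth.txt.
    """
    from .structure import write_pdb  # local import avoids cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    native, planted, site = make_toy_complex(spec)
    decoys = make_decoys(native, n_near, n_far,
                         seed=spec.seed if decoy_seed is None else decoy_seed)
    paths = {
        "native": outdir / "native.pdb",
        "decoys": outdir / "decoys.pdb",
        "cdr": outdir / "cdr.txt",
        "truth": outdir / "epitope_truth.txt",
    }
    paths["native"].write_text(write_pdb([native.ab, native.ag]))
    paths["decoys"].write_text(_multi_model_pdb(decoys))
    paths["cdr"].write_text(
        "".join(f"{r.chain} {r.seqnum} {r.icode}\n" for r in sorted(site.members))
    )
    paths["truth"].write_text(
        "".join(f"{r.chain} {r.seqnum} {r.icode}\n" for r in sorted(planted))
    )
    return paths


def _multi_model_pdb(poses: list[Pose]) -> str:
    st = gemmi.Structure()
    for pose in sorted(poses, key=lambda p: p.source_rank):
        model = gemmi.Model(pose.source_rank)
        for unit in (pose.ab, pose.ag):
            chains: dict[str, gemmi.Chain] = {}
            for res in unit.residues:
                ch = chains.setdefault(res.id.chain, gemmi.Chain(res.id.chain))
                gres = gemmi.Residue()
                gres.name = res.aa_type
                gres.seqid = gemmi.SeqId(res.id.seqnum, res.id.icode or " ")
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.position)
                    ga.occ = 1.0
                    gres.add_atom(ga)
                ch.add_residue(gres)
            for ch in chains.values():
                model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
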