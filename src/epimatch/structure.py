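"""Structure data model, PDB I/O and distance primitives.

The package works on a deliberately small residue/atom model: a
:class:`StructureUnit` is an ordered collection of residues, each holding its
heavy (and optionally hydrogen) atoms with coordinates in Ångströms.  All
geometric predicates downstream (contacts, patch expansion, interface
definition) are built on the two distance primitives defined here:

* :func:`heavy_atom_min_distance` — the minimum over all heavy-atom pairs,
  used for the 4.5 Å inter-molecular contact definition, and
* :func:`representative_distance` — a single-point (Cα) distance used for
  the intramolecular compatibility test of the contact graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "ResidueID",
    "Residue",
    "StructureUnit",
    "BindingSite",
    "ParameterSet",
    "PDBParseError",
    "InvalidResidueError",
    "read_pdb",
    "write_pdb",
    "heavy_atom_min_distance",
    "representative_distance",
    "AA3_TO_1",
    "AA1_TO_3",
    "CANONICAL_AA1",
]

CANONICAL_AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# non-standard residues mapped onto their canonical parent
_NONSTANDARD = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
                "SEP": "SER", "TPO": "THR", "PTR": "TYR", "MLY": "LYS",
                "CSO": "CYS"}

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class PDBParseError(ValueError):
    """Raised when PDB content cannot be parsed or a selection is empty."""


class InvalidResidueError(ValueError):
    """Raised when a residue lacks the atoms an operation requires."""


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element symbol and position (Å)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


class ResidueID(NamedTuple):
    """PDB-style residue address: chain, author sequence number, insertion code."""

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self) -> str:  # "A100" / "A100A"
        return f"{self.chain}{self.seqnum}{self.icode}"


@dataclass
class Residue:
    id: ResidueID
    aa_type: str  # three-letter canonical code, or "UNK"
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not any(a.heavy for a in self.atoms):
            raise InvalidResidueError(f"residue {self.id} has no heavy atoms")

    @property
    def aa1(self) -> str:
        """One-letter code; 'X' for UNK."""
        return AA3_TO_1.get(self.aa_type, "X")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms if a.heavy])

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def representative_point(self, atom_name: str = "CA") -> np.ndarray:
        """Cα position, falling back to the heavy-atom centroid with a warning."""
        atom = self.get_atom(atom_name)
        if atom is not None:
            return atom.position
        warnings.warn(
            f"residue {self.id} lacks atom {atom_name}; using heavy-atom centroid",
            stacklevel=2,
        )
        return self.heavy_coords().mean(axis=0)


@dataclass
class StructureUnit:
    """A parsed antibody or antigen: ordered residues with unique IDs."""

    role: str  # "antibody" | "antigen"
    residues: list[Residue]

    def __post_init__(self) -> None:
        if self.role not in ("antibody", "antigen"):
            raise ValueError(f"role must be 'antibody' or 'antigen', got {self.role!r}")
        ids = [r.id for r in self.residues]
        if len(set(ids)) != len(ids):
            dup = [i for i in ids if ids.count(i) > 1][0]
            raise ValueError(f"duplicate residue ID {dup} in {self.role} unit")
        self._index = {r.id: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __getitem__(self, rid: ResidueID) -> Residue:
        return self._index[rid]

    def __contains__(self, rid: ResidueID) -> bool:
        return rid in self._index

    @property
    def residue_ids(self) -> list[ResidueID]:
        return [r.id for r in self.residues]

    def heavy_coords(self) -> np.ndarray:
        """All heavy-atom coordinates, stacked."""
        return np.vstack([r.heavy_coords() for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureUnit":
        """A copy with every atom mapped through x ↦ R·x + t."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        new_res = [
            Residue(
                r.id,
                r.aa_type,
                [Atom(a.name, a.element, rotation @ a.position + translation) for a in r.atoms],
            )
            for r in self.residues
        ]
        return StructureUnit(self.role, new_res)


@dataclass
class BindingSite:
    """The antibody residues supplied as the binding site (e.g. Chothia CDRs)."""

    unit: StructureUnit
    members: frozenset[ResidueID]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError("binding site is empty")
        missing = [m for m in self.members if m not in self.unit]
        if missing:
            raise ValueError(f"binding-site residues absent from unit: {sorted(missing)}")

    def residues(self) -> list[Residue]:
        return [self.unit[m] for m in sorted(self.members)]


@dataclass(frozen=True)
class ParameterSet:
    """Numeric constants of the prediction and rescoring pipeline.

    contact_cutoff      heavy-atom inter-molecular contact distance (Å)
    compat_cutoff       intramolecular-distance compatibility tolerance (Å)
    surface_threshold   relative-accessibility fraction defining surface residues
    overlap_threshold   fractional residue overlap above which a patch is discarded
    max_epitopes        number of non-overlapping epitopes retained
    near_native_cutoff  interface RMSD below which a decoy is close-to-native (Å)
    interface_cutoff    neighbourhood defining interface residues (Å)
    rescore_top_n       number of docking decoys rescored
    """

    contact_cutoff: float = 4.5
    compat_cutoff: float = 1.0
    surface_threshold: float = 0.07
    overlap_threshold: float = 0.3
    max_epitopes: int = 3
    near_native_cutoff: float = 10.0
    interface_cutoff: float = 10.0
    rescore_top_n: int = 30

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.overlap_threshold >= 1:
            raise ValueError("overlap_threshold must be < 1")


# ---------------------------------------------------------------------------
# distances

def heavy_atom_min_distance(a: Residue, b: Residue) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    ca, cb = a.heavy_coords(), b.heavy_coords()
    if ca.size == 0 or cb.size == 0:
        raise InvalidResidueError("residue with no heavy atoms")
    return float(cdist(ca, cb).min())


def representative_distance(a: Residue, b: Residue, atom_name: str = "CA") -> float:
    """Single-point (Cα by default) distance used for intramolecular tests."""
    return float(np.linalg.norm(a.representative_point(atom_name) - b.representative_point(atom_name)))


# ---------------------------------------------------------------------------
# PDB I/O

def _convert_gemmi_model(model: gemmi.Model, chains: Sequence[str] | None,
                         role: str) -> StructureUnit:
    residues: list[Residue] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            name = res.name.strip().upper()
            if name == "HOH":
                continue
            aa = name if name in AA3_TO_1 else _NONSTANDARD.get(name)
            if aa is None:
                if res.het_flag == "H":
                    continue  # ligands and other heteroatoms
                aa = "UNK"
            # altloc: keep highest occupancy per atom name, first on tie
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(a.name, a.element.name.upper(),
                     np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in best.values()
            ]
            if not any(at.heavy for at in atoms):
                continue
            rid = ResidueID(chain.name, res.seqid.num, (res.seqid.icode or " ").strip())
            residues.append(Residue(rid, aa, atoms))
    residues.sort(key=lambda r: (r.id.chain, r.id.seqnum, r.id.icode))
    if not residues:
        wanted = ", ".join(chains) if chains else "(all)"
        raise PDBParseError(f"no ATOM records for requested chains: {wanted}")
    return StructureUnit(role, residues)


def parse_pdb_models(text: str) -> gemmi.Structure:
    """Parse PDB content with gemmi, normalising parse failures."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"malformed PDB content: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no models in PDB content")
    return st


def read_pdb(text: str, chains: Sequence[str] | str | None = None,
             role: str = "antigen", model_index: int = 0) -> StructureUnit:
    """Parse PDB text into a :class:`StructureUnit`.

    Parameters
    ----------
    text : PDB-format content (ATOM/HETATM records).
    chains : chain IDs to keep; a comma-separated string or sequence.
        ``None`` keeps every chain.
    role : "antibody" or "antigen".
    model_index : which MODEL to read (0-based) for multi-model files.

    Hydrogens are retained but flagged non-heavy; for alternate locations the
    highest-occupancy conformer is kept (first wins a tie); waters and
    non-amino-acid HETATM records are dropped; MSE and similar modified
    residues map to their parent amino acid.
    """
    if isinstance(chains, str):
        chains = [c.strip() for c in chains.split(",") if c.strip()]
    st = parse_pdb_models(text)
    return _convert_gemmi_model(st[model_index], chains, role)


def write_pdb(units: Iterable[StructureUnit] | StructureUnit,
              bfactors: dict[ResidueID, float] | None = None) -> str:
    """Serialize one or more units to PDB text.

    ``bfactors`` optionally sets the B-factor column per residue — used to
    paint epitope membership onto the antigen for visualization.
    """
    if isinstance(units, StructureUnit):
        units = [units]
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for unit in units:
        chains: dict[str, gemmi.Chain] = {}
        for res in unit.residues:
            ch = chains.setdefault(res.id.chain, gemmi.Chain(res.id.chain))
            gres = gemmi.Residue()
            gres.name = res.aa_type
            gres.seqid = gemmi.SeqId(res.id.seqnum, res.id.icode or " ")
            b = 0.0 if bfactors is None else float(bfactors.get(res.id, 0.0))
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                ga.b_iso = b
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
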