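"""Solvent-accessible surface area and surface-residue classification.

Accessibility is computed with the Shrake–Rupley rolling-probe method on the
isolated unit, using a deterministic golden-spiral point lattice so results
are reproducible bit-for-bit.  A residue's relative accessibility is its raw
SASA divided by a theoretical maximum reference area for its amino-acid type
(Tien et al.-style values); residues above the 7% threshold are classified
as surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueID, StructureUnit

__all__ = [
    "SurfaceMap",
    "compute_relative_accessibility",
    "surface_residues",
    "shrake_rupley_sasa",
    "VDW_RADII",
    "MAX_REFERENCE_ASA",
]

# van der Waals radii by element (Å); default for unknown elements is carbon's
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_VDW = 1.70

# theoretical maximum accessible surface areas per residue type (Å²),
# Tien et al. 2013 theoretical values
MAX_REFERENCE_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_UNK_REFERENCE = float(np.mean(list(MAX_REFERENCE_ASA.values())))


@dataclass
class SurfaceMap:
    """Per-residue relative accessibility with a surface threshold."""

    accessibility: dict[ResidueID, float]
    threshold: float = 0.07
    raw_sasa: dict[ResidueID, float] = field(default_factory=dict)

    def is_surface(self, rid: ResidueID) -> bool:
        return self.accessibility[rid] > self.threshold


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n unit vectors."""
    i = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom SASA (Å²) of a set of spheres inflated by the probe radius."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe_radius
    n_atoms = len(coords)
    lattice = _sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.empty(n_atoms)
    max_r = radii.max()
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * lattice
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            diff = pts[:, None, :] - coords[neighbors][None, :, :]
            buried = (np.einsum("ijk,ijk->ij", diff, diff)
                      < (radii[neighbors] ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        out[i] = 4.0 * np.pi * radii[i] ** 2 * exposed / n_points
    return out


def compute_relative_accessibility(unit: StructureUnit, probe_radius: float = 1.4,
                                   threshold: float = 0.07, n_points: int = 960,
                                   reference: dict[str, float] | None = None) -> SurfaceMap:
    """Relative accessibility of every residue of an isolated unit.

    Raw SASA is computed over the unit's heavy atoms only (hydrogens ignored)
    and divided by the per-type maximal reference area; fractions may exceed 1
    for extended termini.  Residue types without a reference area fall back to
    the mean of the 20 canonical values, with a warning.
    """
    if len(unit) == 0:
        raise ValueError("cannot compute accessibility of an empty unit")
    reference = MAX_REFERENCE_ASA if reference is None else reference
    coords, radii, owner = [], [], []
    for idx, res in enumerate(unit):
        for atom in res.heavy_atoms:
            coords.append(atom.position)
            radii.append(VDW_RADII.get(atom.element.upper(), _DEFAULT_VDW))
            owner.append(idx)
    per_atom = shrake_rupley_sasa(np.array(coords), np.array(radii),
                                  probe_radius=probe_radius, n_points=n_points)
    per_res = np.zeros(len(unit))
    np.add.at(per_res, owner, per_atom)
    accessibility: dict[ResidueID, float] = {}
    raw: dict[ResidueID, float] = {}
    for idx, res in enumerate(unit):
        ref = reference.get(res.aa_type)
        if ref is None:
            warnings.warn(
                f"no reference area for residue type {res.aa_type}; using mean",
                stacklevel=2,
            )
            ref = _UNK_REFERENCE
        raw[res.id] = float(per_res[idx])
        accessibility[res.id] = float(per_res[idx] / ref)
    return SurfaceMap(accessibility, threshold=threshold, raw_sasa=raw)


def surface_residues(surface_map: SurfaceMap) -> set[ResidueID]:
    """Residues with relative accessibility strictly above the threshold."""
    return {rid for rid, acc in surface_map.accessibility.items()
            if acc > surface_map.threshold}
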