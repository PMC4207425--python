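"""Enumeration of candidate epitope-like surface patches on the antigen.

One patch is seeded at every surface residue and grown by exactly two rounds
of neighbourhood expansion over the surface residues: first every surface
residue whose heavy atoms come within the contact cutoff of the seed, then
every surface residue within the cutoff of any current member.  Duplicated
member sets from different seeds are retained; deduplication is the ranking
stage's concern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import ParameterSet, ResidueID, StructureUnit

__all__ = ["Patch", "expand_patch", "enumerate_patches", "surface_adjacency"]


class InvalidSeedError(ValueError):
    """Raised when a patch seed is not a surface residue."""


@dataclass(frozen=True)
class Patch:
    """A candidate epitope: seed plus its 2-round surface neighbourhood.

    ``provenance`` records the expansion round at which each member joined
    (0 = seed, 1, 2).
    """

    seed: ResidueID
    members: frozenset[ResidueID]
    provenance: tuple[tuple[ResidueID, int], ...] = ()

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("patch seed must be a member")

    def __len__(self) -> int:
        return len(self.members)


def surface_adjacency(antigen: StructureUnit, surface: set[ResidueID],
                      contact_cutoff: float) -> dict[ResidueID, set[ResidueID]]:
    """Heavy-atom proximity graph over the surface residues (strict < cutoff)."""
    surf = [r for r in antigen.residues if r.id in surface]
    coords, owner = [], []
    for idx, res in enumerate(surf):
        c = res.heavy_coords()
        coords.append(c)
        owner.extend([idx] * len(c))
    adj: dict[ResidueID, set[ResidueID]] = {r.id: set() for r in surf}
    if not surf:
        return adj
    allc = np.vstack(coords)
    owner_arr = np.array(owner)
    tree = cKDTree(allc)
    for i, j in tree.query_pairs(contact_cutoff):
        oi, oj = owner_arr[i], owner_arr[j]
        if oi != oj:
            # query_pairs uses <=; enforce the strict predicate
            if np.linalg.norm(allc[i] - allc[j]) < contact_cutoff:
                adj[surf[oi].id].add(surf[oj].id)
                adj[surf[oj].id].add(surf[oi].id)
    return adj


def _grow(seed: ResidueID, adj: dict[ResidueID, set[ResidueID]],
          rounds: int) -> Patch:
    level = {seed: 0}
    frontier = {seed}
    for ring in range(1, rounds + 1):
        nxt = set()
        for rid in frontier:
            nxt |= adj[rid]
        frontier = {r for r in nxt if r not in level}
        for r in frontier:
            level[r] = ring
    return Patch(seed, frozenset(level), tuple(sorted(level.items())))


def expand_patch(seed: ResidueID, antigen: StructureUnit, surface: set[ResidueID],
                 contact_cutoff: float = 4.5, rounds: int = 2) -> Patch:
    """Grow a single patch from ``seed`` by ``rounds`` expansion rounds."""
    if seed not in surface:
        raise InvalidSeedError(f"seed {seed} is not a surface residue")
    adj = surface_adjacency(antigen, surface, contact_cutoff)
    return _grow(seed, adj, rounds)


def enumerate_patches(antigen: StructureUnit, surface: set[ResidueID],
                      params: ParameterSet | None = None,
                      rounds: int = 2) -> list[Patch]:
    """One patch per surface residue, in deterministic residue order."""
    params = params or ParameterSet()
    if not surface:
        warnings.warn("no surface residues: returning no patches", stacklevel=2)
        return []
    adj = surface_adjacency(antigen, surface, params.contact_cutoff)
    seeds = [r.id for r in antigen.residues if r.id in surface]
    return [_grow(seed, adj, rounds) for seed in seeds]
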