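"""Contact-compatibility graph and epitope ranking.

For a candidate patch *Epi* and the antibody binding site *Ab*, every element
of the Cartesian product Epi × Ab is a node — a putative inter-molecular
residue contact.  Two nodes are connected iff the two contacts can exist
simultaneously in a rigid match: the intramolecular distance between the two
antibody residues and the one between the two antigen residues must agree to
within the compatibility cutoff (1 Å by default).  The patch score is

    Score(Epi) = Σ_n d(n) · PS(T_ab(n), T_ag(n)),

each candidate contact weighted by the number of other contacts it can
satisfy simultaneously and by the asymmetric Precision Score of its
amino-acid pair.  Patches are ranked by score and the top three mutually
non-overlapping ones (sharing ≤30% of the higher-scoring patch's residues)
are kept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .patches import Patch, enumerate_patches
from .potential import PrecisionScoreMatrix
from .sasa import compute_relative_accessibility, surface_residues
from .structure import (
    BindingSite,
    ParameterSet,
    Residue,
    ResidueID,
    StructureUnit,
    representative_distance,
)

__all__ = [
    "ContactNode",
    "ContactGraph",
    "EpitopePrediction",
    "compatible",
    "build_contact_graph",
    "score_patch",
    "patch_overlap_fraction",
    "select_top_patches",
    "predict_epitopes",
]


@dataclass(frozen=True)
class ContactNode:
    """A candidate inter-molecular contact (antibody residue, antigen residue)."""

    ab_residue: ResidueID
    ag_residue: ResidueID
    ab_type: str
    ag_type: str


@dataclass
class ContactGraph:
    nodes: list[ContactNode]
    adjacency: np.ndarray  # boolean |nodes|×|nodes|, symmetric, no self-edges

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class EpitopePrediction:
    """Ranked non-overlapping epitope patches with their scores."""

    ranked: list[tuple[Patch, float]]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranked]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("epitope scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.ranked)

    def patches(self) -> list[Patch]:
        return [p for p, _ in self.ranked]

    def to_json(self, antigen: StructureUnit | None = None) -> str:
        out = []
        for rank, (patch, score) in enumerate(self.ranked, start=1):
            members = []
            for rid in sorted(patch.members):
                entry = {"chain": rid.chain, "seqnum": rid.seqnum, "icode": rid.icode}
                if antigen is not None and rid in antigen:
                    entry["aa_type"] = antigen[rid].aa_type
                members.append(entry)
            out.append({
                "rank": rank,
                "score": score,
                "seed": {"chain": patch.seed.chain, "seqnum": patch.seed.seqnum,
                         "icode": patch.seed.icode},
                "residues": members,
            })
        return json.dumps({"epitopes": out}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EpitopePrediction":
        data = json.loads(text)
        ranked = []
        for epi in data["epitopes"]:
            members = frozenset(
                ResidueID(r["chain"], r["seqnum"], r.get("icode", ""))
                for r in epi["residues"]
            )
            seed = ResidueID(epi["seed"]["chain"], epi["seed"]["seqnum"],
                             epi["seed"].get("icode", ""))
            ranked.append((Patch(seed, members), float(epi["score"])))
        return cls(ranked)

    def to_tsv(self, antigen: StructureUnit | None = None) -> str:
        lines = ["rank\tscore\tchain\tseqnum\ticode\taa_type"]
        for rank, (patch, score) in enumerate(self.ranked, start=1):
            for rid in sorted(patch.members):
                aa = antigen[rid].aa_type if antigen is not None and rid in antigen else "UNK"
                lines.append(f"{rank}\t{score:.6g}\t{rid.chain}\t{rid.seqnum}\t{rid.icode}\t{aa}")
        return "\n".join(lines) + "\n"


def compatible(n1: ContactNode, n2: ContactNode, ab_unit: StructureUnit,
               ag_unit: StructureUnit, compat_cutoff: float = 1.0,
               allow_shared: bool = False) -> bool:
    """Can the two candidate contacts exist simultaneously in a rigid match?

    True iff |d_ab(r_ab1, r_ab2) − d_ag(r_ag1, r_ag2)| < cutoff, with both
    intramolecular distances taken between representative (Cα) points.  Two
    nodes sharing an antibody or antigen residue are incompatible unless
    ``allow_shared`` (one residue cannot realize two simultaneous contacts).
    """
    if not allow_shared and (n1.ab_residue == n2.ab_residue
                             or n1.ag_residue == n2.ag_residue):
        return False
    d_ab = representative_distance(ab_unit[n1.ab_residue], ab_unit[n2.ab_residue])
    d_ag = representative_distance(ag_unit[n1.ag_residue], ag_unit[n2.ag_residue])
    return abs(d_ab - d_ag) < compat_cutoff


def build_contact_graph(patch: Patch, site: BindingSite, ab_unit: StructureUnit,
                        ag_unit: StructureUnit,
                        params: ParameterSet | None = None,
                        allow_shared: bool = False) -> ContactGraph:
    """Graph over Epi × Ab with edges for geometrically compatible contact pairs."""
    params = params or ParameterSet()
    if not patch.members or not site.members:
        raise ValueError("patch and binding site must be non-empty")
    ag_ids = sorted(patch.members)
    ab_ids = sorted(site.members)
    nodes = [
        ContactNode(ab_id, ag_id, ab_unit[ab_id].aa_type, ag_unit[ag_id].aa_type)
        for ag_id in ag_ids
        for ab_id in ab_ids
    ]
    # vectorized edge test on the two intramolecular distance matrices
    ab_pts = np.array([ab_unit[i].representative_point() for i in ab_ids])
    ag_pts = np.array([ag_unit[i].representative_point() for i in ag_ids])
    d_ab = np.linalg.norm(ab_pts[:, None] - ab_pts[None, :], axis=-1)
    d_ag = np.linalg.norm(ag_pts[:, None] - ag_pts[None, :], axis=-1)
    n_ab, n_ag = len(ab_ids), len(ag_ids)
    # node k = (ab index k % n_ab, ag index k // n_ab)
    ab_idx = np.tile(np.arange(n_ab), n_ag)
    ag_idx = np.repeat(np.arange(n_ag), n_ab)
    diff = np.abs(d_ab[ab_idx[:, None], ab_idx[None, :]]
                  - d_ag[ag_idx[:, None], ag_idx[None, :]])
    adj = diff < params.compat_cutoff
    if not allow_shared:
        adj &= ab_idx[:, None] != ab_idx[None, :]
        adj &= ag_idx[:, None] != ag_idx[None, :]
    np.fill_diagonal(adj, False)
    return ContactGraph(nodes, adj)


def score_patch(graph: ContactGraph, ps: PrecisionScoreMatrix) -> float:
    """Σ over nodes of degree × precision score of the node's amino-acid pair."""
    deg = graph.degree()
    total = 0.0
    for node, d in zip(graph.nodes, deg):
        total += float(d) * ps.lookup(node.ab_type, node.ag_type)
    return total


def patch_overlap_fraction(higher: Patch, lower: Patch) -> float:
    """Shared residues as a fraction of the higher-scoring patch's size."""
    if not higher.members:
        raise ValueError("higher-scoring patch is empty")
    return len(higher.members & lower.members) / len(higher.members)


def select_top_patches(scored: list[tuple[Patch, float]],
                       overlap_threshold: float = 0.3,
                       max_epitopes: int = 3) -> list[tuple[Patch, float]]:
    """Greedy selection down the score-sorted list.

    A patch is discarded iff it shares strictly more than the threshold
    fraction of some already-selected (higher-scoring) patch's residues.
    Ties in score are broken lexicographically on the seed residue ID.
    """
    order = sorted(scored, key=lambda t: (-t[1], t[0].seed))
    selected: list[tuple[Patch, float]] = []
    for patch, score in order:
        if any(patch_overlap_fraction(sel, patch) > overlap_threshold
               for sel, _ in selected):
            continue
        selected.append((patch, score))
        if len(selected) >= max_epitopes:
            break
    return selected


def predict_epitopes(antigen: StructureUnit, ab_unit: StructureUnit,
                     site: BindingSite, ps: PrecisionScoreMatrix,
                     params: ParameterSet | None = None,
                     surface: set[ResidueID] | None = None,
                     allow_shared: bool = False) -> EpitopePrediction:
    """Full prediction: patches → contact graphs → scores → top non-overlapping.

    ``surface`` may be supplied to skip the accessibility computation
    (e.g. when reusing a precomputed surface map).
    """
    params = params or ParameterSet()
    if surface is None:
        smap = compute_relative_accessibility(antigen,
                                              threshold=params.surface_threshold)
        surface = surface_residues(smap)
    if not surface:
        warnings.warn("antigen has no surface residues; empty prediction",
                      stacklevel=2)
        return EpitopePrediction([])
    patches = enumerate_patches(antigen, surface, params)
    scored = [
        (p, score_patch(build_contact_graph(p, site, ab_unit, antigen, params,
                                            allow_shared=allow_shared), ps))
        for p in patches
    ]
    return EpitopePrediction(
        select_top_patches(scored, params.overlap_threshold, params.max_epitopes)
    )
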