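"""Rescoring of rigid-body docking decoys against predicted epitopes.

Each decoy pose is scored against each of the predicted epitopes by summing,
over all (binding-site residue, epitope residue) pairs whose heavy atoms come
within the contact cutoff in that pose, the Precision Score of the pair's
amino-acid types:

    score(d, Ab, Epi) = Σ_{r_ab ∈ Ab, r_ag ∈ Epi, dist(r_ab, r_ag) < 4.5 Å}
                        PS(T_ab, T_ag).

The pose keeps the highest of its per-epitope scores, and the top-N decoys
(N = 30 for ZDOCK-style input, 20 for ClusPro-style) are reordered by that
score, ties broken by the original docking rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import EpitopePrediction
from .patches import Patch
from .potential import PrecisionScoreMatrix
from .structure import (
    BindingSite,
    ParameterSet,
    PDBParseError,
    ResidueID,
    StructureUnit,
    parse_pdb_models,
    read_pdb,
    _convert_gemmi_model,
)

__all__ = ["Pose", "RescoredList", "score_pose", "rescore", "read_decoys"]


@dataclass
class Pose:
    """One antibody–antigen orientation: native complex or docking decoy."""

    ab: StructureUnit
    ag: StructureUnit
    source_rank: int = 1
    source_score: float | None = None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Pose":
        """Rigidly transform BOTH units (the pose's geometry is unchanged)."""
        return Pose(self.ab.transformed(rotation, translation),
                    self.ag.transformed(rotation, translation),
                    self.source_rank, self.source_score)


@dataclass
class RescoredList:
    """Decoys reordered by their rescored value, best first."""

    entries: list[tuple[Pose, float, int]]  # (pose, score, best epitope index)

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("rescored entries must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.entries)

    def poses(self) -> list[Pose]:
        return [p for p, _, _ in self.entries]

    def to_tsv(self) -> str:
        lines = ["new_rank\tsource_rank\tscore\tbest_epitope"]
        for new_rank, (pose, score, epi) in enumerate(self.entries, start=1):
            lines.append(f"{new_rank}\t{pose.source_rank}\t{score:.6g}\t{epi + 1}")
        return "\n".join(lines) + "\n"


def score_pose(pose: Pose, site: BindingSite, epi: Patch,
               ps: PrecisionScoreMatrix, contact_cutoff: float = 4.5) -> float:
    """Sum of Precision Scores over epitope-restricted contacts in the pose."""
    ab_res = [pose.ab[rid] for rid in sorted(site.members) if rid in pose.ab]
    ag_res = [pose.ag[rid] for rid in sorted(epi.members) if rid in pose.ag]
    if not ab_res or not ag_res:
        return 0.0
    ab_coords, ab_owner = _stack(ab_res)
    ag_coords, ag_owner = _stack(ag_res)
    tree = cKDTree(ag_coords)
    seen: set[tuple[int, int]] = set()
    total = 0.0
    for ab_idx, hits in enumerate(tree.query_ball_point(ab_coords, contact_cutoff)):
        for ag_idx in hits:
            key = (int(ab_owner[ab_idx]), int(ag_owner[ag_idx]))
            if key in seen:
                continue
            if np.linalg.norm(ab_coords[ab_idx] - ag_coords[ag_idx]) < contact_cutoff:
                seen.add(key)
                total += ps.lookup(ab_res[key[0]].aa_type, ag_res[key[1]].aa_type)
    return total


def _stack(residues) -> tuple[np.ndarray, np.ndarray]:
    coords, owner = [], []
    for idx, res in enumerate(residues):
        c = res.heavy_coords()
        coords.append(c)
        owner.extend([idx] * len(c))
    return np.vstack(coords), np.array(owner)


def rescore(poses: Sequence[Pose], site: BindingSite,
            prediction: EpitopePrediction, ps: PrecisionScoreMatrix,
            params: ParameterSet | None = None) -> RescoredList:
    """Rescore the top-N decoys and reorder by best per-epitope score.

    Poses must arrive ordered by source rank; only the first
    ``params.rescore_top_n`` are rescored.  Each pose's final score is the
    maximum over the predicted epitopes; ties keep the original docking order.
    """
    params = params or ParameterSet()
    if not poses:
        raise ValueError("no poses to rescore")
    if len(prediction) == 0:
        raise ValueError("prediction contains no epitopes")
    subset = sorted(poses, key=lambda p: p.source_rank)[: params.rescore_top_n]
    scored = []
    for pose in subset:
        per_epi = [
            score_pose(pose, site, patch, ps, params.contact_cutoff)
            for patch in prediction.patches()
        ]
        best = int(np.argmax(per_epi))
        scored.append((pose, float(per_epi[best]), best))
    scored.sort(key=lambda t: (-t[1], t[0].source_rank))
    return RescoredList(scored)


def read_decoys(source: str | Path, antibody_chains: Sequence[str] | str,
                antigen_chains: Sequence[str] | str) -> list[Pose]:
    """Load a decoy set from a multi-model PDB file or a directory of PDBs.

    Source rank follows MODEL numbering order (multi-model file) or
    lexicographic file order (directory).  All poses must share an identical
    residue complement.
    """
    source = Path(source)
    units: list[tuple[str, StructureUnit, StructureUnit]] = []
    if source.is_dir():
        files = sorted(p for p in source.iterdir() if p.suffix.lower() == ".pdb")
        if not files:
            raise PDBParseError(f"no .pdb files in directory {source}")
        for f in files:
            text = f.read_text()
            units.append((f.name,
                          read_pdb(text, antibody_chains, "antibody"),
                          read_pdb(text, antigen_chains, "antigen")))
    else:
        st = parse_pdb_models(source.read_text())
        if isinstance(antibody_chains, str):
            antibody_chains = [c.strip() for c in antibody_chains.split(",")]
        if isinstance(antigen_chains, str):
            antigen_chains = [c.strip() for c in antigen_chains.split(",")]
        for model in st:
            units.append((f"model {model.num}",
                          _convert_gemmi_model(model, antibody_chains, "antibody"),
                          _convert_gemmi_model(model, antigen_chains, "antigen")))
    ref_ab = [(r.id, r.aa_type) for r in units[0][1].residues]
    ref_ag = [(r.id, r.aa_type) for r in units[0][2].residues]
    poses = []
    for rank, (label, ab, ag) in enumerate(units, start=1):
        if [(r.id, r.aa_type) for r in ab.residues] != ref_ab \
                or [(r.id, r.aa_type) for r in ag.residues] != ref_ag:
            raise PDBParseError(f"inconsistent residue set in {label}")
        poses.append(Pose(ab, ag, source_rank=rank))
    return poses
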