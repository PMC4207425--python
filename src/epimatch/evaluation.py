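"""Evaluation machinery: native epitopes, residue-level metrics, interface
RMSD, ranking comparison, randomized baseline and specificity cross-tables.

The residue-level metrics follow the usual confusion-table definitions over
the antigen surface: precision = TP/(TP+FP), recall = TP/(TP+FN), plus the
Matthews correlation coefficient.  Docking decoys are judged by the CAPRI
interface RMSD: the interface regions are defined on the native complex
(residues within 10 Å of the binding partner), optimally superimposed with
the Kabsch algorithm, and a decoy with I_rmsd < 10 Å counts as
close-to-native.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import EpitopePrediction, select_top_patches
from .docksorter import Pose, RescoredList
from .patches import Patch, enumerate_patches
from .potential import PrecisionScoreMatrix, contact_pairs
from .sasa import SurfaceMap, compute_relative_accessibility, surface_residues
from .structure import (
    BindingSite,
    ParameterSet,
    Residue,
    ResidueID,
    StructureUnit,
    heavy_atom_min_distance,
)

__all__ = [
    "ConfusionCounts",
    "EvalMetrics",
    "IrmsdReport",
    "native_epitope",
    "confusion_metrics",
    "interface_residues",
    "irmsd",
    "is_close_to_native",
    "compare_rankings",
    "randomized_baseline",
    "specificity_matrix",
]

_BACKBONE = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    precision: float
    recall: float
    mcc: float
    counts: ConfusionCounts | None = None


@dataclass(frozen=True)
class IrmsdReport:
    interface_ab: frozenset[ResidueID]
    interface_ag: frozenset[ResidueID]
    value: float


def native_epitope(native: Pose, surface: SurfaceMap | set[ResidueID] | None = None,
                   params: ParameterSet | None = None,
                   surface_filter: bool = True) -> set[ResidueID]:
    """Antigen residues defining the true epitope of a native complex.

    The epitope is the set of surface antigen residues whose heavy atoms come
    within the contact cutoff of any antibody heavy atom.  With
    ``surface_filter=False`` the unfiltered contact variant (no accessibility
    requirement) is returned instead.
    """
    params = params or ParameterSet()
    site = BindingSite(native.ab, frozenset(native.ab.residue_ids))
    contacts = {ag for _, ag in contact_pairs(native, site, params.contact_cutoff)}
    if not surface_filter:
        return contacts
    if surface is None:
        surface = compute_relative_accessibility(
            native.ag, threshold=params.surface_threshold)
    if isinstance(surface, SurfaceMap):
        surface = surface_residues(surface)
    return contacts & surface


def confusion_metrics(predicted: set[ResidueID], truth: set[ResidueID],
                      universe: set[ResidueID]) -> EvalMetrics:
    """Precision, recall and MCC of a predicted residue set over a universe.

    Undefined ratios (empty denominators) evaluate to 0, so a failed
    prediction reports a 0-row rather than an error.
    """
    if not universe:
        raise ValueError("evaluation universe is empty")
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth sets must lie within the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    counts = ConfusionCounts(tp, fp, fn, tn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return EvalMetrics(precision, recall, mcc, counts)


def interface_residues(native: Pose, interface_cutoff: float = 10.0
                       ) -> tuple[set[ResidueID], set[ResidueID]]:
    """Interface regions of the native complex (residues within the cutoff
    of any residue of the binding partner, heavy-atom minimum distance,
    strict inequality)."""
    ab_set: set[ResidueID] = set()
    ag_set: set[ResidueID] = set()
    for ra in native.ab.residues:
        for rg in native.ag.residues:
            if heavy_atom_min_distance(ra, rg) < interface_cutoff:
                ab_set.add(ra.id)
                ag_set.add(rg.id)
    return ab_set, ag_set


def _interface_coords(pose: Pose, ab_ids: Sequence[ResidueID],
                      ag_ids: Sequence[ResidueID], atom_set: str) -> np.ndarray:
    coords = []
    for unit, ids in ((pose.ab, ab_ids), (pose.ag, ag_ids)):
        for rid in ids:
            res = unit[rid]
            if atom_set == "backbone":
                atoms = [a for a in res.heavy_atoms if a.name in _BACKBONE]
            elif atom_set == "calpha":
                atoms = [a for a in res.heavy_atoms if a.name == "CA"]
            elif atom_set == "all-heavy":
                atoms = res.heavy_atoms
            else:
                raise ValueError(f"unknown atom set {atom_set!r}")
            coords.extend(a.position for a in atoms)
    return np.array(coords)


def irmsd(decoy: Pose, native: Pose, atom_set: str = "backbone",
          interface_cutoff: float = 10.0) -> IrmsdReport:
    """Interface RMSD after optimal (Kabsch) superposition.

    The interface is defined on the NATIVE complex; the pooled interface
    atoms of decoy and native are superimposed by least squares and the RMSD
    of the fit is reported.  The value is invariant to rigid transforms of
    either pose.  The atom set defaults to the backbone (N, Cα, C, O);
    atoms absent from a residue are simply skipped, so Cα-only models
    degrade gracefully.
    """
    ab_ids, ag_ids = interface_residues(native, interface_cutoff)
    if not ab_ids and not ag_ids:
        raise ValueError("native interface is empty at the given cutoff")
    ab_ids, ag_ids = sorted(ab_ids), sorted(ag_ids)
    ref = _interface_coords(native, ab_ids, ag_ids, atom_set)
    mob = _interface_coords(decoy, ab_ids, ag_ids, atom_set)
    if ref.shape != mob.shape or len(ref) == 0:
        raise ValueError("decoy and native interface atom sets do not match")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    value = float(np.sqrt(((rot.apply(mob_c) - ref_c) ** 2).sum() / len(ref)))
    return IrmsdReport(frozenset(ab_ids), frozenset(ag_ids), value)


def is_close_to_native(report: IrmsdReport, near_native_cutoff: float = 10.0) -> bool:
    """Strict: I_rmsd < cutoff."""
    return report.value < near_native_cutoff


def compare_rankings(raw: Sequence[Pose], rescored: RescoredList, native: Pose,
                     tops: Iterable[int] = (1, 5, 10),
                     params: ParameterSet | None = None,
                     irmsd_values: Mapping[int, float] | None = None
                     ) -> dict[int, dict]:
    """Count close-to-native decoys in the top-k of both orderings.

    Returns, per k: the raw and rescored counts and an outcome among
    ``improved`` / ``worse`` / ``unchanged`` / ``no-suitable-decoy`` (the
    last iff both counts are 0).  ``irmsd_values`` may map source ranks to
    precomputed I_rmsd values to avoid recomputation.
    """
    params = params or ParameterSet()
    given = dict(irmsd_values or {})
    cache: dict[int, float] = {}  # keyed by object identity, not rank

    def close(pose: Pose) -> bool:
        key = id(pose)
        if key not in cache:
            if pose.source_rank in given:
                cache[key] = given[pose.source_rank]
            else:
                cache[key] = irmsd(pose, native,
                                   interface_cutoff=params.interface_cutoff).value
        return cache[key] < params.near_native_cutoff

    raw_sorted = sorted(raw, key=lambda p: p.source_rank)
    res_poses = rescored.poses()
    out: dict[int, dict] = {}
    for k in tops:
        raw_count = sum(close(p) for p in raw_sorted[:k])
        res_count = sum(close(p) for p in res_poses[:k])
        if raw_count == 0 and res_count == 0:
            outcome = "no-suitable-decoy"
        elif res_count > raw_count:
            outcome = "improved"
        elif res_count < raw_count:
            outcome = "worse"
        else:
            outcome = "unchanged"
        out[k] = {"raw": raw_count, "rescored": res_count, "outcome": outcome}
    return out


def randomized_baseline(antigen: StructureUnit, ab_unit: StructureUnit,
                        site: BindingSite, truth: set[ResidueID],
                        params: ParameterSet | None = None,
                        n_runs: int = 500, seed: int = 0,
                        surface: set[ResidueID] | None = None
                        ) -> tuple[float, float]:
    """Mean precision/recall of the top patch under randomized patch scores.

    Candidate patches are enumerated once; each run draws an independent
    uniform(0, 1) score per patch, applies the same ranking and overlap
    filtering as the real predictor and evaluates the top patch against the
    native epitope.  Returns run-averaged (precision, recall).
    """
    params = params or ParameterSet()
    if surface is None:
        smap = compute_relative_accessibility(antigen,
                                              threshold=params.surface_threshold)
        surface = surface_residues(smap)
    patches = enumerate_patches(antigen, surface, params)
    universe = set(surface)
    rng = np.random.default_rng(seed)
    precisions, recalls = [], []
    for _ in range(n_runs):
        scores = rng.uniform(size=len(patches))
        selected = select_top_patches(list(zip(patches, scores)),
                                      params.overlap_threshold,
                                      params.max_epitopes)
        top = selected[0][0]
        m = confusion_metrics(set(top.members) & universe, truth & universe, universe)
        precisions.append(m.precision)
        recalls.append(m.recall)
    return float(np.mean(precisions)), float(np.mean(recalls))


def specificity_matrix(predictions: Mapping[str, EpitopePrediction],
                       truths: Mapping[str, set[ResidueID]],
                       universe: set[ResidueID]) -> pd.DataFrame:
    """MCC cross-table: rows = antibody predicted for, columns = antibody
    whose true epitope the top prediction is evaluated against.

    All antibodies must target the same antigen (shared residue universe)."""
    names = list(predictions)
    if set(truths) != set(names):
        raise ValueError("predictions and truths must cover the same antibodies")
    table = pd.DataFrame(0.0, index=names, columns=names)
    for row in names:
        pred = predictions[row]
        top = set(pred.patches()[0].members) if len(pred) else set()
        if not top <= universe:
            raise ValueError(f"prediction for {row} outside the shared antigen universe")
        for col in names:
            table.loc[row, col] = confusion_metrics(top, truths[col] & universe,
                                                    universe).mcc
    return table
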