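"""The asymmetric antibody–antigen Precision Score and its estimation.

PS(T_ab, T_ag) estimates the probability that a rigid-body docking contact
between an antibody residue of type T_ab and an antigen residue of type T_ag
is correct, i.e. reproduces a contact of the native complex.  It is estimated
by tallying, over the top-ranked decoys of a set of training complexes, how
often each observed contact pair coincides (by residue identity) with a
native contact, with a Laplace-style pseudocount so unobserved cells default
to an uninformative 0.5.

The matrix is asymmetric: the two roles are not interchangeable
(PS(G, S) — glycine on the antibody against serine on the antigen — is
estimated independently of PS(S, G)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import (
    AA1_TO_3,
    AA3_TO_1,
    CANONICAL_AA1,
    BindingSite,
    ResidueID,
    StructureUnit,
)

__all__ = [
    "PrecisionScoreMatrix",
    "TrainingCase",
    "contact_pairs",
    "estimate_precision_matrix",
    "load_precision_matrix",
    "save_precision_matrix",
    "MatrixFormatError",
]

_AA_LIST = list(CANONICAL_AA1)


class MatrixFormatError(ValueError):
    """Raised when a precision-score table is malformed."""


@dataclass
class PrecisionScoreMatrix:
    """20×20 map (antibody type, antigen type) → score in [0, 1].

    ``values`` is a DataFrame with antibody one-letter codes as the row index
    and antigen codes as columns.  ``counts`` optionally carries the
    (correct, total) tallies behind each estimated cell.
    """

    values: pd.DataFrame
    counts: pd.DataFrame | None = None  # cells hold (correct, total) tuples

    def __post_init__(self) -> None:
        v = self.values.reindex(index=_AA_LIST, columns=_AA_LIST)
        if v.isna().any().any():
            missing = sorted(
                set(_AA_LIST) - set(self.values.index)
            ) + sorted(set(_AA_LIST) - set(self.values.columns))
            raise MatrixFormatError(f"matrix missing amino acids: {missing}")
        bad = (v < 0) | (v > 1)
        if bad.any().any():
            r = v.index[bad.any(axis=1)][0]
            c = v.columns[bad.loc[r]][0]
            raise MatrixFormatError(f"value outside [0,1] at ({r},{c}): {v.loc[r, c]}")
        self.values = v.astype(float)

    @classmethod
    def uniform(cls, value: float = 1.0) -> "PrecisionScoreMatrix":
        return cls(pd.DataFrame(value, index=_AA_LIST, columns=_AA_LIST))

    @classmethod
    def from_dict(cls, entries: Mapping[tuple[str, str], float],
                  default: float = 0.0) -> "PrecisionScoreMatrix":
        """Build from {(ab_code, ag_code): value}; codes may be 1- or 3-letter."""
        df = pd.DataFrame(default, index=_AA_LIST, columns=_AA_LIST)
        for (ab, ag), val in entries.items():
            df.loc[_one(ab), _one(ag)] = val
        return cls(df)

    def lookup(self, ab_type: str, ag_type: str) -> float:
        """PS for (antibody type, antigen type); accepts 1- or 3-letter codes."""
        ab, ag = _one(ab_type), _one(ag_type)
        try:
            return float(self.values.at[ab, ag])
        except KeyError as exc:
            raise MatrixFormatError(f"no precision score for pair ({ab_type}, {ag_type})") from exc

    def scaled(self, c: float) -> "PrecisionScoreMatrix":
        return PrecisionScoreMatrix(self.values * c)


def _one(code: str) -> str:
    code = code.upper()
    if len(code) == 3:
        code = AA3_TO_1.get(code, "X")
    if code not in _AA_LIST:
        raise MatrixFormatError(f"unknown amino-acid code {code!r}")
    return code


@dataclass
class TrainingCase:
    """One training complex: the native pose and its docking-ranked decoys."""

    native: "Pose"
    decoys: list["Pose"]
    site: BindingSite | None = None

    def __post_init__(self) -> None:
        if not self.decoys:
            raise ValueError("training case has no decoys")


def contact_pairs(pose: "Pose", site: BindingSite,
                  contact_cutoff: float = 4.5) -> set[tuple[ResidueID, ResidueID]]:
    """All (antibody-site residue, antigen residue) pairs in heavy-atom contact.

    The contact predicate is strict: minimum heavy-atom distance < cutoff.
    """
    site_res = [pose.ab[rid] for rid in sorted(site.members) if rid in pose.ab]
    ab_coords, ab_owner = _stack(site_res)
    ag_coords, ag_owner = _stack(pose.ag.residues)
    if len(ab_coords) == 0 or len(ag_coords) == 0:
        return set()
    tree = cKDTree(ag_coords)
    pairs: set[tuple[ResidueID, ResidueID]] = set()
    hits = tree.query_ball_point(ab_coords, contact_cutoff)
    for ab_idx, ag_hits in enumerate(hits):
        for ag_idx in ag_hits:
            d = np.linalg.norm(ab_coords[ab_idx] - ag_coords[ag_idx])
            if d < contact_cutoff:
                pairs.add((site_res[ab_owner[ab_idx]].id,
                           pose.ag.residues[ag_owner[ag_idx]].id))
    return pairs


def _stack(residues) -> tuple[np.ndarray, np.ndarray]:
    coords, owner = [], []
    for idx, res in enumerate(residues):
        c = res.heavy_coords()
        coords.append(c)
        owner.extend([idx] * len(c))
    if not coords:
        return np.empty((0, 3)), np.empty(0, int)
    return np.vstack(coords), np.array(owner)


def estimate_precision_matrix(cases: Iterable[TrainingCase], top_m: int = 200,
                              pseudocount: float = 1.0,
                              contact_cutoff: float = 4.5,
                              site: BindingSite | None = None) -> PrecisionScoreMatrix:
    """Estimate PS by pooled tallies over the top-``top_m`` decoys of each case.

    Every contact pair observed in a decoy counts one toward its
    (T_ab, T_ag) cell's total, and one toward its correct count iff the
    identical residue pair (by ID) is a contact of that case's native pose.
    PS = (correct + ε) / (total + 2ε); with ε = 0 an unobserved cell is 0.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("cannot estimate a precision matrix from zero cases")
    correct = pd.DataFrame(0.0, index=_AA_LIST, columns=_AA_LIST)
    total = pd.DataFrame(0.0, index=_AA_LIST, columns=_AA_LIST)
    for case in cases:
        case_site = case.site or site
        if case_site is None:
            raise ValueError("training case needs a binding site")
        native_contacts = contact_pairs(case.native, case_site, contact_cutoff)
        for decoy in case.decoys[:top_m]:
            for ab_id, ag_id in contact_pairs(decoy, case_site, contact_cutoff):
                tab = _one(decoy.ab[ab_id].aa_type)
                tag = _one(decoy.ag[ag_id].aa_type)
                total.loc[tab, tag] += 1
                if (ab_id, ag_id) in native_contacts:
                    correct.loc[tab, tag] += 1
    eps = float(pseudocount)
    denom = total + 2 * eps
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = (correct + eps) / denom
    ps = ps.fillna(0.0)  # only reachable with eps == 0 and total == 0
    counts = pd.DataFrame(
        [[(correct.iat[i, j], total.iat[i, j]) for j in range(20)] for i in range(20)],
        index=_AA_LIST, columns=_AA_LIST,
    )
    return PrecisionScoreMatrix(ps, counts=counts)


def save_precision_matrix(ps: PrecisionScoreMatrix) -> str:
    """Serialize as a TSV: rows = antibody codes, columns = antigen codes."""
    buf = io.StringIO()
    ps.values.to_csv(buf, sep="\t", index_label="ab\\ag", float_format="%.6g")
    return buf.getvalue()


def load_precision_matrix(table: str) -> PrecisionScoreMatrix:
    """Parse a 20×20 TSV with one-letter header row and column."""
    try:
        df = pd.read_csv(io.StringIO(table), sep="\t", index_col=0)
    except Exception as exc:
        raise MatrixFormatError(f"cannot parse precision-score table: {exc}") from exc
    df.index = [str(i).upper() for i in df.index]
    df.columns = [str(c).upper() for c in df.columns]
    if len(set(df.index)) != len(df.index) or len(set(df.columns)) != len(df.columns):
        raise MatrixFormatError("duplicate amino-acid code in header")
    return PrecisionScoreMatrix(df)
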