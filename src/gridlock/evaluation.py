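"""Hit evaluation: interface Cα RMSD and success-rate / hit-count metrics.

A predicted pose is a *hit* when its interface Cα RMSD from the bound
reference complex is at most 2.5 Å.  The interface is defined on the
reference complex: residues of either molecule with any atom within a
10 Å heavy-atom cutoff of the partner (both defaults configurable).  The
RMSD spans the interface Cα atoms of *both* molecules, computed with the
two receptor frames superposed and no further fitting — consistent with
pose reconstruction, which keeps the receptor fixed in its input frame, so
that a perfect receptor contributes zero and all deviation comes from the
ligand placement.

Aggregates over a case set follow the usual benchmark conventions:
*success rate* is the fraction of cases with at least one hit among each
case's top ``N`` ranked predictions, and *hit count* is the mean number of
hits among the top ``N``; both are non-decreasing in ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structures import Molecule, interface_residues

DEFAULT_HIT_THRESHOLD = 2.5  # Å
DEFAULT_INTERFACE_CUTOFF = 10.0  # Å

__all__ = [
    "HitEvaluation",
    "DEFAULT_HIT_THRESHOLD",
    "DEFAULT_INTERFACE_CUTOFF",
    "interface_calpha_rmsd",
    "success_and_hits",
]


@dataclass(frozen=True)
class HitEvaluation:
    rmsd: float
    is_hit: bool
    threshold: float = DEFAULT_HIT_THRESHOLD

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.is_hit != (self.rmsd <= self.threshold):
            raise ValueError("is_hit must equal (rmsd <= threshold)")

    @classmethod
    def from_rmsd(cls, rmsd: float, threshold: float = DEFAULT_HIT_THRESHOLD) -> "HitEvaluation":
        return cls(rmsd=float(rmsd), is_hit=bool(rmsd <= threshold), threshold=threshold)


def _calpha_map(molecule: Molecule) -> dict[tuple[str, int], np.ndarray]:
    out: dict[tuple[str, int], np.ndarray] = {}
    for a in molecule.atoms:
        if a.name.strip().upper() == "CA" and a.residue_id not in out:
            out[a.residue_id] = a.position
    return out


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``moving`` onto ``target``."""
    cm_m = moving.mean(axis=0)
    cm_t = target.mean(axis=0)
    h = (moving - cm_m).T @ (target - cm_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cm_m, cm_t


def interface_calpha_rmsd(
    prediction: tuple[Molecule, Molecule],
    reference: tuple[Molecule, Molecule],
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> float:
    """Interface Cα RMSD of a predicted complex against the bound reference.

    The reference complex defines the interface residue sets; Cα atoms are
    matched by (chain, residue number).  If the predicted receptor is not
    already in the reference receptor's frame, it is rigidly superposed on
    the reference receptor Cα trace first; the RMSD itself involves no
    fitting.

    Raises ``ValueError`` if the reference interface is empty or an
    interface residue lacks a Cα in either structure.
    """
    pred_rec, pred_lig = prediction
    ref_rec, ref_lig = reference
    iface_rec, iface_lig = interface_residues(ref_rec, ref_lig, cutoff)
    if not iface_rec and not iface_lig:
        raise ValueError("reference complex has an empty interface at this cutoff")

    maps = {
        "pred_rec": _calpha_map(pred_rec),
        "pred_lig": _calpha_map(pred_lig),
        "ref_rec": _calpha_map(ref_rec),
        "ref_lig": _calpha_map(ref_lig),
    }

    ref_pts, pred_pts = [], []
    for rid in sorted(iface_rec):
        if rid not in maps["ref_rec"] or rid not in maps["pred_rec"]:
            raise ValueError(f"interface residue {rid} lacks a Cα atom")
        ref_pts.append(maps["ref_rec"][rid])
        pred_pts.append(maps["pred_rec"][rid])
    n_rec_iface = len(ref_pts)
    for rid in sorted(iface_lig):
        if rid not in maps["ref_lig"] or rid not in maps["pred_lig"]:
            raise ValueError(f"interface residue {rid} lacks a Cα atom")
        ref_pts.append(maps["ref_lig"][rid])
        pred_pts.append(maps["pred_lig"][rid])
    if not ref_pts:
        raise ValueError("no interface Cα atoms to compare")
    ref_arr = np.asarray(ref_pts)
    pred_arr = np.asarray(pred_pts)

    # Superpose the receptor frames (full receptor Cα trace) if they differ.
    rec_ids = sorted(set(maps["ref_rec"]) & set(maps["pred_rec"]))
    ref_rec_arr = np.asarray([maps["ref_rec"][r] for r in rec_ids])
    pred_rec_arr = np.asarray([maps["pred_rec"][r] for r in rec_ids])
    if not np.allclose(ref_rec_arr, pred_rec_arr, atol=1e-9):
        rot, cm_m, cm_t = _kabsch(pred_rec_arr, ref_rec_arr)
        pred_arr = (pred_arr - cm_m) @ rot.T + cm_t

    delta = pred_arr - ref_arr
    return float(np.sqrt((delta**2).sum(axis=1).mean()))


def success_and_hits(
    per_case_hit_lists: Sequence[Sequence[bool]], n: int
) -> tuple[float, float]:
    """Success rate and mean hit count over the top ``n`` ranked predictions.

    Each inner list holds the per-prediction hit flags of one case, in rank
    order.  Raises ``ValueError`` if ``n`` exceeds any case's list length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not per_case_hit_lists:
        raise ValueError("need at least one case")
    for i, hits in enumerate(per_case_hit_lists):
        if len(hits) < n:
            raise ValueError(f"case {i} has only {len(hits)} predictions (< {n})")
    tops = [list(hits[:n]) for hits in per_case_hit_lists]
    success_rate = float(np.mean([any(t) for t in tops]))
    hit_count = float(np.mean([sum(bool(b) for b in t) for t in tops]))
    return success_rate, hit_count
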