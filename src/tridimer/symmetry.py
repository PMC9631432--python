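"""Interface classification by relative rotation between chain pairs.

In a T=3 capsid, chemically identical chains meet across exact icosahedral
axes (C2, C3, C5) and across approximate local ("quasi") axes (QC2, QC3,
QC6).  A contacting chain pair is assigned to an interface class by the
angle of the rigid rotation that superposes one chain onto the other:

=================  ==============  ============
rotation angle     axis            class
=================  ==============  ============
~180 deg           C2 / QC2        dimerization
~120 deg           QC3             trimerization
~72 deg            C5              pentamerization
~60 deg            QC6             hexamerization
=================  ==============  ============

The superposition uses CA atoms of residues shared by author numbering
(conformers of one coat protein share numbering; no sequence alignment).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .structures import ChainModel

__all__ = ["RelativeTransform", "relative_transform", "classify_interface",
           "CANONICAL_ANGLES", "census"]

CANONICAL_ANGLES = {
    "dimerization": 180.0,
    "trimerization": 120.0,
    "pentamerization": 72.0,
    "hexamerization": 60.0,
}

MIN_SHARED_RESIDUES = 30


@dataclass(frozen=True)
class RelativeTransform:
    rotation_angle: float        # degrees, in [0, 180]
    rotation_axis: np.ndarray    # unit vector
    screw_translation: float     # Angstrom along the axis
    rmsd_after_superposition: float  # Angstrom
    n_matched: int


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ p + t ~ q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _axis_angle(R: np.ndarray) -> tuple[float, np.ndarray]:
    cos_t = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_t))
    # antisymmetric part gives the axis except near 0/180 degrees
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(w)
    if s > 1e-8:
        axis = w / s
    else:
        # near 0 or 180: axis from the eigenvector of eigenvalue +1
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
        axis = axis / np.linalg.norm(axis)
    return float(angle), axis


def relative_transform(chain_x: ChainModel, chain_y: ChainModel) -> RelativeTransform:
    """Optimal rigid superposition of chain_x onto chain_y (matched CAs).

    Raises ``ValueError`` when fewer than 30 residues are shared.
    """
    mx, my = chain_x.ca_map(), chain_y.ca_map()
    shared = sorted(set(mx) & set(my))
    if len(shared) < MIN_SHARED_RESIDUES:
        raise ValueError(
            f"chains {chain_x.chain_id}/{chain_y.chain_id} share only "
            f"{len(shared)} residues (< {MIN_SHARED_RESIDUES})")
    P = np.array([mx[i] for i in shared])
    Q = np.array([my[i] for i in shared])
    R, t = _kabsch(P, Q)
    angle, axis = _axis_angle(R)
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    screw = float(np.dot(t, axis))
    return RelativeTransform(angle, axis, screw, rmsd, len(shared))


def classify_interface(t: RelativeTransform,
                       conformers: tuple[str, str] | None = None,
                       angle_tol: float = 12.0) -> str:
    """Interface class of a contacting pair from its relative rotation.

    The pair is assigned to the canonical angle (180, 120, 72, 60) nearest
    its measured rotation angle, provided the deviation is within
    ``angle_tol``; otherwise ``unclassified``.  Nearest-angle assignment
    matters because the 60 and 72 degree bands touch at the default
    tolerance.
    """
    best = min(CANONICAL_ANGLES.items(), key=lambda kv: abs(t.rotation_angle - kv[1]))
    if abs(t.rotation_angle - best[1]) <= angle_tol:
        return best[0]
    return "unclassified"


def census(pairs: list[tuple[ChainModel, ChainModel]],
           angle_tol: float = 12.0) -> dict[str, int]:
    """Per-class interface counts for a list of contacting chain pairs."""
    counts: Counter = Counter()
    for x, y in pairs:
        t = relative_transform(x, y)
        counts[classify_interface(t, (x.conformer, y.conformer), angle_tol)] += 1
    return dict(counts)
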