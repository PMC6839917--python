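"""Rigid-body geometry: superposition, RMSD, domain rotations, interfaces.

These are the metrics used to quantify a conformational change between two
states of a multi-domain protein: least-squares superposition (Kabsch),
paired Calpha RMSD, the rotation of one domain relative to a reference
domain expressed as axis/angle plus screw translation, residue-residue
interface detection by a Calpha-Calpha distance cutoff, and simple
distance descriptors.

Measurement convention for domain rotations: the two models are first
aligned on the reference selection, then the best-fit rotation carrying
the moving selection of the first model onto the (aligned) second model is
extracted.  Reported angles depend on this convention; it is fixed here so
results are reproducible.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegeneracyError, SelectionError
from .models import CalphaModel, DomainDefinition

__all__ = [
    "Superposition",
    "RotationDescriptor",
    "InterfacePair",
    "superpose",
    "paired_rmsd",
    "domain_rotation",
    "interface_pairs",
    "pair_distance",
    "end_to_end",
]


@dataclass(frozen=True)
class Superposition:
    """Proper rigid transform ``x -> rotation @ x + translation`` with its RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RotationDescriptor:
    """Axis-angle description of a relative domain rotation.

    ``angle`` is in degrees on [0, 180]; ``axis`` is a unit vector (by
    convention the rotation is right-handed about it).  ``screw_translation``
    is the displacement component along the axis.  For a zero rotation the
    axis is undefined and ``defined`` is False.
    """

    angle: float
    axis: np.ndarray
    screw_translation: float
    defined: bool = True


class InterfacePair(NamedTuple):
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    distance: float


def _as_points(coords: np.ndarray) -> np.ndarray:
    pts = np.asarray(coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("coordinate set must have shape (n, 3)")
    return pts


def superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares superposition of paired point sets (Kabsch).

    Finds the proper rotation R and translation t minimizing the RMSD of
    ``R @ mobile + t`` against ``reference``.  Reflections are rejected by
    construction (the SVD determinant correction).

    Raises
    ------
    DegeneracyError
        When fewer than 3 points are given, the sets differ in length, or
        either set is collinear/coincident (rank < 2 after centering).
    """
    P = _as_points(mobile)
    Q = _as_points(reference)
    if len(P) != len(Q):
        raise DegeneracyError("paired coordinate sets differ in length")
    n = len(P)
    if n < 3:
        raise DegeneracyError(f"need at least 3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise DegeneracyError("degenerate (collinear or coincident) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _paired_indices(
    model_a: CalphaModel,
    model_b: CalphaModel,
    selection: DomainDefinition | Sequence[DomainDefinition] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of residues common to both models, paired by (chain, resnum, icode)."""
    if selection is None:
        idx_a = np.arange(len(model_a))
    else:
        idx_a = model_a.definition_indices(selection)
    ia, ib = [], []
    for i in idx_a:
        key = (model_a.chain_ids[i], int(model_a.residue_numbers[i]), model_a.icodes[i])
        if model_b.has_residue(*key):
            j = model_b.index_of(*key)
            ia.append(int(i))
            ib.append(j)
    if not ia:
        raise SelectionError("no common residues between models for this selection")
    ia_arr, ib_arr = np.asarray(ia, dtype=np.intp), np.asarray(ib, dtype=np.intp)
    mism = np.sum(model_a.residue_names[ia_arr] != model_b.residue_names[ib_arr])
    if mism:
        warnings.warn(
            f"{mism} paired residues differ in residue name between models",
            stacklevel=3,
        )
    return ia_arr, ib_arr


def paired_rmsd(
    model_a: CalphaModel,
    model_b: CalphaModel,
    selection: DomainDefinition | Sequence[DomainDefinition] | None = None,
) -> float:
    """Calpha RMSD after optimal superposition on the same selection.

    Residues are paired by (chain, residue_number); at least 3 common
    residues are required.
    """
    ia, ib = _paired_indices(model_a, model_b, selection)
    if len(ia) < 3:
        raise SelectionError(f"only {len(ia)} common residues; need at least 3")
    sup = superpose(model_b.coords[ib], model_a.coords[ia])
    return sup.rmsd


def _axis_angle(R: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Angle (deg, [0, 180]) and unit axis of a proper rotation matrix."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    nw = np.linalg.norm(w)
    # arccos near +1 amplifies rounding to ~1e-6 deg; below 1e-4 deg the
    # axis direction is numerically meaningless
    if angle < 1e-4:
        return 0.0, np.array([0.0, 0.0, 1.0]), False
    if nw > 1e-12:
        axis = w / nw
    else:
        # angle ~ 180 deg: axis from the symmetric part
        M = (R + np.eye(3)) / 2.0
        axis = M[:, int(np.argmax(np.diag(M)))]
        axis = axis / np.linalg.norm(axis)
    return angle, axis, True


def domain_rotation(
    model_a: CalphaModel,
    model_b: CalphaModel,
    reference_sel: DomainDefinition | Sequence[DomainDefinition],
    moving_sel: DomainDefinition | Sequence[DomainDefinition],
) -> RotationDescriptor:
    """Rotation of ``moving_sel`` between two states, after reference alignment.

    ``model_b`` is first superposed onto ``model_a`` using ``reference_sel``;
    the best-fit rotation carrying the moving selection of ``model_a`` onto
    the aligned ``model_b`` is then returned as axis-angle plus the screw
    translation (centroid displacement along the axis).
    """
    ref_a, ref_b = _paired_indices(model_a, model_b, reference_sel)
    if len(ref_a) < 3:
        raise DegeneracyError("reference selection pairs fewer than 3 residues")
    align = superpose(model_b.coords[ref_b], model_a.coords[ref_a])
    b_aligned = align.apply(model_b.coords)
    mov_a, mov_b = _paired_indices(model_a, model_b, moving_sel)
    if len(mov_a) < 3:
        raise DegeneracyError("moving selection pairs fewer than 3 residues")
    sup = superpose(model_a.coords[mov_a], b_aligned[mov_b])
    angle, axis, defined = _axis_angle(sup.rotation)
    ca = model_a.coords[mov_a].mean(axis=0)
    cb = b_aligned[mov_b].mean(axis=0)
    screw = float(np.dot(cb - ca, axis)) if defined else 0.0
    return RotationDescriptor(
        angle=angle, axis=axis, screw_translation=screw, defined=defined
    )


def interface_pairs(
    model: CalphaModel,
    sel_a: DomainDefinition | Sequence[DomainDefinition],
    sel_b: DomainDefinition | Sequence[DomainDefinition],
    cutoff: float = 10.0,
) -> list[InterfacePair]:
    """All cross residue pairs with Calpha-Calpha distance <= cutoff (inclusive).

    The two selections must be disjoint.  Pairs are sorted by ascending
    distance.
    """
    ia = model.definition_indices(sel_a)
    ib = model.definition_indices(sel_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError("interface selections overlap")
    d = cdist(model.coords[ia], model.coords[ib])
    out: list[InterfacePair] = []
    for i, j in zip(*np.nonzero(d <= cutoff)):
        gi, gj = int(ia[i]), int(ib[j])
        out.append(
            InterfacePair(
                chain_a=model.chain_ids[gi],
                residue_a=int(model.residue_numbers[gi]),
                chain_b=model.chain_ids[gj],
                residue_b=int(model.residue_numbers[gj]),
                distance=float(d[i, j]),
            )
        )
    out.sort(key=lambda p: p.distance)
    return out


def pair_distance(
    model: CalphaModel,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
) -> float:
    """Euclidean Calpha-Calpha distance between two residues.

    Raises ``KeyError`` when a residue is missing from the model.
    """
    ia = model.index_of(*residue_a)
    ib = model.index_of(*residue_b)
    return float(np.linalg.norm(model.coords[ia] - model.coords[ib]))


def end_to_end(
    model: CalphaModel,
    selection: DomainDefinition | Sequence[DomainDefinition],
) -> float:
    """Distance between the first and last Calpha of a selection (model order)."""
    idx = model.definition_indices(selection)
    if len(idx) < 2:
        raise SelectionError("end_to_end needs a selection with at least 2 atoms")
    return float(np.linalg.norm(model.coords[idx[-1]] - model.coords[idx[0]]))
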