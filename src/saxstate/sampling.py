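"""Staged rigid-body hinge sampling of Calpha models.

A conformer pool is generated from a start model by rotating rigid groups
of domains about hinge pivots.  Each stage of a protocol names the hinges
active in that stage; for every requested sample the hinge angles are
drawn uniformly on [-max_angle, +max_angle] about random (or fixed) axes
through the pivot Calpha, and conformers with steric clashes are rejected
and resampled up to a retry bound.  Members of stage k carry the moves of
stages 1..k (fresh draws per member), so later stages explore a larger
region around the start model while the held-fixed core never moves.

This is a transparent, seedable stand-in for minimization-free rigid-body
exploration: no torsion-space dynamics, no energy model beyond the clash
filter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, SamplingError, SelectionError
from .models import CalphaModel, DomainDefinition

__all__ = [
    "RigidGroup",
    "Hinge",
    "Stage",
    "SamplingProtocol",
    "Conformer",
    "ConformerPool",
    "apply_hinge",
    "clash_check",
    "sample_conformers",
    "sgc_default_protocol",
    "dumbbell_default_protocol",
]

RETRY_BOUND = 50  # resampling attempts per requested conformer

#: Calpha steric diameter used as the default clash cutoff (Angstrom).
DEFAULT_CLASH_CUTOFF = 3.5


@dataclass(frozen=True)
class RigidGroup:
    """A named union of domain selections moved as one rigid body."""

    name: str
    selections: tuple[DomainDefinition, ...]

    def indices(self, model: CalphaModel) -> np.ndarray:
        return model.definition_indices(list(self.selections))


@dataclass(frozen=True)
class Hinge:
    """A pivot about which a rigid group rotates.

    ``axis_mode`` is either the string 'random' (a fresh isotropic axis
    per draw) or a fixed unit 3-vector.
    """

    pivot: tuple[str, int]  # (chain, residue_number)
    moving_group: RigidGroup
    max_angle: float  # degrees
    axis_mode: str | tuple[float, float, float] = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_angle <= 180.0:
            raise ConfigError("hinge max_angle must be in [0, 180] degrees")
        if isinstance(self.axis_mode, str):
            if self.axis_mode != "random":
                raise ConfigError("axis_mode must be 'random' or a fixed 3-vector")
        else:
            v = np.asarray(self.axis_mode, dtype=np.float64)
            if v.shape != (3,) or np.linalg.norm(v) == 0:
                raise ConfigError("fixed hinge axis must be a nonzero 3-vector")


@dataclass(frozen=True)
class Stage:
    hinges: tuple[Hinge, ...]
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("each stage needs n_samples > 0")


@dataclass(frozen=True)
class SamplingProtocol:
    """Ordered stages plus the clash cutoff and master seed."""

    stages: tuple[Stage, ...]
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    seed: int = 0

    def validate(self, model: CalphaModel) -> None:
        for si, stage in enumerate(self.stages):
            seen: set[str] = set()
            idx_sets = []
            for h in stage.hinges:
                if not model.has_residue(*h.pivot):
                    raise ConfigError(
                        f"stage {si + 1}: hinge pivot {h.pivot} absent from model"
                    )
                if h.moving_group.name in seen:
                    continue
                seen.add(h.moving_group.name)
                idx_sets.append(set(h.moving_group.indices(model).tolist()))
            for a in range(len(idx_sets)):
                for b in range(a + 1, len(idx_sets)):
                    if idx_sets[a] & idx_sets[b]:
                        raise ConfigError(
                            f"stage {si + 1}: rigid groups overlap"
                        )


@dataclass(frozen=True)
class Conformer:
    model: CalphaModel
    member_id: str
    stage: int
    perturbations: tuple[tuple[str, float, tuple[float, float, float]], ...]
    rmsd_to_start: float


@dataclass
class ConformerPool:
    """Clash-free conformers with their sampling provenance."""

    members: list[Conformer]
    seed: int | None = None
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ConfigError("conformer pool member ids must be unique")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def models(self) -> list[CalphaModel]:
        return [m.model for m in self.members]

    def ids(self) -> list[str]:
        return [m.member_id for m in self.members]


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation about a unit axis (Rodrigues)."""
    theta = np.radians(angle_deg)
    k = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]], dtype=np.float64
    )
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def apply_hinge(
    model: CalphaModel,
    hinge: Hinge,
    angle: float,
    axis: np.ndarray,
) -> CalphaModel:
    """Rotate the hinge's rigid group about the axis through the pivot Calpha.

    All atoms outside the moving group are unchanged; within-group
    pairwise distances are preserved exactly (rigid rotation).
    """
    axis = np.asarray(axis, dtype=np.float64)
    if axis.shape != (3,) or np.linalg.norm(axis) == 0:
        raise ValueError("hinge axis must be a nonzero 3-vector")
    idx = hinge.moving_group.indices(model)
    if len(idx) == 0:
        raise SelectionError(f"rigid group {hinge.moving_group.name!r} is empty")
    pivot = model.coords[model.index_of(*hinge.pivot)]
    R = _rotation_matrix(axis, angle)
    coords = model.coords.copy()
    coords[idx] = (coords[idx] - pivot) @ R.T + pivot
    return model.with_coords(coords)


def clash_check(
    model: CalphaModel, cutoff: float = DEFAULT_CLASH_CUTOFF
) -> tuple[bool, list[tuple[int, int, float]]]:
    """Steric plausibility filter on non-adjacent Calpha pairs.

    Returns ``(ok, offending_pairs)`` where ``ok`` is True iff no pair of
    residues non-adjacent in sequence (|delta resnum| > 2 on the same
    chain, or on different chains) lies strictly closer than ``cutoff``.
    Offending pairs are (atom_index_i, atom_index_j, distance).
    """
    if len(model) == 0:
        raise SelectionError("cannot clash-check an empty model")
    tree = cKDTree(model.coords)
    offending: list[tuple[int, int, float]] = []
    for i, j in tree.query_pairs(r=cutoff):
        same_chain = model.chain_ids[i] == model.chain_ids[j]
        if same_chain and abs(
            int(model.residue_numbers[i]) - int(model.residue_numbers[j])
        ) <= 2:
            continue
        d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
        if d < cutoff:
            offending.append((int(i), int(j), d))
    return (len(offending) == 0), offending


def _random_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def sample_conformers(
    start: CalphaModel, protocol: SamplingProtocol
) -> ConformerPool:
    """Generate a clash-free conformer pool from a start model.

    For each stage, ``n_samples`` members are drawn; a member of stage k
    applies one fresh draw of every hinge of stages 1..k in order.  Hinge
    angles are uniform on [-max_angle, +max_angle]; axes are isotropic
    unless fixed.  Clashing conformers are rejected and redrawn up to
    RETRY_BOUND times; exhausting the bound raises
    :class:`SamplingError` naming the stage.  The pool is bitwise
    reproducible from the protocol seed.
    """
    protocol.validate(start)
    rng = np.random.default_rng(protocol.seed)
    members: list[Conformer] = []
    counter = 0
    for si, stage in enumerate(protocol.stages):
        active_hinges = [h for st in protocol.stages[: si + 1] for h in st.hinges]
        for _ in range(stage.n_samples):
            accepted = None
            for _attempt in range(RETRY_BOUND):
                m = start
                pert = []
                for h in active_hinges:
                    angle = float(rng.uniform(-h.max_angle, h.max_angle))
                    if isinstance(h.axis_mode, str):
                        axis = _random_axis(rng)
                    else:
                        axis = np.asarray(h.axis_mode, dtype=np.float64)
                        axis = axis / np.linalg.norm(axis)
                    m = apply_hinge(m, h, angle, axis)
                    pert.append(
                        (h.moving_group.name, angle, tuple(float(c) for c in axis))
                    )
                ok, _pairs = clash_check(m, protocol.clash_cutoff)
                if ok:
                    accepted = (m, tuple(pert))
                    break
            if accepted is None:
                raise SamplingError(
                    f"stage {si + 1}: clash-free sampling starved after "
                    f"{RETRY_BOUND} retries"
                )
            counter += 1
            model, pert_t = accepted
            members.append(
                Conformer(
                    model=model,
                    member_id=f"s{si + 1}_{counter:04d}",
                    stage=si + 1,
                    perturbations=pert_t,
                    rmsd_to_start=_raw_rmsd(model.coords, start.coords),
                )
            )
    return ConformerPool(
        members=members, seed=protocol.seed, clash_cutoff=protocol.clash_cutoff
    )


def _indices_to_defs(
    model: CalphaModel, indices: np.ndarray, name: str
) -> list[DomainDefinition]:
    """Per-chain contiguous residue ranges covering the given atom indices."""
    defs: list[DomainDefinition] = []
    by_chain: dict[str, list[int]] = {}
    for i in indices:
        by_chain.setdefault(model.chain_ids[i], []).append(
            int(model.residue_numbers[i])
        )
    for chain, nums in by_chain.items():
        nums = sorted(set(nums))
        ranges: list[tuple[int, int]] = []
        lo = prev = nums[0]
        for n in nums[1:]:
            if n == prev + 1:
                prev = n
            else:
                ranges.append((lo, prev))
                lo = prev = n
        ranges.append((lo, prev))
        defs.append(
            DomainDefinition(name=f"{name}:{chain}", chain=chain, ranges=tuple(ranges))
        )
    return defs


def _label_ranges(model: CalphaModel, label: str) -> list[DomainDefinition]:
    """Contiguous per-chain residue ranges of a domain label, as definitions."""
    return _indices_to_defs(model, model.domain_indices(label), label)


def dumbbell_default_protocol(
    model: CalphaModel,
    n_samples_per_stage: int = 200,
    max_angle: float = 40.0,
    seed: int = 0,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> SamplingProtocol:
    """Two-stage hinge protocol for a labelled two-lobed dumbbell model.

    Stage 1 swings the regulatory lobe about the hinge where the linker
    leaves it; stage 2 swings the regulatory lobe together with the
    linker about the hinge where the linker meets the catalytic lobe.
    The catalytic lobe is held fixed throughout.

    Because the linker termini are embedded inside the lobes, each hinge
    pivot is placed at the linker bead where the chain actually exits the
    lobe (just beyond the lobe's bead envelope), and the embedded linker
    segments move rigidly with their lobe.  Pivoting deeper inside a lobe
    would sweep the buried linker beads through the lobe and make
    clash-free sampling impossible.
    """
    for lab in ("lobe_reg", "linker", "lobe_cat"):
        try:
            model.domain_indices(lab)
        except SelectionError as exc:
            raise ConfigError(f"model lacks required domain label {lab!r}") from exc
    linker_idx = model.domain_indices("linker")
    reg_idx = model.domain_indices("lobe_reg")
    cat_idx = model.domain_indices("lobe_cat")

    def _clearance(lobe_idx: np.ndarray) -> np.ndarray:
        """Distance of each linker bead beyond the lobe's bead envelope."""
        center = model.coords[lobe_idx].mean(axis=0)
        r_max = float(
            np.max(np.linalg.norm(model.coords[lobe_idx] - center, axis=1))
        )
        d = np.linalg.norm(model.coords[linker_idx] - center, axis=1)
        return d - r_max

    clear_reg = _clearance(reg_idx)
    clear_cat = _clearance(cat_idx)
    # preferred: first/last linker bead with a 2 A margin outside the lobe;
    # short linkers fall back to any positive clearance, then to the bead
    # with the largest clearance
    def _pick(clear: np.ndarray, from_end: bool, threshold: float) -> int | None:
        hits = np.flatnonzero(clear >= threshold)
        if len(hits):
            return int(hits[-1] if from_end else hits[0])
        return None

    for threshold in (2.0, 0.0):
        k1 = _pick(clear_reg, from_end=False, threshold=threshold)
        k2 = _pick(clear_cat, from_end=True, threshold=threshold)
        if k1 is not None and k2 is not None and k1 <= k2:
            break
    else:
        # extremely short linker: share the single best-cleared bead
        k1 = k2 = int(np.argmax(np.minimum(clear_reg, clear_cat)))
    p1_pos = int(linker_idx[k1])  # linker bead where the chain exits the reg lobe
    p2_pos = int(linker_idx[k2])  # linker bead where the chain enters the cat lobe
    stage1_moving = np.concatenate(
        [reg_idx, linker_idx[linker_idx < p1_pos]]
    )
    stage2_moving = np.concatenate(
        [reg_idx, linker_idx[linker_idx < p2_pos]]
    )
    group1 = RigidGroup(
        "lobe_reg", tuple(_indices_to_defs(model, stage1_moving, "lobe_reg"))
    )
    group2 = RigidGroup(
        "lobe_reg+linker",
        tuple(_indices_to_defs(model, stage2_moving, "lobe_reg+linker")),
    )
    pivot1 = (model.chain_ids[p1_pos], int(model.residue_numbers[p1_pos]))
    pivot2 = (model.chain_ids[p2_pos], int(model.residue_numbers[p2_pos]))
    return SamplingProtocol(
        stages=(
            Stage(
                hinges=(Hinge(pivot1, group1, max_angle),),
                n_samples=n_samples_per_stage,
            ),
            Stage(
                hinges=(Hinge(pivot2, group2, max_angle),),
                n_samples=n_samples_per_stage,
            ),
        ),
        clash_cutoff=clash_cutoff,
        seed=seed,
    )


# sGC-style domain labels expected on a full heterodimer trace
_SGC_REGULATORY = (
    "alpha_HNOX", "beta_HNOX", "alpha_PAS", "beta_PAS", "alpha_CC", "beta_CC",
)
_SGC_STAGE1 = ("alpha_HNOX", "alpha_Nterm", "alpha_Cterm")


def sgc_default_protocol(
    model: CalphaModel,
    n_samples_per_stage: int = 200,
    max_angle: float = 40.0,
    seed: int = 0,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> SamplingProtocol:
    """Default staged protocol for an sGC-style labelled heterodimer.

    Stage 1 moves the alpha H-NOX domain and any labelled alpha terminal
    tails about the alpha H-NOX/PAS junction; stage 2 moves the whole
    regulatory lobe (both H-NOX and PAS domains plus the coiled-coils)
    about the hinge where the coiled-coils meet the catalytic domains,
    holding the catalytic dimer fixed.  For two-lobed dumbbell labels
    (lobe_reg / linker / lobe_cat) the equivalent dumbbell protocol is
    returned.
    """
    if model.domain_labels is None:
        raise ConfigError("model carries no domain labels")
    labels = set(model.domain_labels.values())
    if {"lobe_reg", "linker", "lobe_cat"} <= labels:
        return dumbbell_default_protocol(
            model, n_samples_per_stage, max_angle, seed, clash_cutoff
        )
    missing = [lab for lab in _SGC_REGULATORY if lab not in labels]
    if missing:
        raise ConfigError(f"model lacks required sGC domain labels: {missing}")
    stage1_labels = [lab for lab in _SGC_STAGE1 if lab in labels]
    stage1_defs = tuple(
        d for lab in stage1_labels for d in _label_ranges(model, lab)
    )
    stage1_group = RigidGroup("alpha_HNOX+tails", stage1_defs)
    hnox_idx = model.domain_indices("alpha_HNOX")
    last_hnox = int(hnox_idx[-1])
    pivot1 = (model.chain_ids[last_hnox], int(model.residue_numbers[last_hnox]))
    reg_defs = tuple(
        d for lab in _SGC_REGULATORY for d in _label_ranges(model, lab)
    )
    reg_group = RigidGroup("regulatory_lobe", reg_defs)
    acc_idx = model.domain_indices("alpha_CC")
    last_cc = int(acc_idx[-1])
    pivot2 = (model.chain_ids[last_cc], int(model.residue_numbers[last_cc]))
    return SamplingProtocol(
        stages=(
            Stage(
                hinges=(Hinge(pivot1, stage1_group, max_angle),),
                n_samples=n_samples_per_stage,
            ),
            Stage(
                hinges=(Hinge(pivot2, reg_group, max_angle),),
                n_samples=n_samples_per_stage,
            ),
        ),
        clash_cutoff=clash_cutoff,
        seed=seed,
    )
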