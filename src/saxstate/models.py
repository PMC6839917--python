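"""Calpha trace models: reading, writing and residue-range selection.

Coarse-grained structural models are represented as ordered Calpha traces,
one bead per residue, with chain identity, author residue numbering and
optional per-atom domain labels.  PDB and mmCIF input is parsed with gemmi;
output is written as standard PDB ATOM records with TER separators.

Only Calpha atoms are retained: the models this package operates on are
backbone traces, and all quantities downstream (scattering, geometry,
sampling) are defined on one bead per residue.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyModelError, FormatError, SelectionError

__all__ = [
    "CalphaModel",
    "DomainDefinition",
    "read_calpha",
    "write_calpha",
    "select",
    "write_domain_sidecar",
    "apply_domain_sidecar",
]


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of inclusive residue-number intervals on one chain.

    Parameters
    ----------
    name : str
        Domain name (e.g. ``"alpha_CC"``).
    chain : str
        Chain identifier the intervals refer to.
    ranges : sequence of (int, int)
        Inclusive ``(lower, upper)`` residue-number intervals.  Intervals
        must be non-overlapping with ``lower <= upper``.
    """

    name: str
    chain: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        rngs = tuple((int(lo), int(hi)) for lo, hi in self.ranges)
        object.__setattr__(self, "ranges", rngs)
        for lo, hi in rngs:
            if lo > hi:
                raise SelectionError(
                    f"domain {self.name!r}: interval ({lo}, {hi}) has lower > upper"
                )
        for (lo1, hi1), (lo2, hi2) in zip(sorted(rngs), sorted(rngs)[1:]):
            if lo2 <= hi1:
                raise SelectionError(
                    f"domain {self.name!r}: intervals ({lo1},{hi1}) and "
                    f"({lo2},{hi2}) overlap"
                )

    def contains(self, chain: str, resnum: int) -> bool:
        return chain == self.chain and any(
            lo <= resnum <= hi for lo, hi in self.ranges
        )


@dataclass
class CalphaModel:
    """An ordered Calpha trace.

    Atoms are stored in canonical order: chains in order of first
    appearance, residues by ascending (residue_number, insertion_code)
    within each chain.  Duplicate (chain, residue_number, icode) triples
    are forbidden.  Coordinates are in Angstrom.

    Attributes
    ----------
    chain_ids : (n,) array of str
    residue_numbers : (n,) array of int
    residue_names : (n,) array of str  (3-letter codes)
    coords : (n, 3) float array, Angstrom
    icodes : (n,) array of str, '' when absent
    domain_labels : dict mapping atom index -> domain name, or None
    model_id : str
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    coords: np.ndarray
    icodes: np.ndarray | None = None
    domain_labels: dict[int, str] | None = None
    model_id: str = ""
    _index: dict[tuple[str, int, str], int] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        if self.icodes is None:
            self.icodes = np.asarray([""] * n, dtype=object)
        else:
            self.icodes = np.asarray(self.icodes, dtype=object)
        if not (
            len(self.chain_ids) == len(self.residue_numbers)
            == len(self.residue_names) == len(self.icodes) == n
        ):
            raise ValueError("CalphaModel field lengths disagree")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("CalphaModel coordinates must be finite")
        # canonical order: chains by first appearance, residues ascending
        order = self._canonical_order()
        if not np.array_equal(order, np.arange(n)):
            self.chain_ids = self.chain_ids[order]
            self.residue_numbers = self.residue_numbers[order]
            self.residue_names = self.residue_names[order]
            self.icodes = self.icodes[order]
            self.coords = self.coords[order]
            if self.domain_labels is not None:
                inv = {int(old): new for new, old in enumerate(order)}
                self.domain_labels = {
                    inv[i]: lab for i, lab in self.domain_labels.items()
                }
        if self.domain_labels is not None:
            bad = [i for i in self.domain_labels if not 0 <= i < n]
            if bad:
                raise ValueError(f"domain_labels reference missing atoms: {bad}")
        keys = list(zip(self.chain_ids, self.residue_numbers.tolist(), self.icodes))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate residue {k} in model")
                seen.add(k)
        self._index = {k: i for i, k in enumerate(keys)}

    def _canonical_order(self) -> np.ndarray:
        chain_rank: dict[str, int] = {}
        for c in self.chain_ids:
            chain_rank.setdefault(c, len(chain_rank))
        key = [
            (chain_rank[c], int(rn), ic)
            for c, rn, ic in zip(self.chain_ids, self.residue_numbers, self.icodes)
        ]
        return np.asarray(
            sorted(range(len(key)), key=key.__getitem__), dtype=np.intp
        )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for c in self.chain_ids:
            if c not in out:
                out.append(c)
        return out

    def index_of(self, chain: str, resnum: int, icode: str = "") -> int:
        """Atom index of the residue, raising ``KeyError`` when absent."""
        assert self._index is not None
        return self._index[(chain, int(resnum), icode)]

    def has_residue(self, chain: str, resnum: int, icode: str = "") -> bool:
        assert self._index is not None
        return (chain, int(resnum), icode) in self._index

    def definition_indices(
        self, definition: DomainDefinition | Sequence[DomainDefinition]
    ) -> np.ndarray:
        """Atom indices matching one or more domain definitions (model order)."""
        defs = (
            [definition] if isinstance(definition, DomainDefinition) else list(definition)
        )
        for d in defs:
            if d.chain not in self.chains:
                raise SelectionError(
                    f"chain {d.chain!r} (domain {d.name!r}) not present in model"
                )
        mask = np.zeros(len(self), dtype=bool)
        for d in defs:
            for i, (c, rn) in enumerate(zip(self.chain_ids, self.residue_numbers)):
                if d.contains(c, int(rn)):
                    mask[i] = True
        return np.flatnonzero(mask)

    def domain_indices(self, name: str) -> np.ndarray:
        """Atom indices carrying the given domain label."""
        if self.domain_labels is None:
            raise SelectionError("model has no domain labels")
        idx = sorted(i for i, lab in self.domain_labels.items() if lab == name)
        if not idx:
            raise SelectionError(f"no atoms labelled {name!r}")
        return np.asarray(idx, dtype=np.intp)

    def take(self, indices: np.ndarray, model_id: str | None = None) -> "CalphaModel":
        """Sub-model containing the given atom indices (model order kept)."""
        indices = np.sort(np.asarray(indices, dtype=np.intp))
        labels = None
        if self.domain_labels is not None:
            pos = {int(old): new for new, old in enumerate(indices)}
            labels = {
                pos[i]: lab for i, lab in self.domain_labels.items() if i in pos
            }
        return CalphaModel(
            chain_ids=self.chain_ids[indices],
            residue_numbers=self.residue_numbers[indices],
            residue_names=self.residue_names[indices],
            coords=self.coords[indices],
            icodes=self.icodes[indices],
            domain_labels=labels,
            model_id=model_id if model_id is not None else self.model_id,
        )

    def with_coords(
        self, coords: np.ndarray, model_id: str | None = None
    ) -> "CalphaModel":
        """Copy of the model with replaced coordinates."""
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if len(coords) != len(self):
            raise ValueError("coordinate array length mismatch")
        return CalphaModel(
            chain_ids=self.chain_ids.copy(),
            residue_numbers=self.residue_numbers.copy(),
            residue_names=self.residue_names.copy(),
            coords=coords.copy(),
            icodes=self.icodes.copy(),
            domain_labels=dict(self.domain_labels) if self.domain_labels else None,
            model_id=model_id if model_id is not None else self.model_id,
        )


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_calpha(path: str | Path, format: str = "auto") -> CalphaModel:
    """Read a Calpha trace from a PDB or mmCIF file.

    Only Calpha atoms are kept, one per residue.  Waters and hetero
    records are dropped; when a residue carries several altloc conformers
    the first occurring CA (altloc A by PDB convention) is retained.
    Residues without a CA record are absent from the model.

    Parameters
    ----------
    path : path-like
    format : {'pdb', 'mmcif', 'auto'}
        'auto' detects the format from file content.

    Raises
    ------
    FormatError
        When the file cannot be parsed in the named format.
    EmptyModelError
        When no Calpha atoms are found.
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: structure contains no models")
    chain_ids, resnums, resnames, icodes, xyz = [], [], [], [], []
    for chain in st[0]:
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            ca = next((a for a in res if a.name.strip() == "CA"), None)
            if ca is None:
                continue
            chain_ids.append(chain.name)
            resnums.append(res.seqid.num)
            resnames.append(res.name)
            icodes.append(res.seqid.icode.strip())
            xyz.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not xyz:
        raise EmptyModelError(f"{path}: no Calpha atoms found")
    return CalphaModel(
        chain_ids=np.asarray(chain_ids, dtype=object),
        residue_numbers=np.asarray(resnums),
        residue_names=np.asarray(resnames, dtype=object),
        coords=np.asarray(xyz),
        icodes=np.asarray(icodes, dtype=object),
        model_id=Path(str(path)).stem,
    )


def write_calpha(model: CalphaModel, path: str | Path) -> None:
    """Write a Calpha trace as standard PDB ATOM records.

    Chains are written in model order and separated by TER records;
    coordinates keep the 3-decimal PDB precision, so
    ``read_calpha(write_calpha(m))`` reproduces identities exactly and
    coordinates to 1e-3 Angstrom.
    """
    if len(model) == 0:
        raise EmptyModelError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.model_id or "model"
    gm = gemmi.Model("1")
    chain = None
    for i in range(len(model)):
        cid = model.chain_ids[i]
        if chain is None or chain.name != cid:
            if chain is not None:
                gm.add_chain(chain)
            chain = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = str(model.residue_names[i])
        ic = model.icodes[i] or " "
        res.seqid = gemmi.SeqId(int(model.residue_numbers[i]), ic)
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        atom.b_iso = 0.0
        x, y, z = model.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        res.add_atom(atom)
        chain.add_residue(res)
    if chain is not None:
        gm.add_chain(chain)
    st.add_model(gm)
    opts = gemmi.PdbWriteOptions()
    opts.ter_records = True
    opts.ter_ignores_type = True
    opts.cryst1_record = False
    try:
        st.write_pdb(str(path), opts)
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_domain_sidecar(model: CalphaModel, path: str | Path) -> None:
    """Persist domain labels as a JSON sidecar (PDB itself carries none).

    Format: ``{label: {chain: [[lo, hi], ...]}}`` with inclusive residue
    ranges, so labels survive a write/read round trip of the coordinates.
    """
    import json

    if model.domain_labels is None:
        raise ValueError("model has no domain labels to persist")
    out: dict[str, dict[str, list[list[int]]]] = {}
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, lab in model.domain_labels.items():
        key = (lab, model.chain_ids[i])
        by_key.setdefault(key, []).append(int(model.residue_numbers[i]))
    for (lab, chain), nums in by_key.items():
        nums = sorted(set(nums))
        ranges: list[list[int]] = []
        lo = prev = nums[0]
        for n in nums[1:]:
            if n == prev + 1:
                prev = n
            else:
                ranges.append([lo, prev])
                lo = prev = n
        ranges.append([lo, prev])
        out.setdefault(lab, {})[chain] = ranges
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)


def apply_domain_sidecar(model: CalphaModel, path: str | Path) -> CalphaModel:
    """Return a copy of the model with labels loaded from a JSON sidecar."""
    import json

    with open(path) as fh:
        raw = json.load(fh)
    labels: dict[int, str] = {}
    for lab, chains in raw.items():
        for chain, ranges in chains.items():
            for lo, hi in ranges:
                for i in range(len(model)):
                    if model.chain_ids[i] == chain and lo <= int(
                        model.residue_numbers[i]
                    ) <= hi:
                        labels[i] = lab
    out = model.with_coords(model.coords)
    out.domain_labels = labels
    return out


def select(model: CalphaModel, definition: DomainDefinition) -> CalphaModel:
    """Atoms of ``model`` whose (chain, residue_number) fall in ``definition``.

    Order is preserved.  Raises :class:`SelectionError` when the chain is
    absent or the selection is empty.
    """
    idx = model.definition_indices(definition)
    if len(idx) == 0:
        raise SelectionError(
            f"selection {definition.name!r} matches no residues in model"
        )
    return model.take(idx)
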