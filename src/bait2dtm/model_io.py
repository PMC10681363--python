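"""Atomic model I/O and omit-template construction.

Omit templates are atomic models with selected atoms removed before density
simulation: a sphere around a chosen site (e.g. a ligand binding pocket),
every n-th residue of each chain, or whole chains.  Density that appears in
the omitted regions of a reconstruction built from template-detected
particles cannot derive from the template and is therefore bias-free
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomicModel",
    "OmitSpec",
    "read_model",
    "write_model",
    "sphere_omit",
    "periodic_omit",
    "chain_omit",
    "model_mass",
    "point_group_rotations",
]


class ModelFormatError(ValueError):
    """Raised when a file cannot be interpreted as an atomic model."""


class SelectionError(ValueError):
    """Raised when an atom selector resolves to zero or several atoms."""


@dataclass
class AtomicModel:
    """Flat, ordered list of atoms stored as parallel arrays.

    Coordinates are in Angstrom, B-factors in A^2.  Atom order is the file
    order and is preserved by every omit operation for surviving atoms.
    """

    elements: list[str]
    positions: np.ndarray  # (n, 3) float64, Angstrom
    b_factors: np.ndarray  # (n,) float64, A^2
    chain_ids: list[str]
    residue_indices: np.ndarray  # (n,) int
    atom_names: list[str]
    residue_names: list[str] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        self.b_factors = np.asarray(self.b_factors, dtype=np.float64).ravel()
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64).ravel()
        if not self.residue_names:
            self.residue_names = ["UNK"] * self.n_atoms
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atomic coordinates must be finite")
        if np.any(self.b_factors < 0):
            raise ValueError("B-factors must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return self.n_atoms

    def select(self, keep: np.ndarray) -> "AtomicModel":
        """Return the sub-model of atoms where ``keep`` is True, order preserved."""
        keep = np.asarray(keep, dtype=bool)
        idx = np.flatnonzero(keep)
        return AtomicModel(
            elements=[self.elements[i] for i in idx],
            positions=self.positions[idx],
            b_factors=self.b_factors[idx],
            chain_ids=[self.chain_ids[i] for i in idx],
            residue_indices=self.residue_indices[idx],
            atom_names=[self.atom_names[i] for i in idx],
            residue_names=[self.residue_names[i] for i in idx],
            source_id=self.source_id,
        )

    def center_of_mass(self) -> np.ndarray:
        w = np.array([_atomic_weight(e) for e in self.elements])
        return (self.positions * w[:, None]).sum(axis=0) / w.sum()


@dataclass
class OmitSpec:
    """Which atoms to remove when building an omit template.

    mode 'sphere' removes all atoms within ``radius`` (closed ball) of the
    atom selected by ``center_selector`` = (chain_id, residue_index,
    atom_name); with ``apply_symmetry_copies`` the removal is repeated around
    each point-group-related copy of the centre (rotations about the model's
    centre of mass).  mode 'periodic' removes every ``period``-th residue of
    each chain (1-based ordinals over that chain's residues in order of
    appearance).  mode 'chain' removes the chains listed in ``chain_ids``.
    """

    mode: Literal["sphere", "periodic", "chain"]
    center_selector: tuple[str, int, str] | None = None
    radius: float = 0.0
    period: int = 0
    chain_ids: Sequence[str] = ()
    apply_symmetry_copies: bool = False
    symmetry: str = "D2"

    def __post_init__(self) -> None:
        if self.mode == "sphere":
            if self.center_selector is None:
                raise ValueError("sphere omit requires a center_selector")
            if self.radius < 0:
                raise ValueError("radius must be >= 0")
        elif self.mode == "periodic":
            if self.period < 2:
                raise ValueError("period must be >= 2")
        elif self.mode == "chain":
            if not self.chain_ids:
                raise ValueError("chain omit requires chain_ids")
        else:
            raise ValueError(f"unknown omit mode {self.mode!r}")


def _atomic_weight(symbol: str) -> float:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return el.weight


def atomic_number(symbol: str) -> int:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return el.atomic_number


def read_model(path: str | Path, include_hetatm: bool = False) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel`.

    HETATM records are excluded by default (the convention used when
    preparing templates); pass ``include_hetatm=True`` to keep them.  Only
    the first altloc of each atom is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    elements: list[str] = []
    positions: list[list[float]] = []
    b_factors: list[float] = []
    chain_ids: list[str] = []
    residue_indices: list[int] = []
    atom_names: list[str] = []
    residue_names: list[str] = []
    if len(st) == 0:
        _raise_empty(path)
    model = st[0]
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            if is_het and not include_hetatm:
                continue
            seen: set[str] = set()
            for atom in residue:
                if atom.name in seen:  # keep first altloc only
                    continue
                seen.add(atom.name)
                elements.append(atom.element.name)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                b_factors.append(max(atom.b_iso, 0.0))
                chain_ids.append(chain.name)
                residue_indices.append(residue.seqid.num)
                atom_names.append(atom.name)
                residue_names.append(residue.name)
    if not elements:
        _raise_empty(path)
    return AtomicModel(
        elements=elements,
        positions=np.array(positions),
        b_factors=np.array(b_factors),
        chain_ids=chain_ids,
        residue_indices=np.array(residue_indices),
        atom_names=atom_names,
        residue_names=residue_names,
        source_id=path.name,
    )


def _raise_empty(path: Path) -> None:
    first_line = ""
    try:
        with open(path) as fh:
            first_line = fh.readline().rstrip("\n")
    except OSError:
        pass
    raise ModelFormatError(
        f"{path} contains no ATOM records (first line: {first_line!r})"
    )


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write the model as PDB (fixed columns, coordinates to 3 decimals)."""
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    gmodel = gemmi.Model("1")
    chain_obj: gemmi.Chain | None = None
    res_obj: gemmi.Residue | None = None
    prev_key: tuple[str, int] | None = None
    for i in range(model.n_atoms):
        cid = model.chain_ids[i]
        rid = int(model.residue_indices[i])
        if chain_obj is None or chain_obj.name != cid:
            gmodel.add_chain(gemmi.Chain(cid))
            chain_obj = gmodel[-1]
            prev_key = None
        key = (cid, rid)
        if key != prev_key:
            res = gemmi.Residue()
            res.name = model.residue_names[i]
            res.seqid = gemmi.SeqId(rid, " ")
            chain_obj.add_residue(res)
            res_obj = chain_obj[-1]
            prev_key = key
        atom = gemmi.Atom()
        atom.name = model.atom_names[i]
        atom.element = gemmi.Element(model.elements[i])
        atom.pos = gemmi.Position(*model.positions[i])
        atom.b_iso = float(model.b_factors[i])
        atom.occ = 1.0
        res_obj.add_atom(atom)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def point_group_rotations(symmetry: str) -> list[np.ndarray]:
    """Rotation matrices of a Cn or Dn point group (identity included).

    Cn: n rotations about z.  Dn: those plus n two-fold axes in the xy
    plane.  D2 therefore returns the identity and 180-degree rotations about
    x, y and z.
    """
    symmetry = symmetry.strip().upper()
    if len(symmetry) < 2 or symmetry[0] not in "CD" or not symmetry[1:].isdigit():
        raise ValueError(f"unsupported point group {symmetry!r}")
    n = int(symmetry[1:])
    if n < 1:
        raise ValueError(f"unsupported point group {symmetry!r}")
    mats = []
    for k in range(n):
        a = 2 * np.pi * k / n
        c, s = np.cos(a), np.sin(a)
        mats.append(np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]))
    if symmetry[0] == "D":
        flip = np.diag([1.0, -1.0, -1.0])  # two-fold about x
        mats += [m @ flip for m in list(mats)]
    return mats


def _resolve_center(model: AtomicModel, selector: tuple[str, int, str]) -> int:
    cid, rid, aname = selector
    hits = [
        i
        for i in range(model.n_atoms)
        if model.chain_ids[i] == cid
        and model.residue_indices[i] == rid
        and model.atom_names[i] == aname
    ]
    if len(hits) != 1:
        raise SelectionError(
            f"selector {selector!r} matched {len(hits)} atoms (need exactly 1)"
        )
    return hits[0]


def sphere_omit(model: AtomicModel, spec: OmitSpec) -> tuple[AtomicModel, int]:
    """Remove all atoms within ``spec.radius`` (closed ball) of the selected atom.

    With ``spec.apply_symmetry_copies`` the centre is replicated by the point
    group's rotations about the model's centre of mass and removal is applied
    around every copy.  Returns the truncated model and the number of atoms
    removed.
    """
    if spec.mode != "sphere":
        raise ValueError("spec.mode must be 'sphere'")
    ci = _resolve_center(model, spec.center_selector)
    center = model.positions[ci]
    centers = [center]
    if spec.apply_symmetry_copies:
        com = model.center_of_mass()
        centers = [
            com + R @ (center - com) for R in point_group_rotations(spec.symmetry)
        ]
    remove = np.zeros(model.n_atoms, dtype=bool)
    for c in centers:
        d = np.linalg.norm(model.positions - c[None, :], axis=1)
        remove |= d <= spec.radius
    return model.select(~remove), int(remove.sum())


def periodic_omit(model: AtomicModel, spec: OmitSpec) -> tuple[AtomicModel, int]:
    """Remove every ``spec.period``-th residue of each chain.

    Residues are counted with 1-based ordinals over each chain's distinct
    residue indices in order of appearance (robust to numbering gaps), and
    ordinals n, 2n, 3n, ... are removed entirely.  Returns the truncated
    model and the number of residues removed.
    """
    if spec.mode != "periodic":
        raise ValueError("spec.mode must be 'periodic'")
    n = spec.period
    # ordinal of each (chain, residue) in order of appearance
    ordinals: dict[tuple[str, int], int] = {}
    counts: dict[str, int] = {}
    for i in range(model.n_atoms):
        key = (model.chain_ids[i], int(model.residue_indices[i]))
        if key not in ordinals:
            counts[key[0]] = counts.get(key[0], 0) + 1
            ordinals[key] = counts[key[0]]
    remove = np.array(
        [
            ordinals[(model.chain_ids[i], int(model.residue_indices[i]))] % n == 0
            for i in range(model.n_atoms)
        ]
    )
    removed_residues = sum(1 for key, o in ordinals.items() if o % n == 0)
    return model.select(~remove), removed_residues


def chain_omit(model: AtomicModel, spec: OmitSpec) -> tuple[AtomicModel, int]:
    """Remove whole chains (e.g. a single protein from a large complex)."""
    if spec.mode != "chain":
        raise ValueError("spec.mode must be 'chain'")
    drop = set(spec.chain_ids)
    remove = np.array([cid in drop for cid in model.chain_ids])
    return model.select(~remove), int(remove.sum())


def apply_omit(model: AtomicModel, spec: OmitSpec) -> tuple[AtomicModel, int]:
    """Dispatch to the omit operation selected by ``spec.mode``."""
    if spec.mode == "sphere":
        return sphere_omit(model, spec)
    if spec.mode == "periodic":
        return periodic_omit(model, spec)
    return chain_omit(model, spec)


def model_mass(model: AtomicModel) -> float:
    """Total molecular mass in kDa (sum of atomic weights)."""
    if model.n_atoms == 0:
        return 0.0
    return sum(_atomic_weight(e) for e in model.elements) / 1000.0
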