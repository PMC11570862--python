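"""Macromolecular structure model and geometry primitives.

Structures are read with biotite (PDB and mmCIF) into a small hierarchical
model — :class:`Atom`, :class:`Residue`, :class:`Structure` — that carries
exactly what the downstream stages need: coordinates, van der Waals radii,
and the polymer/hetero split.  Only the first model of multi-model files is
used; alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from . import _data
from .errors import ContractError, StructureParseError

logger = logging.getLogger(__name__)

_HYDROGEN = frozenset({"H", "D"})


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates and an assigned vdW radius."""

    serial: int
    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coord", np.asarray(self.coord, dtype=float).reshape(3)
        )
        if not np.all(np.isfinite(self.coord)):
            raise ContractError(f"atom {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ContractError(f"atom {self.name}: vdw_radius must be > 0")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


@dataclass
class Residue:
    """One residue (polymer or hetero group) with an ordered atom list."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.res_name = self.res_name.upper()
        if not self.atoms:
            raise ContractError(
                f"residue {self.res_name} {self.chain_id}{self.res_seq}: no atoms"
            )

    def identity(self, structure_id: str) -> str:
        return f"{structure_id}_{self.chain_id}_{self.res_seq}{self.icode}_{self.res_name}"

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.is_heavy]
        if not coords:
            raise ContractError(
                f"residue {self.res_name} {self.chain_id}{self.res_seq}: no heavy atoms"
            )
        return np.asarray(coords)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """A structure: ordered chains of polymer residues plus hetero groups.

    ``ligand_groups`` holds hetero residues that are candidate modulators;
    water and groups on the buffer/ion exclusion list never appear there.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligand_groups: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group in self.ligand_groups:
            if group.res_name in _data.WATER_NAMES:
                raise ContractError("water may not appear in ligand_groups")

    # -- iteration helpers -------------------------------------------------

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def polymer_atoms(self) -> list[Atom]:
        return [a for res in self.iter_residues() for a in res.atoms]

    def all_atoms(self, include_hetero: bool = True) -> list[Atom]:
        atoms = self.polymer_atoms()
        if include_hetero:
            atoms += [a for g in self.ligand_groups for a in g.atoms]
        return atoms

    def n_atoms(self) -> int:
        return len(self.all_atoms())

    def ligand_keys(self) -> list[str]:
        return [g.identity(self.id) for g in self.ligand_groups]

    def get_ligand(self, group_key: str) -> Residue:
        for group in self.ligand_groups:
            if group.identity(self.id) == group_key:
                return group
        raise KeyError(
            f"group {group_key!r} not in ligand_groups of {self.id}; "
            f"available: {self.ligand_keys()}"
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _radius_for(element: str, radii: dict[str, float]) -> float:
    key = element.upper()
    if key not in radii:
        warnings.warn(
            f"unknown element {element!r}: using fallback vdW radius "
            f"{_data.DEFAULT_VDW_RADIUS} Å",
            stacklevel=3,
        )
        return _data.DEFAULT_VDW_RADIUS
    return radii[key]


def read_structure(
    path: str | Path,
    format: str = "auto",
    exclusions: frozenset[str] | None = None,
    structure_id: str | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Polymer residues go to chains; hetero groups (minus water and the
    buffer/ion exclusion list) to ``ligand_groups``.  vdW radii are assigned
    from the bundled element table with a logged fallback for unknowns.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from biotite.structure.io.pdbx import CIFFile
    from biotite.structure.io.pdbx import get_structure as cif_get_structure

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"

    extra = ["occupancy", "atom_id"]
    try:
        if format == "pdb":
            arr = PDBFile.read(str(path)).get_structure(
                model=1, altloc="occupancy", extra_fields=extra
            )
        elif format == "mmcif":
            arr = cif_get_structure(
                CIFFile.read(str(path)), model=1, altloc="occupancy",
                extra_fields=extra,
            )
        else:
            raise ContractError(f"unknown format {format!r}")
    except ContractError:
        raise
    except Exception as exc:  # parse failures from biotite
        raise StructureParseError(f"cannot parse {path} as {format}: {exc}") from exc

    if exclusions is None:
        exclusions = _data.buffer_exclusions()
    radii = _data.vdw_radii()
    sid = structure_id if structure_id is not None else path.stem

    structure = Structure(id=sid)
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for begin, end in zip(starts[:-1], starts[1:]):
        atoms = []
        for i in range(begin, end):
            atoms.append(
                Atom(
                    serial=int(arr.atom_id[i]),
                    name=str(arr.atom_name[i]),
                    element=str(arr.element[i]).upper(),
                    coord=arr.coord[i],
                    vdw_radius=_radius_for(str(arr.element[i]), radii),
                    occupancy=float(arr.occupancy[i]),
                    altloc="",
                    is_hetero=bool(arr.hetero[i]),
                )
            )
        res = Residue(
            chain_id=str(arr.chain_id[begin]),
            res_seq=int(arr.res_id[begin]),
            icode=str(arr.ins_code[begin]).strip(),
            res_name=str(arr.res_name[begin]),
            atoms=atoms,
        )
        if bool(arr.hetero[begin]):
            if res.res_name in _data.WATER_NAMES or res.res_name in exclusions:
                continue  # buffers/ions dropped on read
            structure.ligand_groups.append(res)
        else:
            structure.chains.setdefault(res.chain_id, []).append(res)
    return structure


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (fixture output)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    records: list[tuple[Residue, Atom, bool]] = []
    for res in structure.iter_residues():
        records += [(res, a, False) for a in res.atoms]
    for group in structure.ligand_groups:
        records += [(group, a, True) for a in group.atoms]

    arr = struc.AtomArray(len(records))
    arr.coord = np.asarray([a.coord for _, a, _ in records])
    arr.chain_id = np.asarray([r.chain_id for r, _, _ in records])
    arr.res_id = np.asarray([r.res_seq for r, _, _ in records])
    arr.ins_code = np.asarray([r.icode for r, _, _ in records])
    arr.res_name = np.asarray([r.res_name for r, _, _ in records])
    arr.hetero = np.asarray([h for _, _, h in records])
    arr.atom_name = np.asarray([a.name for _, a, _ in records])
    arr.element = np.asarray([a.element for _, a, _ in records])
    arr.set_annotation(
        "occupancy", np.asarray([a.occupancy for _, a, _ in records], dtype=float)
    )
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Group manipulation
# ---------------------------------------------------------------------------


def strip_group(structure: Structure, group_key: str) -> Structure:
    """Return a copy of ``structure`` without the named ligand group."""
    structure.get_ligand(group_key)  # raises KeyError if absent
    return Structure(
        id=structure.id,
        chains={cid: list(res) for cid, res in structure.chains.items()},
        ligand_groups=[
            g for g in structure.ligand_groups if g.identity(structure.id) != group_key
        ],
    )


def select_modulator(
    structure: Structure, min_heavy_atoms: int = 6
) -> str:
    """Pick the candidate modulator group: the hetero group with the most
    heavy atoms among those with at least ``min_heavy_atoms`` of them.
    Exclusion-list groups were already removed at read time."""
    candidates = [
        g for g in structure.ligand_groups if len(g.heavy_atoms) >= min_heavy_atoms
    ]
    if not candidates:
        raise ContractError(
            f"{structure.id}: no hetero group with >= {min_heavy_atoms} heavy "
            "atoms; pass the modulator group key explicitly"
        )
    best = max(candidates, key=lambda g: len(g.heavy_atoms))
    return best.identity(structure.id)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def _heavy_coord_array(obj: Residue | Iterable[Atom]) -> np.ndarray:
    if isinstance(obj, Residue):
        atoms: Sequence[Atom] = obj.atoms
    else:
        atoms = list(obj)
    coords = [a.coord for a in atoms if a.is_heavy]
    if not coords:
        raise ContractError("empty heavy-atom set")
    return np.asarray(coords)


def min_heavy_distance(
    residue: Residue | Iterable[Atom], atoms: Residue | Iterable[Atom]
) -> float:
    """Minimum pairwise Euclidean distance between heavy atoms of two sets."""
    a = _heavy_coord_array(residue)
    b = _heavy_coord_array(atoms)
    return float(cdist(a, b).min())


def centroid(atoms: Iterable[Atom], weighting: str = "geometric") -> np.ndarray:
    """Geometric centre (unweighted coordinate mean) of an atom collection."""
    if weighting != "geometric":
        raise ContractError(f"unsupported weighting {weighting!r}")
    coords = np.asarray([a.coord for a in atoms])
    if coords.size == 0:
        raise ContractError("centroid of an empty atom set")
    return coords.mean(axis=0)
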