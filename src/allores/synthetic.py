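"""Synthetic fixtures with known ground truth.

Two generators: (a) ideal α-helix structures with a rigid 8-atom modulator
planted at a controlled distance from chosen residues, giving exact
site-membership ground truth; (b) residue×descriptor tables where positive
rows carry a configurable mean shift on a configurable subset of columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from ._data import STANDARD_RESIDUES
from .errors import ContractError
from .nanoenv import DescriptorTable
from .structures import Atom, Residue, Structure

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# ideal α-helix internal coordinates (bond Å / angle ° / dihedral °)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
_A_N_CA_CB, _T_C_N_CA_CB = 110.5, -122.6


@dataclass(frozen=True)
class FixtureSpec:
    n_res: int
    sequence: str = "poly-A"
    site_residues: tuple[int, ...] = ()
    modulator_gap: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (1 <= i <= self.n_res) for i in self.site_residues):
            raise ContractError("site_residues must lie in [1, n_res]")
        if self.modulator_gap <= 0:
            raise ContractError("modulator_gap must be > 0")

    @property
    def structure_id(self) -> str:
        return f"HX{self.n_res:03d}S{self.seed:04d}"

    def three_letter_sequence(self) -> list[str]:
        if self.sequence == "poly-A":
            return ["ALA"] * self.n_res
        if len(self.sequence) != self.n_res:
            raise ContractError("sequence length must equal n_res")
        try:
            return [_ONE_TO_THREE[c.upper()] for c in self.sequence]
        except KeyError as exc:
            raise ContractError(f"unknown 1-letter code {exc}") from exc


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D given A-B-C, |CD|, angle(BCD) and torsion(ABCD)."""
    angle, torsion = radians(angle_deg), radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * cos(angle),
        bond * cos(torsion) * sin(angle),
        bond * sin(torsion) * sin(angle),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix_structure(spec: FixtureSpec) -> Structure:
    """Ideal α-helix (backbone N, Cα, C, O plus Cβ; no Cβ for GLY).

    Built from standard internal coordinates at φ=−57°, ψ=−47°, which gives
    ≈1.5 Å rise and ≈100° turn per residue and Cα ≈ 2.3 Å off the axis.
    """
    if spec.n_res < 4:
        raise ContractError("need n_res >= 4")
    seq = spec.three_letter_sequence()

    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([_B_N_CA, 0.0, 0.0])]
    angle = radians(_A_N_CA_C)
    c_xyz = [ca_xyz[0] + _B_CA_C * np.array([-cos(angle), sin(angle), 0.0])]
    for i in range(1, spec.n_res):
        n_xyz.append(_place(n_xyz[-1], ca_xyz[-1], c_xyz[-1], _B_C_N, _A_CA_C_N, _PSI))
        ca_xyz.append(_place(ca_xyz[-1], c_xyz[-1], n_xyz[-1], _B_N_CA, _A_C_N_CA, _OMEGA))
        c_xyz.append(_place(c_xyz[-1], n_xyz[-1], ca_xyz[-1], _B_CA_C, _A_N_CA_C, _PHI))

    structure = Structure(id=spec.structure_id)
    chain: list[Residue] = []
    serial = 1
    for i in range(spec.n_res):
        atoms = [
            Atom(serial, "N", "N", n_xyz[i], 1.55),
            Atom(serial + 1, "CA", "C", ca_xyz[i], 1.70),
            Atom(serial + 2, "C", "C", c_xyz[i], 1.70),
            Atom(serial + 3, "O", "O",
                 _place(n_xyz[i], ca_xyz[i], c_xyz[i], _B_C_O, _A_CA_C_O, _PSI + 180.0),
                 1.52),
        ]
        serial += 4
        if seq[i] != "GLY":
            atoms.append(
                Atom(serial, "CB", "C",
                     _place(c_xyz[i], n_xyz[i], ca_xyz[i], _B_CA_CB, _A_N_CA_CB,
                            _T_C_N_CA_CB),
                     1.70)
            )
            serial += 1
        chain.append(Residue(chain_id="A", res_seq=i + 1, icode="", res_name=seq[i],
                             atoms=atoms))
    structure.chains["A"] = chain
    return structure


# ---------------------------------------------------------------------------
# Modulator planting
# ---------------------------------------------------------------------------

_CUBE_UNIT = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=float,
)  # 8 carbons on cube corners; the edge length is fitted during placement


def _rotation(angles: np.ndarray) -> np.ndarray:
    ax, ay, az = angles
    rx = np.array([[1, 0, 0], [0, cos(ax), -sin(ax)], [0, sin(ax), cos(ax)]])
    ry = np.array([[cos(ay), 0, sin(ay)], [0, 1, 0], [-sin(ay), 0, cos(ay)]])
    rz = np.array([[cos(az), -sin(az), 0], [sin(az), cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def plant_modulator(
    structure: Structure,
    site_residues: tuple[int, ...] | list[int],
    gap: float,
    seed: int = 0,
    gap_tolerance: float = 0.3,
    clearance: float = 7.0,
    label_cutoff: float = 5.0,
) -> tuple[Structure, set[str]]:
    """Place a rigid 8-carbon cluster ``gap`` Å from each site residue.

    The cube's position, orientation and edge length are optimized so the
    minimum heavy-atom distance to every site residue falls within
    ``gap ± gap_tolerance`` while non-site residues stay beyond
    ``clearance`` where feasible; non-site residues that end up within
    ``label_cutoff`` join the returned ground-truth identity set.
    """
    chain_id = next(iter(structure.chains))
    chain = structure.chains[chain_id]
    by_seq = {r.res_seq: r for r in chain}
    try:
        site = [by_seq[i] for i in site_residues]
    except KeyError as exc:
        raise ContractError(f"site residue {exc} not in structure") from exc
    if not site:
        raise ContractError("site_residues is empty")
    non_site = [r for r in chain if r.res_seq not in set(site_residues)]

    site_coords = [r.heavy_coords() for r in site]
    non_coords = [r.heavy_coords() for r in non_site]
    chain_centroid = np.vstack([r.heavy_coords() for r in chain]).mean(axis=0)
    site_centroid = np.vstack(site_coords).mean(axis=0)
    outward = site_centroid - chain_centroid
    outward = outward / np.linalg.norm(outward)

    def cube_at(params: np.ndarray) -> np.ndarray:
        half = float(np.clip(abs(params[6]), 0.75, 3.5))
        return params[:3] + (half * _CUBE_UNIT) @ _rotation(params[3:6]).T

    def loss(params: np.ndarray) -> float:
        atoms = cube_at(params)
        total = 0.0
        for coords in site_coords:
            total += 100.0 * (cdist(atoms, coords).min() - gap) ** 2
        for coords in non_coords:
            gap_violation = clearance - cdist(atoms, coords).min()
            if gap_violation > 0:
                total += 0.3 * gap_violation**2
        return total

    def within_band(atoms: np.ndarray) -> bool:
        return all(
            abs(cdist(atoms, coords).min() - gap) <= gap_tolerance
            for coords in site_coords
        )

    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    best_loss = np.inf
    best_ok = False
    for attempt in range(12):
        offset = gap + 2.0 + 0.4 * attempt
        start = np.concatenate([
            site_centroid + offset * outward + rng.normal(0, 0.5, 3),
            rng.uniform(0, np.pi, 3),
            [1.5 + 0.2 * attempt],
        ])
        result = minimize(loss, start, method="Powell",
                          options={"maxiter": 6000, "xtol": 1e-4, "ftol": 1e-8})
        atoms = cube_at(result.x)
        ok = within_band(atoms)
        clean = ok and not any(
            cdist(atoms, coords).min() <= label_cutoff for coords in non_coords
        )
        if (ok, -result.fun) > (best_ok, -best_loss):
            best_loss, best, best_ok = result.fun, result.x, ok
        if clean:
            break

    atoms = cube_at(best)
    offenders = [
        r.res_seq
        for r, coords in zip(site, site_coords)
        if abs(cdist(atoms, coords).min() - gap) > gap_tolerance
    ]
    if offenders:
        raise ContractError(
            f"cannot place modulator at {gap}±{gap_tolerance} Å from residues "
            f"{offenders}; try a smaller or more contiguous site"
        )

    serial = max(a.serial for a in structure.all_atoms()) + 1
    ligand = Residue(
        chain_id=chain_id,
        res_seq=max(by_seq) + 100,
        icode="",
        res_name="LIG",
        atoms=[
            Atom(serial + k, f"C{k + 1}", "C", atoms[k], 1.70, is_hetero=True)
            for k in range(len(atoms))
        ],
    )
    holo = Structure(
        id=structure.id,
        chains={cid: list(res) for cid, res in structure.chains.items()},
        ligand_groups=list(structure.ligand_groups) + [ligand],
    )

    truth = {
        r.identity(holo.id)
        for r in chain
        if cdist(atoms, r.heavy_coords()).min() <= label_cutoff
    }
    return holo, truth


def make_holo_fixture(
    seed: int,
    n_res: int | None = None,
    site_size: int | None = None,
    gap: float = 3.5,
) -> tuple[Structure, FixtureSpec, set[str]]:
    """Convenience generator: helix + mid-chain site + planted modulator."""
    rng = np.random.default_rng(seed)
    if n_res is None:
        n_res = int(rng.integers(20, 31))
    if site_size is None:
        site_size = int(rng.integers(3, 5))
    # one face of the helix: offsets 0, 3, 4, 7 share an azimuthal sector
    offsets = (0, 3, 4, 7)[:site_size]
    start = (n_res - offsets[-1]) // 2 + 1
    spec = FixtureSpec(
        n_res=n_res,
        site_residues=tuple(start + o for o in offsets),
        modulator_gap=gap,
        seed=seed,
    )
    apo = make_helix_structure(spec)
    holo, truth = plant_modulator(apo, spec.site_residues, gap, seed=seed)
    return holo, spec, truth


# ---------------------------------------------------------------------------
# Synthetic descriptor tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableSpec:
    n_pos: int
    n_neg: int
    n_features: int
    n_informative: int
    shift: float
    residue_mix: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ContractError("counts must be > 0")
        if not (0 <= self.n_informative <= self.n_features):
            raise ContractError("need 0 <= n_informative <= n_features")
        if self.shift < 0:
            raise ContractError("shift must be >= 0")


def synth_feature_table(spec: TableSpec) -> DescriptorTable:
    """Gaussian table: positive rows are shifted by ``spec.shift`` standard
    deviations on the first ``n_informative`` columns; everything else is
    standard normal.  Fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    x = rng.standard_normal((n, spec.n_features))
    x[: spec.n_pos, : spec.n_informative] += spec.shift

    if spec.residue_mix is None:
        names = list(STANDARD_RESIDUES)
        probs = np.full(len(names), 1.0 / len(names))
    else:
        names = list(spec.residue_mix)
        probs = np.asarray(list(spec.residue_mix.values()), dtype=float)
        probs = probs / probs.sum()
    res_names = rng.choice(names, size=n, p=probs)

    frame = pd.DataFrame(x, columns=[f"f{i:03d}" for i in range(spec.n_features)])
    frame.insert(0, "identity", [f"T{spec.seed}_r{i:05d}" for i in range(n)])
    frame.insert(1, "chain", f"T{spec.seed}_A")
    frame.insert(2, "res_name", res_names)
    frame.insert(3, "label", ["AFR"] * spec.n_pos + ["FR"] * spec.n_neg)
    provenance = {
        "generator": "synth_feature_table",
        "spec": {
            "n_pos": spec.n_pos, "n_neg": spec.n_neg,
            "n_features": spec.n_features, "n_informative": spec.n_informative,
            "shift": spec.shift, "seed": spec.seed,
        },
    }
    return DescriptorTable(frame=frame, provenance=provenance)
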