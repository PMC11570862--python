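"""Per-residue internal-nanoenvironment descriptors.

Each descriptor has an explicit, documented operationalization; every
constant entering a computation is recorded in the table's provenance
snapshot.  Descriptors are computed on the unbound (modulator-free) form so
no feature encodes the label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import _data
from .errors import ContractError
from .sasa import compute_asa, relative_asa
from .structures import Atom, Residue, Structure, centroid, min_heavy_distance

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0636  # kcal·Å·mol⁻¹·e⁻²
KS_COUPLING = 0.084 * 332.0  # Kabsch–Sander electrostatic prefactor, kcal/mol
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol; weaker contacts are not H-bonds

#: formal charges: res_name -> (atom name, charge)
_SIDECHAIN_CHARGES = {
    "LYS": ("NZ", +1.0),
    "ARG": ("CZ", +1.0),
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
    "HIS": ("CE1", +0.5),
}


@dataclass
class NanoenvConfig:
    contact_cutoff: float = 5.0
    sponge_radius: float = 10.0
    sponge_grid: float = 1.0
    hydrophobicity_cutoff: float = 6.5
    probe_radius: float = 1.4
    n_points: int = 960
    residue_one_hot: bool = False


@dataclass
class DescriptorTable:
    """Residue × descriptor matrix with identity keys, labels, provenance."""

    frame: pd.DataFrame  # columns: identity, chain, res_name, label, <descriptors>
    provenance: dict = field(default_factory=dict)

    META_COLUMNS = ("identity", "chain", "res_name", "label")

    @property
    def descriptor_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.META_COLUMNS]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DescriptorTable":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame=frame, provenance=provenance)


# ---------------------------------------------------------------------------
# Scalar descriptors
# ---------------------------------------------------------------------------


def distance_to_cg(residue: Residue, chain_atoms: Sequence[Atom]) -> float:
    """Distance from the residue's heavy-atom centroid to the chain's
    heavy-atom centroid (geometric centre, unweighted)."""
    heavy = [a for a in chain_atoms if a.is_heavy]
    if not heavy:
        raise ContractError("chain has no heavy atoms")
    return float(np.linalg.norm(centroid(residue.heavy_atoms) - centroid(heavy)))


def build_contact_graph(
    residues: Sequence[Residue], cutoff: float = 5.0, structure_id: str = ""
) -> nx.Graph:
    """Residue contact graph: edge iff min heavy-atom distance ≤ cutoff."""
    if not residues:
        raise ContractError("empty residue collection")
    graph = nx.Graph()
    idents = [r.identity(structure_id) for r in residues]
    coords = [r.heavy_coords() for r in residues]
    graph.add_nodes_from(idents)
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            d = float(cdist(coords[i], coords[j]).min())
            if d <= cutoff:
                graph.add_edge(idents[i], idents[j], distance=d)
    return graph


def graph_eccentricity(graph: nx.Graph, node: str) -> int:
    """Max shortest-path hop count to any node in ``node``'s component."""
    if node not in graph:
        raise KeyError(node)
    lengths = nx.single_source_shortest_path_length(graph, node)
    return int(max(lengths.values()))


def graph_bottleneck(graph: nx.Graph, node: str) -> float:
    """Betweenness centrality of ``node`` (standard 2/((n−1)(n−2))
    normalization for undirected graphs)."""
    if node not in graph:
        raise KeyError(node)
    return float(nx.betweenness_centrality(graph, normalized=True)[node])


def sponge_fraction(
    structure: Structure,
    residue: Residue,
    radius: float = 10.0,
    grid: float = 1.0,
) -> float:
    """Void fraction of a grid-sampled ball around the residue centroid.

    The cubic grid is anchored at the residue's heavy-atom centroid, so the
    value is deterministic and rigid-motion invariant up to grid placement.
    """
    if not (radius > grid > 0):
        raise ContractError("require radius > grid > 0")
    centre = centroid(residue.heavy_atoms)
    n = int(np.floor(radius / grid))
    axis = np.arange(-n, n + 1) * grid
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius] + centre

    atoms = [a for a in structure.all_atoms() if a.is_heavy]
    coords = np.asarray([a.coord for a in atoms])
    radii = np.asarray([a.vdw_radius for a in atoms])
    tree = cKDTree(coords)
    near = tree.query_ball_point(centre, radius + float(radii.max()))
    occupied = np.zeros(len(pts), dtype=bool)
    if near:
        d2 = ((pts[:, None, :] - coords[near][None, :, :]) ** 2).sum(axis=2)
        occupied = (d2 < radii[near] ** 2).any(axis=1)
    return float((~occupied).mean())


def hydrophobicity_env(
    chain: Sequence[Residue], residue: Residue, cutoff: float = 6.5
) -> float:
    """Mean Kyte–Doolittle index over the residue and every chain residue
    within ``cutoff`` Å (heavy-atom minimum distance), self included."""
    table = _data.kyte_doolittle()
    values = []
    for other in chain:
        if other is residue or min_heavy_distance(residue, other) <= cutoff:
            if other.res_name in table:
                values.append(table[other.res_name])
    if not values:
        raise ContractError(
            f"no standard residues in the {cutoff} Å neighbourhood of "
            f"{residue.res_name} {residue.res_seq}"
        )
    return float(np.mean(values))


def _charge_sites(structure: Structure) -> list[tuple[Residue, np.ndarray, float]]:
    sites: list[tuple[Residue, np.ndarray, float]] = []
    for chain in structure.chains.values():
        for res in chain:
            rule = _SIDECHAIN_CHARGES.get(res.res_name)
            if rule is not None:
                atom = res.atom(rule[0])
                if atom is not None:
                    sites.append((res, atom.coord, rule[1]))
        # termini: +1 on the first residue's backbone N, −1 on the last
        # residue's OXT (or C when OXT is absent)
        n_term = chain[0].atom("N")
        if n_term is not None:
            sites.append((chain[0], n_term.coord, +1.0))
        c_term = chain[-1].atom("OXT") or chain[-1].atom("C")
        if c_term is not None:
            sites.append((chain[-1], c_term.coord, -1.0))
    return sites


def electrostatic_potential(structure: Structure, residue: Residue) -> float:
    """Coulomb potential at the residue's Cα (else first heavy atom) from
    formal charges, with distance-dependent dielectric ε(r) = 4r and the
    distance floored at 2 Å.  Charges on the residue itself are excluded."""
    ref = residue.atom("CA") or (residue.heavy_atoms[0] if residue.heavy_atoms else None)
    if ref is None:
        raise ContractError("residue has no reference atom")
    potential = 0.0
    for res, coord, q in _charge_sites(structure):
        if res is residue:
            continue
        r = max(float(np.linalg.norm(ref.coord - coord)), 2.0)
        potential += COULOMB_CONSTANT * q / (4.0 * r * r)
    return potential


def kabsch_sander_pairs(chain: Sequence[Residue]) -> dict[tuple[int, int], float]:
    """Accepted backbone H-bonds ``(donor index, acceptor index) -> energy``.

    Kabsch–Sander electrostatic model with the amide H rebuilt 1 Å from N
    along the preceding C=O direction; a pair counts as a bond only when
    its energy beats the −0.5 kcal/mol cutoff.
    """
    n_res = len(chain)
    h_pos: dict[int, np.ndarray] = {}
    for i in range(1, n_res):
        if chain[i].res_name == "PRO":
            continue
        n = chain[i].atom("N")
        c_prev = chain[i - 1].atom("C")
        o_prev = chain[i - 1].atom("O")
        if n is None or c_prev is None or o_prev is None:
            continue
        direction = c_prev.coord - o_prev.coord
        norm = np.linalg.norm(direction)
        if norm > 0:
            h_pos[i] = n.coord + direction / norm

    bonds: dict[tuple[int, int], float] = {}
    for i in h_pos:  # donor residue
        n_atom = chain[i].atom("N")
        for j in range(n_res):  # acceptor residue
            if abs(i - j) < 2:
                continue
            c = chain[j].atom("C")
            o = chain[j].atom("O")
            if c is None or o is None:
                continue
            r_on = np.linalg.norm(o.coord - n_atom.coord)
            r_ch = np.linalg.norm(c.coord - h_pos[i])
            r_oh = np.linalg.norm(o.coord - h_pos[i])
            r_cn = np.linalg.norm(c.coord - n_atom.coord)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clash: not a meaningful bond
                continue
            energy = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < HBOND_ENERGY_CUTOFF:
                bonds[(i, j)] = energy
    return bonds


def kabsch_sander_energies(chain: Sequence[Residue]) -> dict[int, tuple[float, float]]:
    """Best (most negative) donor and acceptor H-bond energy per residue;
    0 when the residue forms no bond in that role."""
    donor = {i: 0.0 for i in range(len(chain))}
    acceptor = {i: 0.0 for i in range(len(chain))}
    for (i, j), energy in kabsch_sander_pairs(chain).items():
        donor[i] = min(donor[i], energy)
        acceptor[j] = min(acceptor[j], energy)
    return {i: (donor[i], acceptor[i]) for i in range(len(chain))}


def hbond_energies(chain: Sequence[Residue], residue: Residue) -> tuple[float, float]:
    """(donor_energy, acceptor_energy) of ``residue`` within its chain."""
    for i, res in enumerate(chain):
        if res is residue:
            return kabsch_sander_energies(chain)[i]
    raise ContractError("residue not found in chain")


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------


def compute_descriptor_table(
    structures: Sequence[Structure],
    labels: pd.DataFrame,
    config: NanoenvConfig | None = None,
) -> DescriptorTable:
    """One descriptor row per labelled residue.

    ``structures`` must be the unbound forms (modulator stripped); ``labels``
    is the labeling table (columns identity, chain, res_name, label).  A
    descriptor that fails on a residue is set to 0 and flagged in a
    companion ``<name>_missing`` indicator column.
    """
    if config is None:
        config = NanoenvConfig()
    wanted = set(labels["identity"])
    rows: list[dict] = []
    missing_counts: dict[str, int] = {}

    for structure in structures:
        asa = compute_asa(
            structure,
            probe_radius=config.probe_radius,
            n_points=config.n_points,
            include_hetero=False,
        )
        for chain_id, chain in structure.chains.items():
            chain_atoms = [a for r in chain for a in r.atoms]
            graph = build_contact_graph(
                chain, cutoff=config.contact_cutoff, structure_id=structure.id
            )
            betweenness = nx.betweenness_centrality(graph, normalized=True)
            hbonds = kabsch_sander_energies(chain)
            for i, res in enumerate(chain):
                ident = res.identity(structure.id)
                if ident not in wanted:
                    continue
                row: dict = {"identity": ident}
                computations = {
                    "relative_asa": lambda: relative_asa(
                        asa.per_residue[ident], res.res_name
                    ),
                    "distance_to_cg": lambda: distance_to_cg(res, chain_atoms),
                    "sponge": lambda: sponge_fraction(
                        structure, res, radius=config.sponge_radius,
                        grid=config.sponge_grid,
                    ),
                    "hydrophobicity_env": lambda: hydrophobicity_env(
                        chain, res, cutoff=config.hydrophobicity_cutoff
                    ),
                    "electrostatic_potential": lambda: electrostatic_potential(
                        structure, res
                    ),
                    "donor_energy": lambda: hbonds[i][0],
                    "acceptor_energy": lambda: hbonds[i][1],
                    "eccentricity": lambda: float(graph_eccentricity(graph, ident)),
                    "bottleneck": lambda: float(betweenness[ident]),
                }
                for name, fn in computations.items():
                    try:
                        row[name] = float(fn())
                        row[f"{name}_missing"] = 0.0
                    except (ContractError, KeyError) as exc:
                        logger.warning("%s on %s failed: %s", name, ident, exc)
                        row[name] = 0.0
                        row[f"{name}_missing"] = 1.0
                        missing_counts[name] = missing_counts.get(name, 0) + 1
                rows.append(row)

    if not rows:
        raise ContractError("no labelled residues matched the given structures")

    values = pd.DataFrame(rows)
    # drop all-zero indicator columns (no failures for that descriptor)
    for col in [c for c in values.columns if c.endswith("_missing")]:
        if (values[col] == 0.0).all():
            values = values.drop(columns=col)

    frame = labels[["identity", "chain", "res_name", "label"]].merge(
        values, on="identity", how="inner"
    )
    unmatched = wanted - set(frame["identity"])
    if unmatched:
        raise ContractError(
            f"labels cover residues absent from the structures: {sorted(unmatched)[:5]}"
        )
    if config.residue_one_hot:
        for res_name in _data.STANDARD_RESIDUES:
            frame[f"is_{res_name}"] = (frame["res_name"] == res_name).astype(float)

    provenance = {
        "config": asdict(config),
        "coulomb_constant": COULOMB_CONSTANT,
        "hbond_energy_cutoff": HBOND_ENERGY_CUTOFF,
        "vdw_radii": _data.vdw_radii(),
        "n_structures": len(structures),
        "missing_counts": missing_counts,
    }
    return DescriptorTable(frame=frame, provenance=provenance)
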