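"""Per-residue buried-area (LASA) computation and AFR/FR labeling.

A residue is labelled AFR when its minimum heavy-atom distance to the
modulator group is at or below the distance cutoff (default 5 Å).  LASA —
the residue's accessible-surface-area loss between the unbound and the
complexed state — is computed alongside and stored, but does not drive the
label unless explicitly requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ContractError, ResidueMismatchError
from .sasa import compute_asa
from .structures import (
    Structure,
    min_heavy_distance,
    read_structure,
    select_modulator,
    strip_group,
)

logger = logging.getLogger(__name__)

LASA_CLAMP = 1e-6


@dataclass
class ResidueRecord:
    """One labelled residue: the unit of classification."""

    identity: str
    res_name: str
    chain_id: str
    lasa: float
    min_dist_modulator: float | None
    label: str  # "AFR" or "FR"

    def __post_init__(self) -> None:
        if self.label not in ("AFR", "FR"):
            raise ContractError(f"label must be AFR or FR, got {self.label!r}")
        if self.label == "AFR" and self.min_dist_modulator is None:
            raise ContractError("AFR label requires a modulator distance")


def _chain_local_key(structure: Structure, residue) -> str:
    return f"{residue.chain_id}_{residue.res_seq}{residue.icode}_{residue.res_name}"


def compute_lasa(
    holo: Structure,
    apo: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[str, float]:
    """Per-residue ASA(apo) − ASA(complex), keyed by holo residue identity.

    Both ASA calls use identical probe and point count; near-zero values
    (< 1e-6 Å²) are clamped to exactly 0.
    """
    holo_map = {
        _chain_local_key(holo, r): r.identity(holo.id) for r in holo.iter_residues()
    }
    apo_map = {_chain_local_key(apo, r) for r in apo.iter_residues()}
    only_holo = sorted(set(holo_map) - apo_map)
    only_apo = sorted(apo_map - set(holo_map))
    if only_holo or only_apo:
        raise ResidueMismatchError(
            f"holo/apo residue sets differ; holo-only={only_holo[:5]}, "
            f"apo-only={only_apo[:5]}"
        )

    asa_complex = compute_asa(
        holo, probe_radius=probe_radius, n_points=n_points, include_hetero=True
    )
    asa_apo = compute_asa(
        apo, probe_radius=probe_radius, n_points=n_points, include_hetero=True
    )
    apo_by_local = {
        _chain_local_key(apo, r): asa_apo.per_residue[r.identity(apo.id)]
        for r in apo.iter_residues()
    }

    lasa: dict[str, float] = {}
    for res in holo.iter_residues():
        ident = res.identity(holo.id)
        value = apo_by_local[_chain_local_key(holo, res)] - asa_complex.per_residue[ident]
        lasa[ident] = 0.0 if value < LASA_CLAMP else value
    return lasa


def label_residues(
    holo: Structure,
    modulator: str | None = "auto",
    distance_cutoff: float = 5.0,
    apo: Structure | None = None,
    require_positive_lasa: bool = False,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> list[ResidueRecord]:
    """Label every polymer residue of ``holo`` as AFR or FR.

    ``modulator`` is a ligand group key; ``"auto"`` selects the largest
    hetero group with at least 6 heavy atoms and raises if none exists
    (pass the key explicitly in that case).  ``modulator=None`` means
    "no modulator": every residue is FR.  When ``apo`` is omitted it is
    derived by stripping the modulator group (rigid approximation).
    """
    if modulator == "auto":
        modulator = select_modulator(holo)  # ContractError when nothing qualifies

    if modulator is None:
        return [
            ResidueRecord(
                identity=r.identity(holo.id),
                res_name=r.res_name,
                chain_id=r.chain_id,
                lasa=0.0,
                min_dist_modulator=None,
                label="FR",
            )
            for r in holo.iter_residues()
        ]

    group = holo.get_ligand(modulator)
    if not group.heavy_atoms:
        raise ContractError(f"modulator group {modulator} has no heavy atoms")
    if apo is None:
        apo = strip_group(holo, modulator)
    lasa = compute_lasa(holo, apo, probe_radius=probe_radius, n_points=n_points)

    records = []
    for res in holo.iter_residues():
        ident = res.identity(holo.id)
        dist = min_heavy_distance(res, group)
        is_afr = dist <= distance_cutoff
        if require_positive_lasa:
            is_afr = is_afr and lasa[ident] > 0.0
        records.append(
            ResidueRecord(
                identity=ident,
                res_name=res.res_name,
                chain_id=res.chain_id,
                lasa=lasa[ident],
                min_dist_modulator=dist,
                label="AFR" if is_afr else "FR",
            )
        )
    return records


def records_to_frame(structure: Structure, records: Sequence[ResidueRecord]) -> pd.DataFrame:
    rows = [
        {
            "identity": r.identity,
            "res_name": r.res_name,
            "chain": f"{structure.id}_{r.chain_id}",
            "lasa": r.lasa,
            "min_dist_modulator": r.min_dist_modulator,
            "label": r.label,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def build_dataset(
    structures: Sequence[tuple],
    distance_cutoff: float = 5.0,
    n_points: int = 960,
) -> tuple[pd.DataFrame, list[str]]:
    """Label a collection of holo structures into one table.

    ``structures`` holds ``(holo, apo_or_None, modulator_or_"auto")`` triples
    where the structure slots accept either paths or :class:`Structure`
    objects.  Failures are recorded in the returned error ledger and the run
    continues; an empty result raises.
    """
    frames: list[pd.DataFrame] = []
    errors: list[str] = []
    for entry in structures:
        holo, apo, modulator = (tuple(entry) + ("auto",))[:3]
        try:
            if not isinstance(holo, Structure):
                holo = read_structure(Path(holo))
            if apo is not None and not isinstance(apo, Structure):
                apo = read_structure(Path(apo))
            records = label_residues(
                holo,
                modulator=modulator,
                distance_cutoff=distance_cutoff,
                apo=apo,
                n_points=n_points,
            )
            frame = records_to_frame(holo, records)
            n_afr = int((frame["label"] == "AFR").sum())
            for chain, count in frame.groupby("chain").size().items():
                logger.info("%s: %d residues (%d AFR total)", chain, count, n_afr)
            frames.append(frame)
        except (ContractError, KeyError, OSError) as exc:
            errors.append(f"{holo if isinstance(holo, str) else getattr(holo, 'id', holo)}: {exc}")
    if not frames:
        raise ContractError(f"no structures labelled successfully; errors: {errors}")
    table = pd.concat(frames, ignore_index=True)
    dup = table["identity"].duplicated()
    if dup.any():
        raise ContractError(
            f"duplicate residue identities: {sorted(table['identity'][dup])[:5]}"
        )
    return table, errors
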