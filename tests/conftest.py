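"""Shared fixtures.  Structure fixtures are session-scoped: they are
deterministic and read-only for every test that uses them."""

from __future__ import annotations

import numpy as np
import pytest

from allores.labeling import label_residues
from allores.structures import Atom, Residue, Structure
from allores.synthetic import FixtureSpec, make_helix_structure, plant_modulator


@pytest.fixture(scope="session")
def helix20() -> Structure:
    return make_helix_structure(FixtureSpec(n_res=20, seed=1))


@pytest.fixture(scope="session")
def holo_case():
    """(holo structure, ground-truth identity set, fixture spec)."""
    spec = FixtureSpec(n_res=20, site_residues=(9, 12, 13), modulator_gap=3.5, seed=1)
    apo = make_helix_structure(spec)
    holo, truth = plant_modulator(apo, spec.site_residues, spec.modulator_gap, seed=1)
    return holo, truth, spec


@pytest.fixture(scope="session")
def holo_records(holo_case):
    holo, _, _ = holo_case
    return label_residues(holo)


def single_atom_structure(element="C", radius=1.70, coord=(0.0, 0.0, 0.0), sid="ONE"):
    atom = Atom(1, "CA", element, np.asarray(coord), radius)
    res = Residue("A", 1, "", "ALA", [atom])
    return Structure(id=sid, chains={"A": [res]})


def structure_from_points(points, radius=1.70, sid="PTS", res_name="ALA"):
    """One single-atom residue per coordinate; handy for geometric oracles."""
    chain = [
        Residue("A", i + 1, "", res_name,
                [Atom(i + 1, "CA", "C", np.asarray(p, dtype=float), radius)])
        for i, p in enumerate(points)
    ]
    return Structure(id=sid, chains={"A": chain})
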