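"""Loaders for the small bundled lookup tables (shipped as plain TSV/TXT)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

_PKG = "allores.data"

#: Fallback van der Waals radius for elements absent from the bundled table.
DEFAULT_VDW_RADIUS = 1.70

#: The 20 canonical amino-acid residue types.
STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


def _read_tsv(name: str) -> dict[str, float]:
    text = resources.files(_PKG).joinpath(name).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key.upper()] = float(value)
    return table


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    return _read_tsv("vdw_radii.tsv")


@lru_cache(maxsize=None)
def max_asa() -> dict[str, float]:
    return _read_tsv("max_asa.tsv")


@lru_cache(maxsize=None)
def kyte_doolittle() -> dict[str, float]:
    return _read_tsv("kyte_doolittle.tsv")


@lru_cache(maxsize=None)
def buffer_exclusions() -> frozenset[str]:
    text = resources.files(_PKG).joinpath("buffer_exclusions.txt").read_text()
    names = {
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(names)
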