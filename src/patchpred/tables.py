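"""Loaders for the small physico-chemical lookup tables shipped as package data.

Every table is a plain TSV so that users can substitute their own (radius sets,
accessibility references, hydropathy scales) through the config paths.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path


def _read_tsv(path_or_trav) -> list[list[str]]:
    if hasattr(path_or_trav, "read_text"):
        text = path_or_trav.read_text()
    else:
        text = Path(path_or_trav).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _data_file(name: str):
    return resources.files("patchpred.data").joinpath(name)


@lru_cache(maxsize=None)
def vdw_radii(path: str | None = None) -> dict[str, float]:
    """Per-element van der Waals radii in Angstrom; key ``X`` is the fallback."""
    rows = _read_tsv(path if path else _data_file("vdw_radii.tsv"))
    return {el: float(r) for el, r in rows}


@lru_cache(maxsize=None)
def max_asa(path: str | None = None) -> dict[str, float]:
    """Per-residue-type maximum ASA (Gly-X-Gly reference) in A^2."""
    rows = _read_tsv(path if path else _data_file("max_asa.tsv"))
    return {res: float(a) for res, a in rows}


@lru_cache(maxsize=None)
def kyte_doolittle(path: str | None = None) -> dict[str, float]:
    """Kyte-Doolittle hydropathy values keyed by 3-letter residue type."""
    rows = _read_tsv(path if path else _data_file("kyte_doolittle.tsv"))
    return {res: float(h) for res, h in rows}


@lru_cache(maxsize=None)
def hbond_chemistry(path: str | None = None) -> list[dict]:
    """Donor/acceptor definitions: residue ('*' = any), atom, role, antecedent."""
    rows = _read_tsv(path if path else _data_file("hbond_chemistry.tsv"))
    return [
        {
            "residue": res,
            "atom": atom,
            "role": role,
            "antecedent": ante,
            "h_computable": hc == "1",
        }
        for res, atom, role, ante, hc in rows
    ]


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def element_radius(element: str, radii: dict[str, float] | None = None) -> float:
    radii = radii if radii is not None else vdw_radii()
    return radii.get(element.upper(), radii.get("X", 1.80))
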