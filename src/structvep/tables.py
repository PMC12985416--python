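"""Residue-level reference tables used by the feature extractors.

All scales ship as editable JSON (``data/scales.json``) so a user can swap a
hydrophobicity or max-ASA reference without touching code.  Values are keyed by
one-letter amino-acid codes; element-keyed van der Waals radii carry an ``X``
fallback entry for unusual elements.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


@lru_cache(maxsize=1)
def _scales() -> dict:
    ref = resources.files("structvep.data").joinpath("scales.json")
    with ref.open("r") as fh:
        raw = json.load(fh)
    return {
        name: {k: v for k, v in table.items() if k != "comment"}
        for name, table in raw.items()
    }


def scale(name: str) -> dict[str, float]:
    """Return one named scale table (e.g. ``"hydrophobicity"``, ``"max_asa"``)."""
    tables = _scales()
    if name not in tables:
        raise KeyError(f"unknown scale table {name!r}; have {sorted(tables)}")
    return dict(tables[name])


@lru_cache(maxsize=1)
def background_frequencies() -> dict[str, float]:
    """BLOSUM62 background amino-acid frequencies, normalized to sum to 1."""
    freq = scale("aa_frequency")
    total = sum(freq.values())
    return {a: f / total for a, f in freq.items()}


@lru_cache(maxsize=1)
def vdw_radii() -> dict[str, float]:
    return scale("vdw_radii")


def vdw_radius(element: str) -> float:
    radii = vdw_radii()
    return radii.get(element.upper(), radii["X"])


def max_asa(aa: str) -> float:
    table = scale("max_asa")
    if aa not in table:
        raise KeyError(f"no max-ASA reference for residue type {aa!r}")
    return table[aa]
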