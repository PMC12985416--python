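"""Per-residue structural features from predicted protein structures.

Predicted models (AlphaFold2 convention) store the per-residue confidence
score pLDDT in the B-factor field, constant across the atoms of a residue; we
read the C-alpha value.  Solvent accessible surface area is computed with the
Shrake-Rupley rolling-probe algorithm on a deterministic Fibonacci sphere
point set, and relative accessibility (rASA) divides residue SASA by the
theoretical maximum ASA of the residue type.  rASA can exceed 1 with
theoretical maxima; values are reported unclamped and flagged above 1.2 so the
downstream model sees the untruncated distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import tables

logger = logging.getLogger(__name__)

RASA_FLAG_THRESHOLD = 1.2


@dataclass
class Atom:
    element: str
    x: float
    y: float
    z: float
    radius: float


@dataclass
class Residue:
    index: int  # 1-based
    aa: str
    atoms: list[Atom]
    plddt: float


@dataclass
class StructureModel:
    accession: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ResidueStructFeatures:
    index: int
    aa: str
    plddt: float
    sasa: float
    rasa: float


def parse_structure(path: str | Path, accession: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a StructureModel.

    Expects one chain of full residue coverage (contiguous 1-based indices);
    chain breaks raise an error listing the missing indices.  pLDDT is taken
    from the C-alpha temperature factor (falling back to the first atom for
    residues without a C-alpha, e.g. coarse fixtures).
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"no model/chain in {path}")
    chain = st[0][0]
    residues: list[Residue] = []
    for res in chain:
        tab = gemmi.find_tabulated_residue(res.name)
        one = tab.one_letter_code.upper() if tab else "X"
        atoms = []
        plddt = None
        for atom in res:
            el = atom.element.name if atom.element else "X"
            atoms.append(
                Atom(el, atom.pos.x, atom.pos.y, atom.pos.z, tables.vdw_radius(el))
            )
            if atom.name == "CA":
                plddt = atom.b_iso
        if plddt is None:
            plddt = res[0].b_iso
        if plddt is None or math.isnan(plddt):
            raise ValueError(f"no pLDDT channel (temperature factor) in {path}")
        if not 0.0 <= plddt <= 100.0:
            raise ValueError(f"pLDDT {plddt} out of [0, 100] at residue {res.seqid.num}")
        residues.append(Residue(res.seqid.num, one, atoms, float(plddt)))
    indices = [r.index for r in residues]
    expected = list(range(1, len(residues) + 1))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))
        raise ValueError(f"chain break in {path}: missing residue indices {missing}")
    return StructureModel(accession or path.stem, residues)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley SASA per atom, in square Angstrom.

    For each atom, test points are placed on a sphere of radius
    ``r_atom + probe`` and the exposed fraction (points outside every other
    atom's expanded sphere) scales the expanded-sphere area.
    """
    if n_points < 10:
        raise ValueError("n_points < 10 gives insufficient surface sampling")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("every atom must have a positive radius")
    n = len(coords)
    expanded = radii + probe_radius
    unit = fibonacci_sphere(n_points)
    sasa = np.empty(n)
    tree = cKDTree(coords)
    reach = 2.0 * expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], reach) if j != i]
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            # <= so a point exactly on a coincident atom's surface counts buried
            buried = (d2 <= (expanded[nb] ** 2)[None, :] + 1e-9).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = frac * 4.0 * math.pi * expanded[i] ** 2
    return sasa


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[int, float]:
    """Per-residue SASA map (residue SASA = sum over its atoms)."""
    if len(model) == 0:
        raise ValueError("empty structure model")
    coords, radii, owner = [], [], []
    for res in model.residues:
        for a in res.atoms:
            coords.append([a.x, a.y, a.z])
            radii.append(a.radius)
            owner.append(res.index)
    atom_sasa = compute_atom_sasa(
        np.array(coords), np.array(radii), probe_radius, n_points
    )
    out: dict[int, float] = {r.index: 0.0 for r in model.residues}
    for idx, s in zip(owner, atom_sasa):
        out[idx] += float(s)
    return out


def compute_rasa(
    sasa: float, aa: str, max_asa_table: dict[str, float] | None = None
) -> float:
    """Relative accessibility: residue SASA over the max ASA of its type."""
    if sasa < 0:
        raise ValueError("SASA must be non-negative")
    table = max_asa_table if max_asa_table is not None else tables.scale("max_asa")
    if aa not in table:
        raise KeyError(f"unknown residue type {aa!r} for max-ASA normalization")
    return sasa / table[aa]


def residue_features(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    max_asa_table: dict[str, float] | None = None,
) -> dict[int, ResidueStructFeatures]:
    """pLDDT + SASA + rASA for every residue of a parsed structure."""
    sasa_map = compute_sasa(model, probe_radius, n_points)
    out = {}
    for res in model.residues:
        sasa = sasa_map[res.index]
        rasa = compute_rasa(sasa, res.aa, max_asa_table)
        if rasa > RASA_FLAG_THRESHOLD:
            logger.info(
                "rASA %.2f > %.1f at %s residue %d (kept unclamped)",
                rasa, RASA_FLAG_THRESHOLD, model.accession, res.index,
            )
        out[res.index] = ResidueStructFeatures(res.index, res.aa, res.plddt, sasa, rasa)
    return out
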