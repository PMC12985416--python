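"""Sequence-derived variant features and feature-vector assembly.

The conservation signal is a position-specific independent-counts (PSIC)
profile: homologous sequences in an alignment are greedily clustered at a 62%
identity threshold, each cluster contributes a single independent count per
column (split over its members' residues; gaps contribute nothing), and
observed frequencies are regularized with a background pseudo-count before the
log-odds transform

    score(j, a) = ln( (c(j, a) + w * bg_a) / ((n_eff(j) + w) * bg_a) )

so scores are always finite.  DeltaPSIC is oriented wild-type minus variant:
positive for a disruptive substitution at a conserved position.

Substitution and physicochemical features come from standard tables (BLOSUM62
via Biopython; Kyte-Doolittle hydrophobicity, Zamyatnin volumes, Chou-Fasman
propensities, BLOSUM62 background frequencies from the shipped JSON scales).
The assembled vector follows one of two named schemas; FULL appends the two
gene-level features (protein length, GO-term count) to REDUCED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from . import tables
from .structfeat import ResidueStructFeatures
from .tables import AMINO_ACIDS
from .variantio import ProteinContext, VariantRecord

logger = logging.getLogger(__name__)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = set("-.")

REDUCED_FEATURES: list[str] = [
    "psic_wt",
    "psic_var",
    "delta_psic",
    "blosum62",
    "d_hydrophobicity",
    "d_volume",
    "wt_helix_propensity",
    "var_helix_propensity",
    "wt_sheet_propensity",
    "var_sheet_propensity",
    "wt_turn_propensity",
    "var_turn_propensity",
    "wt_frequency",
    "var_frequency",
    "plddt",
    "sasa",
    "rasa",
]
FULL_FEATURES: list[str] = REDUCED_FEATURES + ["protein_length", "go_term_count"]

SCHEMAS = {"FULL": FULL_FEATURES, "REDUCED": REDUCED_FEATURES}


def schema_features(schema: str) -> list[str]:
    key = schema.upper()
    if key not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected FULL or REDUCED")
    return list(SCHEMAS[key])


@dataclass
class Msa:
    """A query-anchored multiple sequence alignment (no insertions relative
    to the query are required; gap columns in the query are skipped by
    ``column_map``)."""

    query_id: str
    rows: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def query_row(self) -> str:
        return self.rows[self.ids.index(self.query_id)]

    @property
    def column_map(self) -> dict[int, int]:
        """Alignment column -> 1-based query position, for non-gap query columns."""
        mapping = {}
        pos = 0
        for col, ch in enumerate(self.query_row):
            if ch not in GAP_CHARS:
                pos += 1
                mapping[col] = pos
        return mapping

    @property
    def query_sequence(self) -> str:
        return "".join(ch for ch in self.query_row if ch not in GAP_CHARS)


def read_msa(path: str | Path, query_id: str | None = None) -> Msa:
    """Read an aligned FASTA; the query is the named row or the first row."""
    aln = AlignIO.read(str(path), "fasta")
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    return Msa(query_id or ids[0], rows, ids)


@dataclass
class PsicProfile:
    scores: np.ndarray  # (n_query_positions, 20) natural-log odds
    n_eff: np.ndarray  # per-column effective (independent) sequence count
    background: np.ndarray  # 20-vector, positive, sums to 1
    flagged_columns: list[int] = field(default_factory=list)  # all-gap columns

    def score(self, position: int, aa: str) -> float:
        """Log-odds score at a 1-based query position for one amino acid."""
        return float(self.scores[position - 1, AA_INDEX[aa]])


def _pairwise_identity(a: str, b: str) -> float:
    same = total = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        total += 1
        if x == y:
            same += 1
    return same / total if total else 0.0


def greedy_cluster(rows: list[str], identity: float) -> list[list[int]]:
    """Greedy single-pass clustering: a row joins the first cluster whose
    representative (first member) it matches at or above the identity
    threshold, else founds a new cluster."""
    clusters: list[list[int]] = []
    for i, row in enumerate(rows):
        for members in clusters:
            if _pairwise_identity(row, rows[members[0]]) >= identity:
                members.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def default_background(msa: Msa, min_rows: int = 10) -> np.ndarray:
    """Pooled amino-acid frequencies of the alignment (with +1 smoothing),
    falling back to the BLOSUM62 background for tiny alignments."""
    if len(msa.rows) < min_rows:
        bg = tables.background_frequencies()
        return np.array([bg[a] for a in AMINO_ACIDS])
    counts = np.ones(20)
    for row in msa.rows:
        for ch in row:
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
    return counts / counts.sum()


def compute_psic_profile(
    msa: Msa,
    background: np.ndarray | None = None,
    clustering_identity: float = 0.62,
    pseudo_weight: float = 1.0,
) -> PsicProfile:
    """Position-specific independent-counts conservation profile.

    Sequences are clustered once over the whole alignment; per column, each
    cluster with at least one non-gap member contributes one independent count
    split over its members' residues in proportion to their multiplicity.
    An all-gap column falls back to pure pseudo-counts (scores exactly 0) and
    is flagged.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    bg = (
        np.asarray(background, dtype=float)
        if background is not None
        else default_background(msa)
    )
    if bg.shape != (20,) or np.any(bg <= 0):
        raise ValueError("background must be a strictly positive 20-vector")
    bg = bg / bg.sum()

    clusters = greedy_cluster(msa.rows, clustering_identity)
    col_map = msa.column_map
    n_pos = len(col_map)
    scores = np.zeros((n_pos, 20))
    n_eff = np.zeros(n_pos)
    flagged: list[int] = []

    for col, qpos in col_map.items():
        counts = np.zeros(20)
        eff = 0.0
        for members in clusters:
            residues = [
                msa.rows[m][col] for m in members if msa.rows[m][col] in AA_INDEX
            ]
            if not residues:
                continue
            eff += 1.0
            share = 1.0 / len(residues)
            for ch in residues:
                counts[AA_INDEX[ch]] += share
        if eff == 0.0:
            flagged.append(qpos)
        freq = (counts + pseudo_weight * bg) / (eff + pseudo_weight)
        scores[qpos - 1] = np.log(freq / bg)
        n_eff[qpos - 1] = max(eff, 1.0)
    if flagged:
        logger.warning("PSIC: %d all-gap column(s) scored from pseudo-counts", len(flagged))
    return PsicProfile(scores, n_eff, bg, flagged)


def delta_psic(profile: PsicProfile, position: int, wt_aa: str, var_aa: str) -> float:
    """score(position, wt) - score(position, var); positive when the variant
    residue is less compatible with the column than the wild type."""
    return profile.score(position, wt_aa) - profile.score(position, var_aa)


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def substitution_score(wt_aa: str, var_aa: str) -> int:
    """Symmetric BLOSUM62 lookup."""
    if wt_aa not in AMINO_ACIDS or var_aa not in AMINO_ACIDS:
        raise KeyError(f"unknown amino-acid code in ({wt_aa!r}, {var_aa!r})")
    return int(_BLOSUM62[wt_aa, var_aa])


def physchem_features(wt_aa: str, var_aa: str) -> dict[str, float]:
    """Physicochemical deltas (variant minus wild type) plus per-residue
    secondary-structure propensities and background frequencies."""
    hydro = tables.scale("hydrophobicity")
    vol = tables.scale("volume")
    helix = tables.scale("helix_propensity")
    sheet = tables.scale("sheet_propensity")
    turn = tables.scale("turn_propensity")
    freq = tables.background_frequencies()
    return {
        "d_hydrophobicity": hydro[var_aa] - hydro[wt_aa],
        "d_volume": vol[var_aa] - vol[wt_aa],
        "wt_helix_propensity": helix[wt_aa],
        "var_helix_propensity": helix[var_aa],
        "wt_sheet_propensity": sheet[wt_aa],
        "var_sheet_propensity": sheet[var_aa],
        "wt_turn_propensity": turn[wt_aa],
        "var_turn_propensity": turn[var_aa],
        "wt_frequency": freq[wt_aa],
        "var_frequency": freq[var_aa],
    }


@dataclass
class FeatureVector:
    schema: str  # "FULL" | "REDUCED"
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = schema_features(self.schema)
        if self.names != expected:
            raise ValueError(f"feature names do not match schema {self.schema}")
        if len(self.values) != len(self.names):
            raise ValueError("value count does not match schema")
        if np.any(~np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"missing/non-finite feature value(s): {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def assemble_feature_vector(
    variant: VariantRecord,
    context: ProteinContext,
    struct: ResidueStructFeatures,
    profile: PsicProfile,
    schema: str = "FULL",
) -> FeatureVector:
    """Deterministic ordered feature vector for one mapped variant.

    Requires the structural features to refer to the variant position; any
    missing constituent raises naming the offending feature.
    """
    if struct.index != variant.position:
        raise ValueError(
            f"structural features are for residue {struct.index}, "
            f"variant is at {variant.position}"
        )
    values: dict[str, float] = {
        "psic_wt": profile.score(variant.position, variant.wt_aa),
        "psic_var": profile.score(variant.position, variant.var_aa),
        "delta_psic": delta_psic(profile, variant.position, variant.wt_aa, variant.var_aa),
        "blosum62": float(substitution_score(variant.wt_aa, variant.var_aa)),
    }
    values.update(physchem_features(variant.wt_aa, variant.var_aa))
    values.update({"plddt": struct.plddt, "sasa": struct.sasa, "rasa": struct.rasa})
    if schema.upper() == "FULL":
        values["protein_length"] = float(context.length)
        values["go_term_count"] = float(context.go_term_count)
    names = schema_features(schema)
    missing = [n for n in names if n not in values]
    if missing:
        raise ValueError(f"missing feature constituent(s): {missing}")
    return FeatureVector(schema.upper(), names, np.array([values[n] for n in names]))
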