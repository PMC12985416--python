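"""Seeded synthetic fixtures with planted class structure.

Every generator is a pure function of (config, seed): proteins are random
sequences laid on an ideal alpha-helix with one dummy side-chain sphere per
residue (so interior residues are occluded and termini exposed), pLDDT is
high in the core and low in disordered terminal segments, and alignments emit
the query residue with a per-position conservation probability.  Pathogenic
variants are planted preferentially at conserved, buried, high-confidence
positions with dissimilar substitutions, benign variants at the opposite
extreme with conservative substitutions; emitted labels are flipped with a
small noise probability and the manifest records every planted quantity and
direction, so tests assert signal recovery rather than a hard-coded sign.

Comparator scores follow a binormal model with a target AUROC: positive-class
scores ~ N(mu, 1), negatives ~ N(0, 1) with mu = sqrt(2) * PhiInv(AUROC),
squashed to [0, 1] by the logistic map (a monotone transform, so the AUROC is
preserved exactly in expectation).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3
from scipy.special import expit
from scipy.stats import norm

from . import structfeat, tables
from .seqfeat import AA_INDEX, Msa, substitution_score
from .structfeat import Atom, Residue, StructureModel
from .tables import AMINO_ACIDS
from .variantio import (
    Label,
    Origin,
    ProteinContext,
    VariantRecord,
    harmonize_label,
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    The effect weights are dimensionless log-linear sampling weights: the
    probability that a pathogenic variant lands on a position scales with
    ``exp(conservation_gap * z_cons + burial_gap * z_buried + plddt_gap *
    z_plddt)`` and benign variants use the negated exponent.
    """

    seed: int = 0
    n_proteins: int = 16
    length_range: tuple[int, int] = (120, 220)
    n_variants: int = 2000
    pathogenic_fraction: float = 0.4
    conservation_gap: float = 1.5
    burial_gap: float = 1.0
    plddt_gap: float = 1.0
    gene_level_signal: bool = False
    gene_weight: float = 1.5
    substitution_signal: bool = True
    label_noise: float = 0.05
    msa_depth: int = 60
    sasa_points: int = 480

    def __post_init__(self) -> None:
        if self.length_range[0] < 20:
            raise ValueError("minimum protein length is 20 residues")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if not 0.0 < self.pathogenic_fraction < 1.0:
            raise ValueError("pathogenic_fraction must be in (0, 1)")


@dataclass
class SyntheticProtein:
    accession: str
    sequence: str
    plddt: np.ndarray
    conservation: np.ndarray
    model: StructureModel
    pdb_text: str
    msa_rows: list[str]
    go_term_count: int

    @property
    def msa(self) -> Msa:
        ids = [self.accession] + [
            f"{self.accession}_h{i}" for i in range(1, len(self.msa_rows))
        ]
        return Msa(self.accession, list(self.msa_rows), ids)

    def context(self) -> ProteinContext:
        return ProteinContext(
            accession=self.accession,
            sequence=self.sequence,
            go_term_count=self.go_term_count,
        )


# --- geometry --------------------------------------------------------------

_HELIX_RADIUS = 2.3  # Angstrom
_HELIX_RISE = 1.5  # Angstrom per residue
_HELIX_TURN = math.radians(100.0)
_SIDECHAIN_OFFSET = 1.8  # Angstrom, radially outward


def _helix_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n)
    theta = _HELIX_TURN * i
    ca = np.column_stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
    )
    outward = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    cb = ca + _SIDECHAIN_OFFSET * outward
    return ca, cb


def _pdb_atom_line(serial, name, resname, resseq, xyz, b, element) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d} {name:<4s} {resname:>3s} A{resseq:>4d}    "
        f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.00:>6.2f}{b:>6.2f}          {element:>2s}"
    )


def gen_protein(config: SyntheticConfig, index: int) -> SyntheticProtein:
    """One synthetic protein: sequence, helix structure with pLDDT in the
    B-factor field, per-position conservation, and an alignment.

    Deterministic (byte-identical files) for a fixed (config.seed, index).
    """
    rng = np.random.default_rng([config.seed, index])
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    freqs = np.full(20, 1.0 / 20)
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=freqs))

    # disordered terminal segments: low confidence, ordered core: high
    tail = max(5, int(0.15 * length))
    plddt = np.full(length, 90.0) + rng.normal(0, 3.0, length)
    plddt[:tail] = 45.0 + rng.normal(0, 4.0, tail)
    plddt[-tail:] = 45.0 + rng.normal(0, 4.0, tail)
    plddt = np.clip(plddt, 0.0, 100.0)

    conservation = rng.uniform(0.15, 0.98, size=length)

    ca, cb = _helix_coords(length)
    residues, lines = [], []
    serial = 1
    for j in range(length):
        resname = seq3(sequence[j]).upper()
        b = round(float(plddt[j]), 2)
        atoms = [
            Atom("C", *ca[j], tables.vdw_radius("C")),
            Atom("C", *cb[j], tables.vdw_radius("C")),
        ]
        lines.append(_pdb_atom_line(serial, "CA", resname, j + 1, ca[j], b, "C"))
        serial += 1
        lines.append(_pdb_atom_line(serial, "CB", resname, j + 1, cb[j], b, "C"))
        serial += 1
        residues.append(Residue(j + 1, sequence[j], atoms, b))
    pdb_text = "\n".join(lines + ["TER", "END"]) + "\n"

    accession = f"SYN{index:03d}"
    msa_rows = gen_msa(sequence, conservation, config.msa_depth, rng)
    go_count = int(rng.integers(5, 120))
    return SyntheticProtein(
        accession=accession,
        sequence=sequence,
        plddt=plddt,
        conservation=conservation,
        model=StructureModel(accession, residues),
        pdb_text=pdb_text,
        msa_rows=msa_rows,
        go_term_count=go_count,
    )


def gen_msa(
    sequence: str,
    conservation: np.ndarray,
    depth: int,
    rng: np.random.Generator | int,
) -> list[str]:
    """Gap-free alignment rows: the query first, then ``depth - 1`` homologs
    that emit the query residue with probability c_j per column, otherwise a
    uniform background draw."""
    if len(conservation) != len(sequence):
        raise ValueError("conservation profile must match sequence length")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(sequence)
    alphabet = np.array(list(AMINO_ACIDS))
    rows = [sequence]
    for _ in range(depth - 1):
        keep = rng.random(n) < conservation
        background = alphabet[rng.integers(0, 20, size=n)]
        row = np.where(keep, np.array(list(sequence)), background)
        rows.append("".join(row))
    return rows


# --- variant planting ------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _pick_substitution(
    wt: str,
    damaging: bool,
    rng: np.random.Generator,
    observed: set[str] | None = None,
) -> str:
    """Neutral variants prefer residues observed among homologs at the column
    (tolerated in evolution) with conservative BLOSUM scores; damaging
    variants prefer unobserved, dissimilar residues."""
    others = [a for a in AMINO_ACIDS if a != wt]
    observed = observed or set()
    if damaging:
        pool = [a for a in others if a not in observed] or others
        pool = sorted(pool, key=lambda a: substitution_score(wt, a))[:3]
    else:
        pool = [a for a in others if a in observed]
        if not pool:
            pool = sorted(others, key=lambda a: -substitution_score(wt, a))[:3]
    return pool[rng.integers(len(pool))]


def gen_variant_set(
    config: SyntheticConfig, proteins: list[SyntheticProtein]
) -> tuple[list[VariantRecord], dict]:
    """Labeled variant set with planted structure plus a ground-truth manifest.

    One variant per selected (protein, position) site.  Site weights are
    log-linear in standardized conservation, burial (1 - rASA), pLDDT and --
    when gene-level signal is enabled -- the protein's GO-term count.
    """
    rng = np.random.default_rng([config.seed, 999_983])

    site_rows = []
    for p_idx, prot in enumerate(proteins):
        feats = structfeat.residue_features(prot.model, n_points=config.sasa_points)
        for pos in range(1, len(prot.sequence) + 1):
            site_rows.append(
                {
                    "protein": p_idx,
                    "position": pos,
                    "conservation": prot.conservation[pos - 1],
                    "rasa": feats[pos].rasa,
                    "plddt": prot.plddt[pos - 1],
                    "go": prot.go_term_count,
                }
            )
    sites = pd.DataFrame(site_rows)
    if config.n_variants > len(sites):
        raise ValueError(
            f"requested {config.n_variants} variants but only {len(sites)} "
            "positions are available"
        )
    gene_w = config.gene_weight if config.gene_level_signal else 0.0
    composite = (
        config.conservation_gap * _zscore(sites["conservation"].to_numpy())
        + config.burial_gap * _zscore(-sites["rasa"].to_numpy())
        + config.plddt_gap * _zscore(sites["plddt"].to_numpy())
        + gene_w * _zscore(sites["go"].to_numpy(dtype=float))
    )

    n_path = int(round(config.n_variants * config.pathogenic_fraction))
    n_ben = config.n_variants - n_path
    # Gumbel top-k gives exponential-weight sampling without replacement
    gumbel = rng.gumbel(size=len(sites))
    order_path = np.argsort(-(composite + gumbel))
    path_idx = order_path[:n_path]
    remaining = np.setdiff1d(np.arange(len(sites)), path_idx)
    gumbel2 = rng.gumbel(size=len(remaining))
    order_ben = np.argsort(-(-composite[remaining] + gumbel2))
    ben_idx = remaining[order_ben[:n_ben]]

    records: list[VariantRecord] = []
    manifest_variants = []
    raw_path = ["Pathogenic", "Likely pathogenic"]
    raw_ben = ["Benign", "Likely benign"]
    for site_i, true_pathogenic in [(i, True) for i in path_idx] + [
        (i, False) for i in ben_idx
    ]:
        site = sites.iloc[int(site_i)]
        prot = proteins[int(site["protein"])]
        pos = int(site["position"])
        wt = prot.sequence[pos - 1]
        if config.substitution_signal:
            observed = {row[pos - 1] for row in prot.msa_rows[1:]} - {wt}
            var = _pick_substitution(wt, true_pathogenic, rng, observed)
        else:
            others = [a for a in AMINO_ACIDS if a != wt]
            var = others[rng.integers(len(others))]
        flipped = bool(rng.random() < config.label_noise)
        emitted_pathogenic = true_pathogenic ^ flipped
        raw = (raw_path if emitted_pathogenic else raw_ben)[rng.integers(2)]
        rec = VariantRecord(
            gene_symbol=f"GENE{int(site['protein']):02d}",
            protein_accession=prot.accession,
            position=pos,
            wt_aa=wt,
            var_aa=var,
            raw_label=raw,
            label=harmonize_label(raw),
            review_stars=int(rng.integers(1, 4)),
            origin=Origin.GERMLINE,
        )
        records.append(rec)
        manifest_variants.append(
            {
                "id": rec.variant_id,
                "true_label": "PATHOGENIC" if true_pathogenic else "BENIGN",
                "emitted_label": rec.label.value,
                "flipped": flipped,
                "conservation": float(site["conservation"]),
                "rasa": float(site["rasa"]),
                "plddt": float(site["plddt"]),
            }
        )
    manifest = {
        "config": asdict(config),
        "planted_directions": {
            "conservation": "pathogenic_high",
            "rasa": "pathogenic_low",
            "plddt": "pathogenic_high",
            "go_term_count": "pathogenic_high" if gene_w > 0 else "none",
        },
        "variants": manifest_variants,
    }
    return records, manifest


# --- comparator scores -----------------------------------------------------


def binormal_separation(target_auc: float) -> float:
    """Positive-class mean mu such that the binormal AUROC equals the target."""
    return math.sqrt(2.0) * norm.ppf(target_auc)


def gen_comparator_scores(
    labels,
    target_auc: float = 0.85,
    n_tools: int = 12,
    seed: int = 0,
    n_call_tools: int | None = None,
) -> tuple[pd.DataFrame, list]:
    """Binormal comparator score table plus its tool manifest.

    Each tool draws independent noise; the logistic squashing to [0, 1] is
    monotone so the target AUROC is preserved.  The first ``n_call_tools``
    tools also emit binary calls at the binormal midpoint.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must be in [0.5, 1)")
    from .evalbench import ToolSpec

    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    mu = binormal_separation(target_auc)
    if n_call_tools is None:
        n_call_tools = n_tools
    data, manifest = {}, []
    for t in range(n_tools):
        name = f"tool{t:02d}"
        raw = rng.normal(0.0, 1.0, size=len(labels)) + mu * labels
        data[name] = expit(raw)
        has_calls = t < n_call_tools
        if has_calls:
            data[f"{name}_call"] = (raw > mu / 2.0).astype(int)
        manifest.append(ToolSpec(name=name, has_calls=has_calls))
    return pd.DataFrame(data), manifest


def gen_vus_score_table(
    n_lp_vus: int = 166,
    n_lp_conflicting: int = 49,
    n_lb_vus: int = 75,
    n_lb_conflicting: int = 30,
    n_background: int = 600,
    tools: tuple[str, ...] = ("model", "toolA", "toolB", "toolC"),
    genes: tuple[str, ...] = ("NF1", "FH", "MLH1", "PALB2", "BLM", "NBN"),
    seed: int = 0,
) -> pd.DataFrame:
    """VUS/conflicting score table whose extreme-consensus rows mirror a
    chosen reassignment split, for exercising the consensus rule end to end.

    High-consensus rows draw all tool scores above 0.96, low-consensus rows
    below 0.04, background rows in the intermediate band.
    """
    rng = np.random.default_rng(seed)
    rows = []
    specs = (
        [("VUS", "hi")] * n_lp_vus
        + [("CONFLICTING", "hi")] * n_lp_conflicting
        + [("VUS", "lo")] * n_lb_vus
        + [("CONFLICTING", "lo")] * n_lb_conflicting
        + [("VUS", "mid")] * n_background
    )
    statuses = ["SINGLE_SUBMITTER", "MULTIPLE_NO_CONSENSUS", "EXPERT"]
    for i, (prior, band) in enumerate(specs):
        if band == "hi":
            scores = rng.uniform(0.961, 1.0, size=len(tools))
        elif band == "lo":
            scores = rng.uniform(0.0, 0.039, size=len(tools))
        else:
            scores = rng.uniform(0.10, 0.90, size=len(tools))
        row = {
            "id": f"vus{i:05d}",
            "gene": genes[rng.integers(len(genes))],
            "prior_label": prior,
            "review_status": statuses[rng.choice(3, p=[0.65, 0.30, 0.05])],
        }
        row.update({t: float(s) for t, s in zip(tools, scores)})
        rows.append(row)
    return pd.DataFrame(rows)


# --- study bundle ----------------------------------------------------------


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    proteins: list[SyntheticProtein]
    variants: list[VariantRecord]
    manifest: dict

    def contexts(self) -> dict[str, ProteinContext]:
        return {p.accession: p.context() for p in self.proteins}

    def write(self, outdir: str | Path) -> Path:
        """Materialize the fixture directory (FASTA, PDB, aligned FASTA,
        variant CSV, manifest JSON)."""
        from .variantio import write_variant_table

        outdir = Path(outdir)
        (outdir / "structures").mkdir(parents=True, exist_ok=True)
        (outdir / "msas").mkdir(exist_ok=True)
        with (outdir / "proteins.fasta").open("w") as fh:
            for p in self.proteins:
                fh.write(f">{p.accession}\n{p.sequence}\n")
        ctx_rows = [
            {"accession": p.accession, "length": len(p.sequence),
             "go_term_count": p.go_term_count}
            for p in self.proteins
        ]
        pd.DataFrame(ctx_rows).to_csv(outdir / "protein_context.csv", index=False)
        for p in self.proteins:
            (outdir / "structures" / f"{p.accession}.pdb").write_text(p.pdb_text)
            with (outdir / "msas" / f"{p.accession}.fasta").open("w") as fh:
                msa = p.msa
                for rid, row in zip(msa.ids, msa.rows):
                    fh.write(f">{rid}\n{row}\n")
        write_variant_table(self.variants, outdir / "variants.csv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate the full in-memory synthetic study at the configured sizes."""
    config = config or SyntheticConfig()
    proteins = [gen_protein(config, i) for i in range(config.n_proteins)]
    variants, manifest = gen_variant_set(config, proteins)
    return SyntheticStudy(config, proteins, variants, manifest)
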