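"""Read, harmonize, filter and partition missense-variant tables.

The canonical on-disk format is a delimited table (ClinVar-style export) with
one row per protein-level missense variant.  Clinical-significance strings are
harmonized into four classes (pathogenic, benign, VUS, conflicting); anything
else maps to an explicit UNKNOWN sentinel and is excluded downstream with an
audited counter rather than silently.

Filtering follows the study design for hereditary-cancer panels: germline
origin and ClinVar review status of at least one star; somatic records are
excluded.  The pathogenic/benign pool is partitioned into a stratified
train/test split whose sizes depend only on the pool size and test fraction.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqUtils import seq1
from sklearn.model_selection import train_test_split

from .tables import AMINO_ACIDS

logger = logging.getLogger(__name__)


class Label(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"
    VUS = "VUS"
    CONFLICTING = "CONFLICTING"
    UNKNOWN = "UNKNOWN"


class Origin(str, Enum):
    GERMLINE = "GERMLINE"
    SOMATIC = "SOMATIC"
    OTHER = "OTHER"


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with a harmonized clinical label."""

    gene_symbol: str
    protein_accession: str
    position: int  # 1-based residue index on the canonical isoform
    wt_aa: str
    var_aa: str
    raw_label: str
    label: Label
    review_stars: int
    origin: Origin

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS or self.var_aa not in AMINO_ACIDS:
            raise ValueError(
                f"amino acids must be standard one-letter codes, got "
                f"{self.wt_aa!r}->{self.var_aa!r}"
            )
        if self.wt_aa == self.var_aa:
            raise ValueError("missense variant requires wt_aa != var_aa")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not 0 <= self.review_stars <= 4:
            raise ValueError("review_stars must be in 0..4")

    @property
    def variant_id(self) -> str:
        return f"{self.protein_accession}:{self.wt_aa}{self.position}{self.var_aa}"


@dataclass
class ProteinContext:
    """Per-protein metadata needed for feature assembly."""

    accession: str
    sequence: str
    go_term_count: int = 0
    structure_path: Path | None = None
    msa_path: Path | None = None

    def __post_init__(self) -> None:
        if self.go_term_count < 0:
            raise ValueError("go_term_count must be non-negative")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledSplit:
    train: list[VariantRecord]
    test: list[VariantRecord]
    seed: int
    test_fraction: float


_PATHOGENIC = {
    "pathogenic",
    "likely pathogenic",
    "pathogenic/likely pathogenic",
    "likely pathogenic/pathogenic",
}
_BENIGN = {
    "benign",
    "likely benign",
    "benign/likely benign",
    "likely benign/benign",
}


def harmonize_label(raw_label: str) -> Label:
    """Map a free-text clinical-significance string onto the four-class scheme.

    Pathogenic and likely-pathogenic (including slash-combined ClinVar
    spellings) merge into PATHOGENIC; likewise for BENIGN.  Any string starting
    with "conflicting" maps to CONFLICTING.  Matching is case-insensitive.
    Out-of-vocabulary strings return the UNKNOWN sentinel, never a silent class.
    """
    text = " ".join(raw_label.strip().lower().split())
    if text.startswith("conflicting"):
        return Label.CONFLICTING
    if text in _PATHOGENIC:
        return Label.PATHOGENIC
    if text in _BENIGN:
        return Label.BENIGN
    if text in {"uncertain significance", "variant of uncertain significance", "vus"}:
        return Label.VUS
    return Label.UNKNOWN


def harmonize_origin(raw: str) -> Origin:
    text = raw.strip().lower()
    if "germline" in text:
        return Origin.GERMLINE
    if "somatic" in text:
        return Origin.SOMATIC
    return Origin.OTHER


# HGVS protein-change notation, three-letter codes: p.Arg1699Trp
_HGVS_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse ``p.Arg1699Trp`` into ``("R", 1699, "W")``.

    Raises ValueError for anything that is not a simple single-residue
    substitution in three-letter HGVS notation.
    """
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable protein change {text!r}")
    wt3, pos, var3 = m.groups()
    wt, var = seq1(wt3), seq1(var3)
    if wt not in AMINO_ACIDS or var not in AMINO_ACIDS:
        raise ValueError(f"non-standard residue in protein change {text!r}")
    return wt, int(pos), var


@dataclass
class VariantDialect:
    """Column mapping from a foreign delimited table onto the canonical fields.

    Either ``protein_change`` (HGVS p. notation) or the explicit
    ``position``/``wt_aa``/``var_aa`` triple must be mapped.
    """

    gene: str = "gene"
    accession: str = "accession"
    position: str | None = "position"
    wt_aa: str | None = "wt_aa"
    var_aa: str | None = "var_aa"
    protein_change: str | None = None
    label: str = "clinical_significance"
    review_stars: str = "review_stars"
    origin: str = "origin"
    delimiter: str = ","

    def required_columns(self) -> list[str]:
        cols = [self.gene, self.accession, self.label, self.review_stars, self.origin]
        if self.protein_change is not None:
            cols.append(self.protein_change)
        else:
            cols.extend([self.position, self.wt_aa, self.var_aa])
        return [c for c in cols if c is not None]


CANONICAL_DIALECT = VariantDialect()

CANONICAL_COLUMNS = [
    "gene",
    "accession",
    "position",
    "wt_aa",
    "var_aa",
    "clinical_significance",
    "review_stars",
    "origin",
]


def parse_variant_table(
    path: str | Path,
    dialect: VariantDialect = CANONICAL_DIALECT,
    with_report: bool = False,
) -> list[VariantRecord] | tuple[list[VariantRecord], Counter]:
    """Parse a delimited variant table into validated records.

    Rows that are not simple missense substitutions (synonymous, malformed
    protein change, unknown residue codes, bad positions) are skipped and
    counted per reason, not fatal.  A missing required column raises a
    configuration error naming the column; an empty file yields an empty list
    with a logged warning.

    When ``with_report`` is true, returns ``(records, skip_counter)``.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    skips: Counter = Counter()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            logger.warning("variant table %s is empty", path)
            return (records, skips) if with_report else records
        missing = [c for c in dialect.required_columns() if c not in reader.fieldnames]
        if missing:
            raise KeyError(
                f"variant table {path} is missing required column(s): {missing}"
            )
        for row in reader:
            try:
                if dialect.protein_change is not None:
                    wt, pos, var = parse_protein_change(row[dialect.protein_change])
                else:
                    wt = row[dialect.wt_aa].strip()
                    var = row[dialect.var_aa].strip()
                    pos = int(row[dialect.position])
                raw = row[dialect.label]
                rec = VariantRecord(
                    gene_symbol=row[dialect.gene].strip(),
                    protein_accession=row[dialect.accession].strip(),
                    position=pos,
                    wt_aa=wt,
                    var_aa=var,
                    raw_label=raw,
                    label=harmonize_label(raw),
                    review_stars=int(row[dialect.review_stars]),
                    origin=harmonize_origin(row[dialect.origin]),
                )
            except (ValueError, KeyError) as exc:
                skips[str(exc)[:60]] += 1
                continue
            records.append(rec)
    if skips:
        logger.info(
            "skipped %d non-missense/unparseable row(s) in %s", sum(skips.values()), path
        )
    return (records, skips) if with_report else records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the canonical CSV dialect (lossless round-trip)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene_symbol,
                    r.protein_accession,
                    r.position,
                    r.wt_aa,
                    r.var_aa,
                    r.raw_label,
                    r.review_stars,
                    r.origin.value.lower(),
                ]
            )


def filter_variants(
    records: Sequence[VariantRecord],
    min_stars: int = 1,
    require_germline: bool = True,
) -> list[VariantRecord]:
    """Keep records with review_stars >= min_stars and (optionally) germline origin.

    Order is preserved; an empty result is allowed.
    """
    kept = []
    for r in records:
        if r.review_stars < min_stars:
            continue
        if require_germline and r.origin is not Origin.GERMLINE:
            continue
        kept.append(r)
    return kept


def select_training_pool(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Pathogenic/benign records usable for supervised model development."""
    return [r for r in records if r.label in (Label.PATHOGENIC, Label.BENIGN)]


def select_withheld(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """VUS and conflicting-interpretation records, reserved for reclassification."""
    return [r for r in records if r.label in (Label.VUS, Label.CONFLICTING)]


def validate_mapping(record: VariantRecord, context: ProteinContext) -> bool:
    """True iff the variant position exists on the sequence and carries wt_aa."""
    if not context.sequence:
        raise ValueError(f"empty sequence for {context.accession}")
    if record.position > context.length:
        return False
    return context.sequence[record.position - 1] == record.wt_aa


def split_train_test(
    pool: Sequence[VariantRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> LabeledSplit:
    """Stratified train/test partition of the pathogenic/benign pool.

    Sizes are ``round(N * (1 - test_fraction))`` / remainder, a function of the
    pool size and fraction only; membership is deterministic for a fixed seed.
    A single-class pool is an error because stratification is impossible.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = [r.label for r in pool]
    bad = {l for l in labels if l not in (Label.PATHOGENIC, Label.BENIGN)}
    if bad:
        raise ValueError(f"pool must contain only PATHOGENIC/BENIGN labels, got {bad}")
    if len(set(labels)) < 2:
        raise ValueError("cannot stratify a single-class pool")
    n = len(pool)
    n_train = int(round(n * (1.0 - test_fraction)))
    idx_train, idx_test = train_test_split(
        range(n),
        train_size=n_train,
        stratify=[l.value for l in labels],
        random_state=seed,
        shuffle=True,
    )
    return LabeledSplit(
        train=[pool[i] for i in sorted(idx_train)],
        test=[pool[i] for i in sorted(idx_test)],
        seed=seed,
        test_fraction=test_fraction,
    )
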