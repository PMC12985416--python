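"""Consensus reclassification of uncertain and conflicting variants.

A small ensemble of predictors (the trained model plus orthogonal external
tools) is averaged per variant after each tool's score is normalized onto
[0, 1] with a monotone map.  Variants whose mean score is strictly above the
high threshold become likely pathogenic, strictly below the low threshold
likely benign, and everything else -- including boundary values and variants
with too few available scores -- stays unchanged.  Summaries cross-tabulate
reassignments by gene, prior label (VUS vs conflicting) and ClinVar review
status.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class Assigned(str, Enum):
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    UNCHANGED = "UNCHANGED"


class ReviewStatus(str, Enum):
    SINGLE_SUBMITTER = "SINGLE_SUBMITTER"
    MULTIPLE_NO_CONSENSUS = "MULTIPLE_NO_CONSENSUS"
    EXPERT = "EXPERT"


@dataclass
class ReclassificationDecision:
    variant_id: str
    tool_scores: dict[str, float]
    mean_score: float
    assigned: Assigned
    prior_label: str  # "VUS" | "CONFLICTING"
    gene: str = ""
    review_status: ReviewStatus | None = None
    insufficient_evidence: bool = False


def normalize_tool_scores(
    raw,
    method: str = "minmax",
    higher_is_damaging: bool = True,
) -> np.ndarray:
    """Monotone map of raw tool scores onto [0, 1].

    Orientation is handled first (scores where smaller means more damaging are
    negated).  ``minmax`` is the affine map onto [0, 1] and requires at least
    two distinct values; ``rank_percentile`` maps tied values to the lowest
    rank of their tie group divided by n, which is robust for unbounded or
    heavy-tailed scores.
    """
    raw = np.asarray(raw, dtype=float)
    x = raw if higher_is_damaging else -raw
    if method == "minmax":
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            raise ValueError(
                "constant score vector cannot be min-max normalized; "
                "use method='rank_percentile'"
            )
        return (x - lo) / (hi - lo)
    if method == "rank_percentile":
        mask = np.isfinite(x)
        out = np.full_like(x, np.nan)
        out[mask] = rankdata(x[mask], method="min") / mask.sum()
        return out
    raise ValueError(f"unknown normalization method {method!r}")


def consensus_reclassify(
    tool_scores: Mapping[str, float],
    hi: float = 0.95,
    lo: float = 0.05,
    min_tools: int = 4,
    variant_id: str = "",
    prior_label: str = "VUS",
    gene: str = "",
    review_status: ReviewStatus | None = None,
) -> ReclassificationDecision:
    """Apply the consensus mean-score rule to one variant.

    Thresholds are strict inequalities (a mean exactly at a threshold stays
    unchanged).  Missing (NaN) tool scores are dropped; a variant with fewer
    than ``min_tools`` available scores is unchanged with an
    insufficient-evidence flag.
    """
    if hi <= lo:
        raise ValueError(f"hi threshold ({hi}) must exceed lo threshold ({lo})")
    available = {
        t: float(s) for t, s in tool_scores.items() if s is not None and np.isfinite(s)
    }
    for t, s in available.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"tool {t!r} score {s} outside [0, 1]; normalize first")
    if len(available) < min_tools:
        return ReclassificationDecision(
            variant_id, available, float("nan"), Assigned.UNCHANGED,
            prior_label, gene, review_status, insufficient_evidence=True,
        )
    # canonical tool order keeps the mean exactly permutation-invariant
    mean = float(np.mean([available[t] for t in sorted(available)]))
    if mean > hi:
        assigned = Assigned.LIKELY_PATHOGENIC
    elif mean < lo:
        assigned = Assigned.LIKELY_BENIGN
    else:
        assigned = Assigned.UNCHANGED
    return ReclassificationDecision(
        variant_id, available, mean, assigned, prior_label, gene, review_status
    )


def reclassify_table(
    scores: pd.DataFrame,
    tool_columns: Sequence[str],
    hi: float = 0.95,
    lo: float = 0.05,
    min_tools: int | None = None,
) -> list[ReclassificationDecision]:
    """Row-wise consensus reclassification of a VUS score table.

    Expects columns ``id``, ``gene``, ``prior_label`` and optionally
    ``review_status`` plus one normalized-score column per tool.  By default
    all configured tools are required (``min_tools`` = ensemble size).
    """
    if min_tools is None:
        min_tools = len(tool_columns)
    decisions = []
    for _, row in scores.iterrows():
        status = row.get("review_status")
        decisions.append(
            consensus_reclassify(
                {t: row[t] for t in tool_columns},
                hi=hi,
                lo=lo,
                min_tools=min_tools,
                variant_id=str(row.get("id", "")),
                prior_label=str(row.get("prior_label", "VUS")),
                gene=str(row.get("gene", "")),
                review_status=ReviewStatus(status) if pd.notna(status) and status else None,
            )
        )
    return decisions


def summarize_reclassification(
    decisions: Sequence[ReclassificationDecision],
) -> dict:
    """Cross-tabulate reassignments by gene, prior label and review status.

    Totals are conserved: per-gene (and per-prior-label) counts of each
    assigned class sum to that class's total.
    """
    by_gene: dict[str, Counter] = {}
    by_prior: dict[str, Counter] = {}
    by_review: dict[str, Counter] = {}
    totals: Counter = Counter()
    for d in decisions:
        key = d.assigned.value
        totals[key] += 1
        if d.assigned is not Assigned.UNCHANGED:
            by_gene.setdefault(d.gene, Counter())[key] += 1
            by_prior.setdefault(d.prior_label, Counter())[key] += 1
            if d.review_status is not None:
                by_review.setdefault(d.review_status.value, Counter())[key] += 1
    return {
        "totals": dict(totals),
        "by_gene": {g: dict(c) for g, c in by_gene.items()},
        "by_prior_label": {p: dict(c) for p, c in by_prior.items()},
        "by_review_status": {r: dict(c) for r, c in by_review.items()},
    }


def decisions_frame(decisions: Sequence[ReclassificationDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append(
            {
                "id": d.variant_id,
                "gene": d.gene,
                "prior_label": d.prior_label,
                "review_status": d.review_status.value if d.review_status else "",
                "mean_score": d.mean_score,
                "assigned": d.assigned.value,
                "insufficient_evidence": d.insufficient_evidence,
            }
        )
    return pd.DataFrame(rows)
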