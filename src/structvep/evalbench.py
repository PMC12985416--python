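"""Classification metrics, bootstrap confidence intervals, and comparator
benchmarking.

AUROC uses the rank (Mann-Whitney) formulation with midrank tie correction
(scikit-learn's implementation); threshold metrics come from the confusion
matrix at a 0.5 default score threshold unless explicit binary calls are
supplied.  Confidence intervals are percentile bootstrap over resamples of the
evaluation set at its original size; resamples containing a single class are
excluded and counted, never imputed.

External predictors arrive as a per-variant score table with a per-tool
manifest declaring score orientation (whether larger means more damaging) and
whether the tool emits binary calls; tools without calls are evaluated on
AUROC only, and per-tool missing rows are dropped tool-wise, so each tool is
scored on its own n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

logger = logging.getLogger(__name__)

METRICS = ("auroc", "f1", "mcc", "precision", "recall", "accuracy")


@dataclass
class ConfidenceInterval:
    lo: float
    hi: float
    n_boot: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("CI lower bound exceeds upper bound")


@dataclass
class MetricsReport:
    auroc: float
    f1: float | None
    mcc: float | None
    precision: float | None
    recall: float | None
    accuracy: float | None
    n: int
    ci: dict[str, ConfidenceInterval] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {m: getattr(self, m) for m in METRICS}
        out["n"] = self.n
        for m, ci in self.ci.items():
            out[f"{m}_ci"] = [ci.lo, ci.hi]
        return out


def _validate(y_true: np.ndarray) -> None:
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to compute metrics")


def compute_metrics(
    y_true,
    scores,
    calls=None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Full metric set from scores (and calls, defaulting to score > threshold)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _validate(y_true)
    if calls is None:
        calls = (scores > threshold).astype(int)
    else:
        calls = np.asarray(calls, dtype=int)
    return MetricsReport(
        auroc=float(roc_auc_score(y_true, scores)),
        f1=float(f1_score(y_true, calls, zero_division=0)),
        mcc=float(matthews_corrcoef(y_true, calls)),
        precision=float(precision_score(y_true, calls, zero_division=0)),
        recall=float(recall_score(y_true, calls, zero_division=0)),
        accuracy=float(accuracy_score(y_true, calls)),
        n=len(y_true),
    )


def _metric_value(metric, y, s, c) -> float:
    if metric == "auroc":
        return float(roc_auc_score(y, s))
    fn = {
        "f1": lambda: f1_score(y, c, zero_division=0),
        "mcc": lambda: matthews_corrcoef(y, c),
        "precision": lambda: precision_score(y, c, zero_division=0),
        "recall": lambda: recall_score(y, c, zero_division=0),
        "accuracy": lambda: accuracy_score(y, c),
    }[metric]
    return float(fn())


def bootstrap_ci(
    y_true,
    scores,
    calls=None,
    metrics: tuple[str, ...] = METRICS,
    n_boot: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    return_indices: bool = False,
) -> dict[str, ConfidenceInterval]:
    """Percentile 2.5/97.5 bootstrap CIs over resamples at the original size.

    Single-class resamples are excluded from every metric and counted in
    ``n_excluded``.  Deterministic for a fixed seed.  ``return_indices``
    additionally returns the drawn index matrix (for bookkeeping audits).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _validate(y_true)
    if len(y_true) < 2:
        raise ValueError("need at least two observations")
    if calls is None:
        calls = (scores > threshold).astype(int)
    else:
        calls = np.asarray(calls, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    idx_matrix = rng.integers(0, n, size=(n_boot, n))
    samples: dict[str, list[float]] = {m: [] for m in metrics}
    n_excluded = 0
    for idx in idx_matrix:
        yb = y_true[idx]
        if len(np.unique(yb)) < 2:
            n_excluded += 1
            continue
        sb, cb = scores[idx], calls[idx]
        for m in metrics:
            samples[m].append(_metric_value(m, yb, sb, cb))
    if n_excluded == n_boot:
        raise ValueError("every bootstrap resample was single-class")
    out = {
        m: ConfidenceInterval(
            lo=float(np.percentile(vals, 2.5)),
            hi=float(np.percentile(vals, 97.5)),
            n_boot=n_boot,
            n_excluded=n_excluded,
        )
        for m, vals in samples.items()
    }
    return (out, idx_matrix) if return_indices else out


@dataclass
class ToolSpec:
    """Comparator-tool metadata: score orientation and call availability."""

    name: str
    has_calls: bool = False
    higher_is_damaging: bool = True


def benchmark_comparators(
    y_true,
    table: pd.DataFrame,
    manifest: list[ToolSpec],
    n_boot: int = 0,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, MetricsReport]:
    """Per-tool metrics from a score table aligned row-wise with ``y_true``.

    Score columns are named after the tool; optional call columns are
    ``<tool>_call`` with binary values (1 = damaging).  Rows missing a tool's
    score are dropped for that tool only, so each tool reports its own n.
    Score-only tools get AUROC alone; a tool left with a single class after
    dropping is skipped with a warning.  ``n_boot > 0`` attaches bootstrap CIs.
    """
    y_true = np.asarray(y_true, dtype=int)
    reports: dict[str, MetricsReport] = {}
    for tool in manifest:
        if tool.name not in table.columns:
            raise KeyError(f"comparator table has no column for tool {tool.name!r}")
        raw = pd.to_numeric(table[tool.name], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(raw)
        if not mask.any():
            raise ValueError(f"tool {tool.name!r} has no non-missing scores")
        y = y_true[mask]
        if len(np.unique(y)) < 2:
            logger.warning("tool %s left single-class after dropping; skipped", tool.name)
            continue
        s = raw[mask]
        if not tool.higher_is_damaging:
            s = -s
        if tool.has_calls:
            call_col = f"{tool.name}_call"
            if call_col in table.columns:
                calls = pd.to_numeric(table[call_col], errors="coerce").to_numpy()[mask]
                calls = np.where(np.isfinite(calls), calls, s > threshold).astype(int)
            else:
                calls = (s > threshold).astype(int)
            rep = compute_metrics(y, s, calls)
        else:
            rep = MetricsReport(
                auroc=float(roc_auc_score(y, s)),
                f1=None, mcc=None, precision=None, recall=None, accuracy=None,
                n=int(mask.sum()),
            )
        if n_boot > 0:
            metrics = METRICS if tool.has_calls else ("auroc",)
            calls_arg = calls if tool.has_calls else None
            rep.ci = bootstrap_ci(
                y, s, calls_arg, metrics=metrics, n_boot=n_boot, seed=seed
            )
        reports[tool.name] = rep
    return reports


def comparator_table_frame(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Benchmark summary shaped like a predictor-comparison table."""
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "predictor": name,
                "size": r.n,
                "auroc": r.auroc,
                "f1": r.f1,
                "mcc": r.mcc,
            }
        )
    return pd.DataFrame(rows).sort_values("auroc", ascending=False, ignore_index=True)


CORRECT_COUNT_BINS = [(0, 0), (1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12)]


def _bin_label(count: int) -> str:
    for lo, hi in CORRECT_COUNT_BINS:
        if lo <= count <= hi:
            return f"[{lo}]" if lo == hi else f"[{lo}-{hi}]"
    return f"[>{CORRECT_COUNT_BINS[-1][1]}]"


def stratify_failures(
    y_true,
    model_calls,
    comparator_calls: pd.DataFrame,
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant success flags and correct-predictor-count bins.

    ``comparator_calls`` holds one binary call column per call-producing tool;
    ``features`` carries the stratification features (e.g. plddt, delta_psic,
    sasa) aligned row-wise.  Returns a frame with per-variant model success,
    the number of comparators that called the variant correctly, its bin
    label, and the feature columns, ready for distribution plots.
    """
    y_true = np.asarray(y_true, dtype=int)
    model_calls = np.asarray(model_calls, dtype=int)
    correct_counts = (comparator_calls.to_numpy(dtype=int) == y_true[:, None]).sum(axis=1)
    out = pd.DataFrame(
        {
            "y_true": y_true,
            "model_correct": model_calls == y_true,
            "n_comparators_correct": correct_counts,
            "bin": [_bin_label(c) for c in correct_counts],
        }
    )
    return pd.concat([out, features.reset_index(drop=True)], axis=1)


def per_class_accuracy(y_true, calls) -> dict[str, float]:
    """Recall on each class (per-class accuracy of a binary predictor)."""
    y_true = np.asarray(y_true, dtype=int)
    calls = np.asarray(calls, dtype=int)
    out = {}
    for cls, name in ((1, "pathogenic"), (0, "benign")):
        mask = y_true == cls
        out[name] = float((calls[mask] == cls).mean()) if mask.any() else float("nan")
    return out
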