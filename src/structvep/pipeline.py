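"""End-to-end orchestration: config validation, feature assembly, staged runs.

A single validated config drives the stage sequence
simulate -> prepare -> features -> train -> benchmark -> reclassify; any
suffix of the sequence can be skipped but stages always execute in order.
Each stage logs its input/output counts and contributes output checksums to a
run manifest, so re-running an identical config reproduces identical
checksums for the deterministic stages.  Inputs are never mutated; all
outputs land under the configured run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import evalbench, modelcore, reclassify, seqfeat, structfeat, synthfix, variantio

logger = logging.getLogger(__name__)

STAGES = ["simulate", "prepare", "features", "train", "benchmark", "reclassify"]


class SyntheticSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
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


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    algorithm: Literal["rf", "xgb"] = "rf"
    schema_name: Literal["full", "reduced"] = "full"
    outer_k: int = 5
    inner_k: int = 3
    n_trials: int = 150
    test_fraction: float = 0.2
    small_space: bool = False  # compact search space for desk-scale runs


class BenchmarkSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_tools: int = 12
    target_auc: float = 0.85
    n_boot: int = 1000


class ReclassifySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hi: float = 0.95
    lo: float = 0.05
    min_tools: int | None = None
    n_background: int = 600

    @model_validator(mode="after")
    def _check_thresholds(self):
        if self.hi <= self.lo:
            raise ValueError(
                f"hi threshold ({self.hi}) must exceed lo threshold ({self.lo})"
            )
        return self


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "structvep_run"
    stages: list[str] = STAGES
    min_stars: int = 1
    synthetic: SyntheticSection = SyntheticSection()
    model: ModelSection = ModelSection()
    benchmark: BenchmarkSection = BenchmarkSection()
    reclassify: ReclassifySection = ReclassifySection()

    @model_validator(mode="after")
    def _check_stages(self):
        if self.stages != STAGES[: len(self.stages)]:
            raise ValueError(
                f"stages must be a prefix of {STAGES} (any suffix is skippable)"
            )
        return self


def validate_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a JSON/YAML config; defaults fill an empty file and
    unknown keys are rejected by name."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(**(raw or {}))


ALGORITHMS = {"rf": modelcore.RANDOM_FOREST, "xgb": modelcore.GRADIENT_BOOSTING}


# --- feature assembly ------------------------------------------------------


def build_feature_table(
    variants: list[variantio.VariantRecord],
    contexts: dict[str, variantio.ProteinContext],
    struct_maps: dict[str, dict[int, structfeat.ResidueStructFeatures]],
    profiles: dict[str, seqfeat.PsicProfile],
    schema: str = "FULL",
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Assemble the feature matrix for mapped variants.

    Returns ``(X, y, meta)``: features indexed like ``meta`` (variant id,
    gene, accession, position), with y = 1 for pathogenic.  Variants failing
    sequence mapping are dropped with a counter logged.
    """
    rows, labels, meta = [], [], []
    n_unmapped = 0
    for rec in variants:
        ctx = contexts[rec.protein_accession]
        if not variantio.validate_mapping(rec, ctx):
            n_unmapped += 1
            continue
        struct = struct_maps[rec.protein_accession][rec.position]
        vec = seqfeat.assemble_feature_vector(
            rec, ctx, struct, profiles[rec.protein_accession], schema
        )
        rows.append(vec.as_dict())
        labels.append(1 if rec.label is variantio.Label.PATHOGENIC else 0)
        meta.append(
            {
                "id": rec.variant_id,
                "gene": rec.gene_symbol,
                "accession": rec.protein_accession,
                "position": rec.position,
            }
        )
    if n_unmapped:
        logger.info("dropped %d variant(s) failing sequence mapping", n_unmapped)
    X = pd.DataFrame(rows, columns=seqfeat.schema_features(schema))
    return X, np.array(labels, dtype=int), pd.DataFrame(meta)


def extract_study_features(
    study: synthfix.SyntheticStudy,
    variants: list[variantio.VariantRecord] | None = None,
    schema: str = "FULL",
    sasa_points: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Run the full feature pipeline (PSIC + structure) over a synthetic study."""
    n_points = sasa_points or study.config.sasa_points
    contexts = study.contexts()
    struct_maps = {
        p.accession: structfeat.residue_features(p.model, n_points=n_points)
        for p in study.proteins
    }
    profiles = {
        p.accession: seqfeat.compute_psic_profile(p.msa) for p in study.proteins
    }
    return build_feature_table(
        variants if variants is not None else study.variants,
        contexts, struct_maps, profiles, schema,
    )


# --- staged run ------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksum_tree(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stage prefix and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stages": [],
    }
    state: dict = {}
    for stage in config.stages:
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            counts = _STAGE_FNS[stage](config, state, stage_dir)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        entry = {
            "name": stage,
            "counts": counts,
            "outputs": _checksum_tree(stage_dir),
        }
        logger.info("stage %s: %s", stage, counts)
        manifest["stages"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    synth_cfg = synthfix.SyntheticConfig(
        seed=config.seed, **config.synthetic.model_dump()
    )
    study = synthfix.generate_study(synth_cfg)
    study.write(outdir)
    state["study"] = study
    return {"proteins": len(study.proteins), "variants": len(study.variants)}


def _stage_prepare(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    study = state["study"]
    records = variantio.filter_variants(study.variants, min_stars=config.min_stars)
    pool = variantio.select_training_pool(records)
    split = variantio.split_train_test(
        pool, test_fraction=config.model.test_fraction, seed=config.seed
    )
    variantio.write_variant_table(records, outdir / "harmonized.csv")
    (outdir / "split.json").write_text(
        json.dumps(
            {
                "seed": split.seed,
                "test_fraction": split.test_fraction,
                "train_ids": [r.variant_id for r in split.train],
                "test_ids": [r.variant_id for r in split.test],
            },
            indent=2,
        )
    )
    state["split"] = split
    return {
        "filtered": len(records),
        "pool": len(pool),
        "train": len(split.train),
        "test": len(split.test),
    }


def _stage_features(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    study, split = state["study"], state["split"]
    schema = config.model.schema_name.upper()
    frames = {}
    for part, recs in (("train", split.train), ("test", split.test)):
        X, y, meta = extract_study_features(study, recs, schema=schema)
        frame = pd.concat([meta, X], axis=1)
        frame["label"] = y
        frame["split"] = part
        frames[part] = (X, y, meta)
        frame.to_csv(outdir / f"features_{part}.csv", index=False)
    state["features"] = frames
    state["schema"] = schema
    return {p: len(frames[p][1]) for p in frames}


def _stage_train(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    X_train, y_train, _ = state["features"]["train"]
    algo = ALGORITHMS[config.model.algorithm]
    space = modelcore.SMALL_SPACES[algo] if config.model.small_space else None
    report = modelcore.nested_cv(
        X_train.to_numpy(dtype=float),
        y_train,
        algorithm=algo,
        outer_k=config.model.outer_k,
        inner_k=config.model.inner_k,
        n_trials=config.model.n_trials,
        seed=config.seed,
        space=space,
    )
    best_fold = int(np.argmax([m.auroc for m in report.fold_metrics]))
    bundle = modelcore.fit_final(
        X_train, y_train, algo, report.best_params[best_fold], seed=config.seed
    )
    bundle.save(outdir / "model")
    (outdir / "cv_report.json").write_text(
        json.dumps(
            {
                "mean": report.mean,
                "sd": report.sd,
                "best_params": report.best_params,
                "n_trials": report.n_trials,
            },
            indent=2,
            default=str,
        )
    )
    state["bundle"] = bundle
    state["cv_report"] = report
    return {"outer_folds": len(report.fold_metrics), "trials_per_fold": report.n_trials}


def _stage_benchmark(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    X_test, y_test, _ = state["features"]["test"]
    bundle = state["bundle"]
    scores = modelcore.predict_proba(bundle, X_test)
    table, manifest = synthfix.gen_comparator_scores(
        y_test,
        target_auc=config.benchmark.target_auc,
        n_tools=config.benchmark.n_tools,
        seed=config.seed + 101,
    )
    table.insert(0, "model", scores)
    manifest.insert(0, evalbench.ToolSpec(name="model", has_calls=True))
    table["model_call"] = (scores > bundle.decision_threshold).astype(int)
    reports = evalbench.benchmark_comparators(
        y_test, table, manifest, n_boot=config.benchmark.n_boot, seed=config.seed
    )
    frame = evalbench.comparator_table_frame(reports)
    frame.to_csv(outdir / "benchmark.csv", index=False)
    call_cols = [t.name for t in manifest if t.has_calls and t.name != "model"]
    strata = evalbench.stratify_failures(
        y_test,
        (scores > bundle.decision_threshold).astype(int),
        table[[f"{c}_call" for c in call_cols]],
        X_test[["plddt", "delta_psic", "sasa"]],
    )
    strata.to_csv(outdir / "failure_strata.csv", index=False)
    state["benchmark"] = reports
    return {"tools": len(reports), "test_n": len(y_test)}


def _stage_reclassify(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    rc = config.reclassify
    table = synthfix.gen_vus_score_table(
        n_background=rc.n_background, seed=config.seed + 202
    )
    tool_cols = ["model", "toolA", "toolB", "toolC"]
    decisions = reclassify.reclassify_table(
        table, tool_cols, hi=rc.hi, lo=rc.lo, min_tools=rc.min_tools
    )
    reclassify.decisions_frame(decisions).to_csv(outdir / "decisions.csv", index=False)
    summary = reclassify.summarize_reclassification(decisions)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    state["reclassification"] = summary
    return {
        "variants": len(decisions),
        "likely_pathogenic": summary["totals"].get("LIKELY_PATHOGENIC", 0),
        "likely_benign": summary["totals"].get("LIKELY_BENIGN", 0),
    }


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "prepare": _stage_prepare,
    "features": _stage_features,
    "train": _stage_train,
    "benchmark": _stage_benchmark,
    "reclassify": _stage_reclassify,
}
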