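# structvep

Structure-aware pathogenicity classification of missense variants in
hereditary-cancer gene panels.

Clinical testing for hereditary cancer syndromes returns a large fraction of
missense variants of uncertain significance (VUS) or with conflicting
interpretations. `structvep` is a toolkit for building and evaluating
panel-specific variant effect classifiers that combine evolutionary
conservation with structural context from predicted protein models, and for
applying a conservative consensus rule that reassigns a small, high-confidence
subset of VUS. It is aimed at computational genetics groups who curate
protein-level variant tables (ClinVar-style) and have predicted structures and
alignments for the panel proteins.

## What it computes

**Features** (per variant, at the mutated residue):

- *Conservation*: a position-specific independent-counts (PSIC) profile from
  the protein's alignment. Sequences are greedily clustered at 62% identity;
  each cluster contributes one independent count per column, regularized with
  a background pseudo-count:

  `score(j, a) = ln[ (c(j,a) + w·bg_a) / ((n_eff(j) + w) · bg_a) ]`

  The model sees `psic_wt`, `psic_var` and `ΔPSIC = score(j, wt) − score(j, var)`,
  which is large and positive for a radical substitution at a conserved site.
- *Structure*: per-residue pLDDT (read from the B-factor field of
  AlphaFold2-style models), solvent accessible surface area by the
  Shrake–Rupley rolling-probe algorithm on a deterministic Fibonacci point
  set, and relative accessibility `rASA = SASA / maxASA(aa)` (Tien et al.
  theoretical maxima).
- *Substitution chemistry*: BLOSUM62 score, hydrophobicity and volume deltas,
  secondary-structure propensities and background frequencies of both
  residues; optionally the gene-level features protein length and GO-term
  count (the FULL schema; REDUCED omits them).

**Models**: a random forest and an XGBoost classifier, selected by nested
cross-validation (stratified 5-fold outer loop for performance estimation, a
3-fold inner loop driving a seeded tree-structured Parzen estimator over the
hyperparameter space, mean inner AUROC as the objective). Interpretation uses
exact tree-Shapley attributions (local accuracy `base + Σφᵢ = f(x)` holds to
machine precision).

**Evaluation**: AUROC (Mann–Whitney with tie correction), F1, MCC, precision,
recall and accuracy with 1000-resample percentile bootstrap confidence
intervals (single-class resamples excluded and counted), per-tool
benchmarking against external predictor score tables with tool-wise missing
data handling, and failure-mode stratification by pLDDT / ΔPSIC / SASA and
correct-predictor-count bins.

**Reclassification**: per VUS, the mean of several normalized predictor
scores; strictly above 0.95 → likely pathogenic, strictly below 0.05 → likely
benign, otherwise unchanged, with summaries by gene, prior label and review
status.

A seeded synthetic-fixture generator (`structvep.synthfix`) produces
proteins, helix structures with pLDDT, alignments, labeled variant tables and
comparator scores with planted class structure, so the whole pipeline is
testable without any downloads.

## Worked example

```bash
python examples/04_reclassify_vus.py
```

```
scoring 920 VUS/conflicting variants with 4 tools

totals: {
  "LIKELY_PATHOGENIC": 215,
  "LIKELY_BENIGN": 105,
  "UNCHANGED": 600
}
by prior label: {
  "VUS": {"LIKELY_PATHOGENIC": 166, "LIKELY_BENIGN": 75},
  "CONFLICTING": {"LIKELY_PATHOGENIC": 49, "LIKELY_BENIGN": 30}
}
```

Only variants whose four normalized scores agree at the extremes move; the
intermediate mass stays unchanged. The other examples
(`01_simulate_and_features.py`, `02_train_and_explain.py`,
`03_benchmark_predictors.py`) walk through feature extraction, nested-CV
training with Shapley rankings, and bootstrap benchmarking; for instance the
training example prints a mean outer AUROC of 0.952 ± 0.024 on a 700-variant
planted cohort with the conservation features leading the Shapley ranking.

A thin CLI mirrors the stages:

```bash
structvep simulate --seed 1 --out fixture/
structvep prepare --variants fixture/variants.csv --out prep/
structvep run-all --config config.yaml --out run/
```

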