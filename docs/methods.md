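# Methods

## Problem setting and data model

The package classifies single-residue missense substitutions in a fixed panel
of proteins as pathogenic or benign, and applies the trained classifier (with
orthogonal predictors) to variants of uncertain significance. All coordinates
are protein-level: a variant is `(gene, accession, position, wt, var)` with a
free-text clinical label, a ClinVar-style review-star count (0–4) and an
origin. Label harmonization merges "likely" categories with their definite
counterparts (pathogenic + likely pathogenic → PATHOGENIC, same for benign),
maps any "conflicting …" string to CONFLICTING and anything out of vocabulary
to an explicit UNKNOWN sentinel that is excluded downstream with an audited
counter. Default filtering keeps germline records with at least one review
star. Records whose stated wild-type residue disagrees with the canonical
sequence at the stated position are dropped (mapping validation), making the
usual silent exclusions of such pipelines auditable.

The supervised pool is partitioned once into train/test with
`n_train = round(N·(1−f))`, stratified by class; with `f = 0.2` a
3091-variant pool yields 2473/618, matching the published partition this
design reproduces. Sizes depend only on `N` and `f`; membership only on the
seed.

## Conservation: PSIC profiles

The cited PSIC method leaves several constants open, so the implementation
fixes a concrete, configurable scheme:

- greedy single-pass clustering of alignment rows at 62% identity (identity
  over mutually non-gap columns; a row joins the first cluster whose founder
  it matches), so duplicated sequences collapse to one independent count;
- per column, each cluster with a non-gap member contributes one count split
  over its members' residues by multiplicity; `n_eff(j)` is the number of
  contributing clusters;
- frequencies are regularized with a background pseudo-count of weight
  `w = 1` and scored as natural-log odds against the background, so scores
  are always finite and a column exactly at the background scores zero.

The background defaults to the alignment's pooled residue frequencies
(+1 smoothing), falling back to the BLOSUM62 background below 10 rows, where
pooled estimates are too noisy. ΔPSIC is oriented wild-type minus variant:
positive means the variant residue is less compatible with the column, the
direction in which damaging substitutions at conserved sites score high.

## Structural features

Structures follow the AlphaFold2 convention: one chain, full residue
coverage, per-residue confidence (pLDDT ∈ [0,100]) stored in the B-factor
field and read from the Cα atom. Chain breaks are an error naming the missing
indices rather than a silent gap, because downstream feature assembly indexes
residues positionally.

SASA is Shrake–Rupley with a golden-angle Fibonacci point set (deterministic
for a fixed point count, default 960; the isolated-sphere error at 960 points
is well under 1%). Van der Waals radii are an element-keyed table (C 1.7,
N 1.55, O 1.52, S 1.8 Å, fallback 1.7) and the probe radius defaults to
1.4 Å. A surface point exactly on another atom's expanded sphere counts as
buried, so coincident atoms fully occlude each other. rASA divides residue
SASA by the Tien et al. (2013) theoretical maximum for the residue type;
because theoretical maxima can be exceeded, rASA is reported unclamped and
values above 1.2 are logged — clamping would distort the feature distribution
the model learns. The SASA contract is defined at atom level, so coarse
fixtures (Cα plus one dummy side-chain sphere) and all-atom models both work.

## Feature schemas

The ordered REDUCED schema holds 17 variant-level features: `psic_wt`,
`psic_var`, `delta_psic`, `blosum62`, hydrophobicity and volume deltas
(variant − wild type; Kyte–Doolittle and Zamyatnin scales), Chou–Fasman
helix/sheet/turn propensities and BLOSUM62 background frequencies of both
residues, and `plddt`, `sasa`, `rasa`. FULL appends the two gene-level
features `protein_length` and `go_term_count`. All scales ship as editable
JSON because the feature families, not the specific scales, are what the
design fixes; the per-residue frequency feature uses the fixed background
table (an alignment-derived variant would be the natural alternative and is
deliberately not emitted, to keep the feature independent of MSA depth).

## Model development

Two tree ensembles are supported: a scikit-learn random forest and an XGBoost
classifier. Performance estimation is nested cross-validation: a stratified
5-fold outer loop scores held-out folds; within each outer-training fold a
3-fold stratified inner loop supplies the objective (mean inner AUROC) for a
Bayesian hyperparameter search, and the winning configuration is refit on the
outer-training fold before scoring. Hyperparameter search never evaluates on
outer-test rows (the report retains the outer-test index sets so this is
assertable). The search is a seeded tree-structured Parzen estimator written
for this package: after a random start-up phase trials are split at the γ =
0.25 quantile, per-dimension Parzen densities l/g are fitted to the good/bad
values, and the candidate maximizing Σ(log l − log g) is suggested. Integer
dimensions round, log-uniform dimensions work in log space, categorical
dimensions use Laplace-smoothed frequencies; determinism follows from the
single seeded generator.

Declared production spaces: RF — trees 100–1000, depth 3–30 or unrestricted
(encoded as an integer dimension whose top sentinel maps to `None`), min leaf
1–10, feature fraction {sqrt, log2, 0.3, 0.5, 0.7, 1.0}; XGB — trees
100–1000, learning rate 1e-3–0.3 log-uniform, depth 2–10, subsample and
column fraction 0.5–1.0. Tests, examples and the acceptance script use a
compact space (trees 50–200) and 4–8 trials per inner loop; these are the
package's desk-scale problem sizes and do not change the procedure. The
decision threshold for binary calls is fixed at 0.5.

Interpretation uses exact path-dependent tree-Shapley attributions: the
recursion carries the subset-weight polynomial along each decision path, and
the conditional expectation splits un-fixed features over children by
training cover. For forests this is implemented here (verified in tests
against explicit subset enumeration on small trees); for XGBoost the
booster's native contribution predictions are used (margin space). In both
cases local accuracy — base value plus attributions equals the model output
per row — holds to 1e-6 or better, and global importance ranks features by
mean absolute attribution. Because the reference distribution is the
path-dependent training cover, no explicit background matrix is required;
the `background` argument exists for API symmetry only.

The full-vs-reduced ablation runs identical stratified folds with fixed
hyperparameters on both matrices, so the AUROC delta is attributable to the
feature set alone; running an inner search per matrix would confound the
delta with search noise at these sizes.

## Evaluation and benchmarking

AUROC uses the rank (Mann–Whitney) formulation with midrank tie correction;
threshold metrics derive from the confusion matrix at 0.5 unless explicit
calls are supplied. Confidence intervals are percentile 2.5/97.5 bootstrap
over 1000 resamples at the original sample size; resamples containing a
single class are excluded and counted, never imputed. Comparator tables are
dbNSFP-style score columns with a per-tool manifest declaring score
orientation (tools where smaller means more damaging are negated before
ranking) and call availability; missing rows are dropped per tool, so each
tool reports its own n, and score-only tools are evaluated on AUROC alone.
Failure-mode stratification flags per-variant success per predictor and bins
variants by the number of call-producing comparators that were correct
([0], [1–2], …, [11–12]), carrying the stratification features (pLDDT,
ΔPSIC, SASA) alongside for distribution plots.

## Consensus reclassification

Tool scores are first normalized onto [0,1] with a monotone map: bounded
scores pass through, min-max for bounded-but-unscaled scores, and rank
normalization for unbounded or heavy-tailed scores (tied values share the
lowest rank of their tie group, divided by n). The per-variant mean of the
configured ensemble (default: model score plus three external tools) is
compared against strict thresholds: > 0.95 → likely pathogenic, < 0.05 →
likely benign, otherwise unchanged — a mean exactly at a threshold does not
move, because the rule is defined with strict inequalities. All configured
tools are required by default (`min_tools` = ensemble size); variants with
fewer available scores stay unchanged with an insufficient-evidence flag.
Summaries cross-tabulate reassignments by gene, prior label and review
status, with totals conserved across every breakdown.

## Synthetic study conditions

The fixture generator is a pure function of (config, seed) and emulates the
statistical structure the classifier is meant to exploit:

- **Proteins** (default 16, lengths 120–220): uniform-random sequences on an
  ideal α-helix (2.3 Å radius, 1.5 Å rise, 100°/residue) with one dummy
  side-chain sphere per residue, so interior residues are occluded by their
  helical neighbors and termini are exposed. pLDDT is ~90 in the core and ~45
  in 15% disordered terminal segments, mimicking the confidence/disorder
  correlation of predicted structures.
- **Alignments** (depth 60): per column, homologs emit the query residue with
  probability c_j (c_j ~ U(0.15, 0.98)), otherwise a uniform background draw;
  no gaps by default.
- **Variants** (default 2000, 40% pathogenic): one variant per selected site.
  Site selection is log-linear — pathogenic sampling weight
  `exp(1.5·z_cons + 1.0·z_buried + 1.0·z_plddt)`, benign the negated
  exponent (Gumbel top-k sampling without replacement). Pathogenic variants
  substitute residues *not observed* among homologs at the column with low
  BLOSUM scores; benign variants prefer residues the alignment has already
  tolerated. This observed/unobserved mechanism is the main source of the
  ΔPSIC separation, exactly as in real cohorts where benign substitutions
  recapitulate evolutionary variation. Emitted labels flip with probability
  0.05 (label noise emulating annotation error); the manifest records the
  true label, the flip flag and every planted quantity and direction, so
  tests assert signal recovery rather than a hard-coded sign. Under these
  defaults a depth-3 boosted-stump oracle on {ΔPSIC, rASA} alone reaches
  AUROC ≥ 0.90 (fixture calibration check), and the full nested-CV pipeline
  reaches ≈ 0.95.
- **Gene-level signal** is off by default (GO counts are noise, so the
  FULL-vs-REDUCED ablation delta is ≈ 0); a switch plants it by biasing
  pathogenic variants toward high-GO proteins, for ablation positive
  controls.
- **Comparator scores** follow a binormal model: positives ~ N(μ,1),
  negatives ~ N(0,1) with μ = √2·Φ⁻¹(AUROC*), squashed by the logistic map
  (monotone, AUROC-preserving); calls threshold at the binormal midpoint.

What the fixture does **not** emulate: real fold geometry (burial contrast is
milder than in globular proteins), gapped alignments and phylogenetic
correlation between homologs, gene-specific mutation spectra, class imbalance
at real ClinVar proportions, and correlated errors between comparator tools.
Passing tests therefore demonstrate that the machinery recovers planted
signal of realistic form and magnitude — not that any particular real-data
AUROC would be attained.

## Numerical choices and degenerate inputs

- Splits and folds are stratified; a single-class pool or a class smaller
  than the outer fold count is an error, not a warning.
- PSIC pseudo-counts guarantee finite scores; columns covered only by gaps in
  homolog rows simply contribute no counts.
- The consensus mean is averaged in canonical tool order, making it exactly
  permutation-invariant at float precision.
- Bootstrap with every resample single-class is an error; n_boot = 1 with a
  fixed seed is reproducible by hand from the returned index matrix.
- SASA with fewer than 10 surface points is rejected as undersampled.
- Model bundles lock the ordered feature schema; prediction on a matrix with
  missing, extra or re-ordered (unnamed) columns fails loudly.

## Known limitations

- The PSIC weighting scheme is one concrete member of the family the cited
  method describes; its four constants (identity threshold, pseudo-weight,
  background, log base) are config knobs but no attempt is made to match any
  specific historical implementation bit-for-bit.
- Path-dependent tree-Shapley (cover-conditioned) is used rather than
  interventional Shapley against an explicit background; rankings can differ
  between the two conventions for strongly correlated features.
- The pipeline consumes precomputed comparator scores; it never runs external
  predictors, and orientation/vocabulary of foreign tables must be declared
  in the tool manifest.
- No probability calibration is applied; scores are used for ranking and for
  the strict consensus thresholds, not as calibrated posteriors.
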