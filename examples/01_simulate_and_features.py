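"""Generate a small synthetic cohort and extract the variant feature matrix.

The generator plants pathogenic variants at conserved, buried,
high-confidence (pLDDT) positions; the class-wise feature means printed at
the end show the planted directions coming back out of the real feature
pipeline (PSIC conservation from the alignments, Shrake-Rupley SASA/rASA and
pLDDT from the structures).
"""

from structvep import pipeline, synthfix

config = synthfix.SyntheticConfig(
    seed=1, n_proteins=6, length_range=(80, 120), n_variants=400,
    msa_depth=30, sasa_points=240,
)
study = synthfix.generate_study(config)
print(f"{len(study.proteins)} proteins, {len(study.variants)} labeled variants")

X, y, meta = pipeline.extract_study_features(study, schema="FULL")
print(f"feature matrix: {X.shape[0]} variants x {X.shape[1]} features "
      f"({y.mean():.0%} pathogenic)")

means = X.assign(pathogenic=y).groupby("pathogenic")[
    ["delta_psic", "rasa", "plddt", "blosum62"]
].mean().round(3)
print("\nclass-wise feature means (0 = benign, 1 = pathogenic):")
print(means)
print(
    "\nPathogenic variants show larger conservation loss (delta_psic), "
    "deeper burial (lower rASA), higher structural confidence (pLDDT) and "
    "more radical substitutions (lower BLOSUM62) -- the planted biology."
)
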