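"""PSIC conservation profiles, substitution/physicochemical features, and
feature-vector assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from structvep import seqfeat
from structvep.seqfeat import (
    AA_INDEX,
    FULL_FEATURES,
    REDUCED_FEATURES,
    Msa,
    assemble_feature_vector,
    compute_psic_profile,
    delta_psic,
    physchem_features,
    schema_features,
    substitution_score,
)
from structvep.structfeat import ResidueStructFeatures
from structvep.tables import AMINO_ACIDS
from structvep.variantio import Label, Origin, ProteinContext, VariantRecord

UNIFORM = np.full(20, 0.05)


def _msa(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Msa(ids[0], rows, ids)


def test_single_row_profile_matches_closed_form():
    """One sequence, uniform background: n_eff = 1 and the observed residue
    scores ln((1 + w*bg) / ((1 + w) * bg)) = ln(1.05 / 0.1)."""
    profile = compute_psic_profile(_msa(["ACD"]), background=UNIFORM)
    assert np.allclose(profile.n_eff, 1.0)
    expected_hit = math.log(1.05 / 0.1)
    expected_miss = math.log(0.05 / 0.1)
    assert profile.score(1, "A") == pytest.approx(expected_hit)
    assert profile.score(2, "C") == pytest.approx(expected_hit)
    for aa in AMINO_ACIDS:
        if aa != "A":
            assert profile.score(1, aa) == pytest.approx(expected_miss)
    assert profile.score(1, "A") > 0 > profile.score(1, "W")


def test_conserved_column_scores_query_highest():
    rows = ["AC" for _ in range(50)]
    profile = compute_psic_profile(_msa(rows), background=UNIFORM)
    for aa in AMINO_ACIDS:
        if aa != "A":
            assert profile.score(1, "A") > profile.score(1, aa)


def test_duplicate_rows_collapse_to_single_count():
    """Exact duplicates form one cluster, so 50 copies give the same profile
    as the single sequence."""
    one = compute_psic_profile(_msa(["ACDEF"]), background=UNIFORM)
    many = compute_psic_profile(_msa(["ACDEF"] * 50), background=UNIFORM)
    assert np.allclose(one.scores, many.scores)
    assert np.allclose(many.n_eff, 1.0)


def test_uniform_column_scores_near_zero():
    """A column carrying every residue once within one cluster is at the
    background, so all scores vanish."""
    stem = "ACDEFGHIKLMNPQRSTVWY"  # shared context keeps identity >= 62%
    rows = [stem * 2 + aa for aa in AMINO_ACIDS]
    profile = compute_psic_profile(_msa(rows), background=UNIFORM)
    col = len(stem) * 2 + 1
    for aa in AMINO_ACIDS:
        assert profile.score(col, aa) == pytest.approx(0.0, abs=1e-12)


def test_profile_columns_normalize_before_log():
    """Implied frequencies exp(score) * bg sum to one per column."""
    rng = np.random.default_rng(0)
    rows = [
        "".join(rng.choice(list(AMINO_ACIDS), size=12)) for _ in range(15)
    ]
    profile = compute_psic_profile(_msa(rows))
    freqs = np.exp(profile.scores) * profile.background
    assert np.allclose(freqs.sum(axis=1), 1.0)


def test_gap_columns_contribute_nothing():
    """Homolog gaps add no counts: a column covered only by the query scores
    like the single-row profile there."""
    profile = compute_psic_profile(_msa(["AC", "-C", "-C"]), background=UNIFORM)
    single = compute_psic_profile(_msa(["AC"]), background=UNIFORM)
    assert profile.n_eff[0] == pytest.approx(1.0)
    assert np.allclose(profile.scores[0], single.scores[0])


@given(
    st.sampled_from(list(AMINO_ACIDS)),
    st.sampled_from(list(AMINO_ACIDS)),
)
def test_delta_psic_antisymmetric(wt, var):
    profile = compute_psic_profile(_msa(["AC", "AG", "TC"]), background=UNIFORM)
    assert delta_psic(profile, 1, wt, var) == pytest.approx(
        -delta_psic(profile, 1, var, wt)
    )


def test_delta_psic_directions():
    profile = compute_psic_profile(_msa(["AC"] * 30), background=UNIFORM)
    assert delta_psic(profile, 1, "A", "A") == 0.0
    assert delta_psic(profile, 1, "A", "W") > 2.0  # conserved column, drastic change


def test_blosum62_lookups_and_symmetry():
    assert substitution_score("A", "A") == 4
    assert substitution_score("W", "C") == -2
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            assert substitution_score(a, b) == substitution_score(b, a)
    with pytest.raises(KeyError):
        substitution_score("A", "Z")


def test_physchem_deltas():
    same = physchem_features("A", "A")
    assert same["d_hydrophobicity"] == 0.0 and same["d_volume"] == 0.0
    assert physchem_features("G", "W")["d_volume"] > 0
    fwd, rev = physchem_features("D", "F"), physchem_features("F", "D")
    assert fwd["d_hydrophobicity"] == pytest.approx(-rev["d_hydrophobicity"])
    assert fwd["d_volume"] == pytest.approx(-rev["d_volume"])
    assert fwd["wt_helix_propensity"] == rev["var_helix_propensity"]


def _variant(pos=1, wt="A", var="W"):
    return VariantRecord(
        gene_symbol="G", protein_accession="P1", position=pos, wt_aa=wt, var_aa=var,
        raw_label="Pathogenic", label=Label.PATHOGENIC, review_stars=2,
        origin=Origin.GERMLINE,
    )


@pytest.fixture
def assembly_inputs():
    ctx = ProteinContext(accession="P1", sequence="ACDEF", go_term_count=17)
    profile = compute_psic_profile(_msa(["ACDEF", "ACDEG", "TCDEF"]), background=UNIFORM)
    struct = ResidueStructFeatures(index=1, aa="A", plddt=88.0, sasa=40.0, rasa=0.31)
    return ctx, profile, struct


def test_schemas_differ_by_gene_level_features(assembly_inputs):
    ctx, profile, struct = assembly_inputs
    full = assemble_feature_vector(_variant(), ctx, struct, profile, "FULL")
    red = assemble_feature_vector(_variant(), ctx, struct, profile, "REDUCED")
    assert len(full.values) == len(red.values) + 2
    assert schema_features("FULL") == REDUCED_FEATURES + ["protein_length", "go_term_count"]
    assert full.as_dict()["protein_length"] == 5.0
    assert full.as_dict()["go_term_count"] == 17.0


def test_assembly_deterministic_and_recomposable(assembly_inputs):
    ctx, profile, struct = assembly_inputs
    v1 = assemble_feature_vector(_variant(), ctx, struct, profile, "FULL")
    v2 = assemble_feature_vector(_variant(), ctx, struct, profile, "FULL")
    assert np.array_equal(v1.values, v2.values)
    expected = {
        "psic_wt": profile.score(1, "A"),
        "psic_var": profile.score(1, "W"),
        "delta_psic": profile.score(1, "A") - profile.score(1, "W"),
        "blosum62": float(substitution_score("A", "W")),
        "plddt": 88.0,
        "sasa": 40.0,
        "rasa": 0.31,
    }
    expected.update(physchem_features("A", "W"))
    got = v1.as_dict()
    for name, value in expected.items():
        assert got[name] == pytest.approx(value), name


def test_assembly_rejects_position_mismatch(assembly_inputs):
    ctx, profile, struct = assembly_inputs
    with pytest.raises(ValueError, match="residue 1"):
        assemble_feature_vector(_variant(pos=2, wt="C"), ctx, struct, profile, "FULL")


def test_feature_extraction_order_independent(small_study):
    from structvep import pipeline

    variants = list(small_study.variants[:40])
    X1, y1, m1 = pipeline.extract_study_features(small_study, variants, "REDUCED")
    shuffled = list(reversed(variants))
    X2, y2, m2 = pipeline.extract_study_features(small_study, shuffled, "REDUCED")
    a = X1.assign(id=m1["id"]).sort_values("id").reset_index(drop=True)
    b = X2.assign(id=m2["id"]).sort_values("id").reset_index(drop=True)
    assert a.equals(b)
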