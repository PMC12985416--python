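"""Variant-table parsing, label harmonization, filtering and splitting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from structvep import variantio
from structvep.variantio import (
    Label,
    Origin,
    ProteinContext,
    VariantRecord,
    filter_variants,
    harmonize_label,
    parse_protein_change,
    parse_variant_table,
    split_train_test,
    validate_mapping,
    write_variant_table,
)


def make_record(
    pos=3, wt="R", var="W", raw="Pathogenic", stars=2, origin=Origin.GERMLINE, gene="BRCA1"
):
    return VariantRecord(
        gene_symbol=gene,
        protein_accession="P38398",
        position=pos,
        wt_aa=wt,
        var_aa=var,
        raw_label=raw,
        label=harmonize_label(raw),
        review_stars=stars,
        origin=origin,
    )


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Pathogenic", Label.PATHOGENIC),
        ("Likely pathogenic", Label.PATHOGENIC),
        ("Pathogenic/Likely pathogenic", Label.PATHOGENIC),
        ("likely BENIGN", Label.BENIGN),
        ("Benign/Likely benign", Label.BENIGN),
        ("Uncertain significance", Label.VUS),
        ("Conflicting interpretations of pathogenicity", Label.CONFLICTING),
        ("Conflicting classifications of pathogenicity", Label.CONFLICTING),
        ("drug response", Label.UNKNOWN),
        ("", Label.UNKNOWN),
    ],
)
def test_harmonize_label(raw, expected):
    assert harmonize_label(raw) is expected


def test_record_invariants():
    with pytest.raises(ValueError):
        make_record(wt="A", var="A")  # synonymous is not missense
    with pytest.raises(ValueError):
        make_record(pos=0)
    with pytest.raises(ValueError):
        make_record(wt="B")


def test_parse_protein_change():
    assert parse_protein_change("p.Arg1699Trp") == ("R", 1699, "W")
    with pytest.raises(ValueError):
        parse_protein_change("p.Arg1699fs")


def test_parse_variant_table_counts_skips(tmp_path):
    """A malformed protein-change row and a synonymous row are skipped and
    counted; well-formed rows survive with direct field mapping."""
    path = tmp_path / "variants.csv"
    path.write_text(
        "gene,accession,position,wt_aa,var_aa,clinical_significance,review_stars,origin\n"
        "BRCA1,P38398,1699,R,W,Pathogenic,3,germline\n"
        "BRCA1,P38398,1699,R,R,Benign,2,germline\n"  # synonymous -> skipped
        "TP53,P04637,175,R,H,Likely pathogenic,2,germline\n"
        "ATM,Q13315,x,R,H,Benign,1,germline\n"  # bad position -> skipped
        "NF1,P21359,1276,G,E,Uncertain significance,1,germline\n"
    )
    records, skips = parse_variant_table(path, with_report=True)
    assert len(records) == 3
    assert sum(skips.values()) == 2
    first = records[0]
    assert (first.gene_symbol, first.position, first.wt_aa, first.var_aa) == (
        "BRCA1", 1699, "R", "W",
    )
    assert first.label is Label.PATHOGENIC


def test_parse_missing_column_is_config_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("gene,accession,position,wt_aa,var_aa,review_stars,origin\n")
    with pytest.raises(KeyError, match="clinical_significance"):
        parse_variant_table(path)


def test_parse_empty_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    assert parse_variant_table(path) == []


def test_hgvs_dialect(tmp_path):
    path = tmp_path / "clinvar.tsv"
    path.write_text(
        "Gene\tUniProt\tChange\tSignificance\tStars\tOrigin\n"
        "BRCA1\tP38398\tp.Arg1699Trp\tPathogenic\t3\tgermline\n"
    )
    dialect = variantio.VariantDialect(
        gene="Gene", accession="UniProt", protein_change="Change",
        position=None, wt_aa=None, var_aa=None,
        label="Significance", review_stars="Stars", origin="Origin",
        delimiter="\t",
    )
    (rec,) = parse_variant_table(path, dialect)
    assert (rec.wt_aa, rec.position, rec.var_aa) == ("R", 1699, "W")


def test_round_trip(tmp_path):
    records = [
        make_record(),
        make_record(pos=10, wt="G", var="E", raw="Likely benign", stars=1),
        make_record(pos=7, wt="K", var="N", raw="Uncertain significance", stars=0),
    ]
    path = tmp_path / "rt.csv"
    write_variant_table(records, path)
    assert parse_variant_table(path) == records


def test_filter_variants_fixture():
    """3 somatic + 2 zero-star germline records out of 10 are removed."""
    records = (
        [make_record(pos=i + 2, origin=Origin.SOMATIC, stars=4) for i in range(3)]
        + [make_record(pos=i + 10, stars=0) for i in range(2)]
        + [make_record(pos=i + 20, stars=1 + i % 3) for i in range(5)]
    )
    kept = filter_variants(records)
    assert len(kept) == 5
    assert all(r.origin is Origin.GERMLINE and r.review_stars >= 1 for r in kept)
    assert kept == [r for r in records if r in kept]  # order preserved


def test_filter_edge_cases():
    germ1 = make_record(stars=1)
    som4 = make_record(pos=5, origin=Origin.SOMATIC, stars=4)
    assert filter_variants([germ1]) == [germ1]
    assert filter_variants([som4]) == []
    assert filter_variants([som4], require_germline=False) == [som4]


@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.sampled_from(list(Origin))), max_size=30
    )
)
def test_filtering_idempotent(spec):
    records = [
        make_record(pos=i + 2, stars=stars, origin=origin)
        for i, (stars, origin) in enumerate(spec)
    ]
    once = filter_variants(records)
    assert filter_variants(once) == once


def test_validate_mapping():
    ctx = ProteinContext(accession="X", sequence="MARK")
    assert validate_mapping(make_record(pos=3, wt="R", var="W"), ctx)
    assert not validate_mapping(make_record(pos=3, wt="K", var="W"), ctx)
    assert not validate_mapping(make_record(pos=99, wt="R", var="W"), ctx)


def _pool(n_path, n_ben):
    return [
        make_record(pos=i + 2, raw="Pathogenic" if i < n_path else "Benign")
        for i in range(n_path + n_ben)
    ]


def test_split_reproduces_published_sizes():
    """An 80/20 stratified split of a 3091-variant pool yields 2473/618."""
    pool = _pool(1000, 2091)
    split = split_train_test(pool, test_fraction=0.2, seed=0)
    assert (len(split.train), len(split.test)) == (2473, 618)


def test_split_deterministic_and_disjoint():
    pool = _pool(5, 5)
    s1 = split_train_test(pool, 0.2, seed=7)
    s2 = split_train_test(pool, 0.2, seed=7)
    assert s1.train == s2.train and s1.test == s2.test
    ids = {r.variant_id for r in s1.train} | {r.variant_id for r in s1.test}
    assert len(ids) == 10
    assert not ({r.variant_id for r in s1.train} & {r.variant_id for r in s1.test})


def test_split_stratification_counts():
    """100 records at a 30/70 class mix give a 6/14 test split."""
    split = split_train_test(_pool(30, 70), 0.2, seed=1)
    n_path_test = sum(r.label is Label.PATHOGENIC for r in split.test)
    assert (n_path_test, len(split.test) - n_path_test) == (6, 14)


@given(st.integers(0, 10_000))
def test_split_sizes_depend_only_on_n_and_fraction(seed):
    split = split_train_test(_pool(20, 30), 0.25, seed=seed)
    assert (len(split.train), len(split.test)) == (38, 12)


def test_split_rejects_single_class_and_vus():
    with pytest.raises(ValueError):
        split_train_test([make_record(pos=i + 2) for i in range(10)], 0.2, 0)
    with pytest.raises(ValueError):
        split_train_test(
            _pool(3, 3) + [make_record(pos=50, raw="Uncertain significance")], 0.2, 0
        )
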