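"""CPM normalization, expression filtering, rank-sum DE and set overlap."""

import numpy as np
import pandas as pd
import pytest

from lcenet.expression import (
    Contrast,
    ExpressionStudy,
    contrasts_from_study,
    cpm,
    de_sets_by_class,
    differential_expression,
    filter_expressed,
    ingest_de_table,
    overlap_de_sets,
    select_de,
)


def _study(counts, classes=None, tissues=None, site="colon"):
    counts = pd.DataFrame(counts)
    counts.index = [f"f{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    classes = pd.Series(classes or ["mRNA"] * counts.shape[0], index=counts.index)
    tissues = tissues or ["normal"] * counts.shape[1]
    samples = pd.DataFrame(
        {"tissue": tissues, "site": site}, index=counts.columns
    )
    return ExpressionStudy(counts, classes, samples)


def test_cpm_arithmetic_and_column_sums():
    counts = pd.DataFrame({"s1": [1, 1, 2]})
    out = cpm(counts, pd.Series({"s1": 4}))
    assert out["s1"].tolist() == [250000.0, 250000.0, 500000.0]
    assert out["s1"].sum() == pytest.approx(1e6)
    assert cpm(pd.DataFrame({"s": [5]}), pd.Series({"s": 100})).iloc[0, 0] == 50000


def test_cpm_zero_library_names_sample():
    with pytest.raises(ValueError, match="s1"):
        cpm(pd.DataFrame({"s1": [1]}), pd.Series({"s1": 0}))


def test_filter_expressed_80_percent_boundary():
    # f0: CPM>1 in 8/10 samples (kept); f1: 7/10 (dropped); f2 always high
    big, small = 500, 0
    rows = {
        "f0": [big] * 8 + [small] * 2,
        "f1": [big] * 7 + [small] * 3,
        "f2": [big] * 10,
    }
    counts = pd.DataFrame(rows).T
    counts.columns = [f"s{i}" for i in range(10)]
    study = ExpressionStudy(
        counts,
        pd.Series(["mRNA"] * 3, index=counts.index),
        pd.DataFrame({"tissue": ["normal"] * 10, "site": "colon"},
                     index=counts.columns),
        library_sizes=pd.Series(1000, index=counts.columns),
    )
    filtered, dropped = filter_expressed(study)
    assert list(filtered.counts.index) == ["f0", "f2"]
    assert list(dropped) == ["f1"]


def test_de_identical_groups_is_null():
    study = _study(
        np.full((2, 8), 50), tissues=["M0"] * 4 + ["normal"] * 4
    )
    contrast = Contrast("colon_M0N", [f"s{i}" for i in range(4)],
                        [f"s{i}" for i in range(4, 8)])
    rec = differential_expression(study, contrast)
    assert rec["log2_fc"].tolist() == [0.0, 0.0]
    assert (rec["p_value"] == 1.0).all()
    assert (rec["direction"] == "down").all()  # sign(0) never counts as up
    assert select_de(rec).empty


def test_de_log2fc_uses_pseudocount():
    study = _study(
        [[100, 110, 90, 10, 9, 11]], tissues=["M0"] * 3 + ["normal"] * 3
    )
    # force CPM == raw values via explicit library sizes of 1e6
    study.library_sizes = pd.Series(1e6, index=study.counts.columns)
    contrast = Contrast("colon_M0N", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    rec = differential_expression(study, contrast)
    assert rec.loc[0, "log2_fc"] == pytest.approx(np.log2(100.5 / 10.5))
    assert rec.loc[0, "direction"] == "up"


def test_de_group_size_contract():
    study = _study(np.full((1, 3), 5), tissues=["M0", "normal", "normal"])
    with pytest.raises(ValueError, match="2 samples"):
        differential_expression(
            study, Contrast("colon_M0N", ["s0"], ["s1", "s2"])
        )


@pytest.mark.parametrize(
    "lfc, fdr, kept",
    [(1.0, 0.049, True), (0.99, 0.001, False), (-1.0, 0.049, True),
     (2.0, 0.05, False)],
)
def test_select_de_boundaries(lfc, fdr, kept):
    rec = pd.DataFrame(
        {"feature_id": ["f"], "feature_class": ["mRNA"], "log2_fc": [lfc],
         "fdr": [fdr], "direction": ["up"]}
    )
    assert (len(select_de(rec)) == 1) is kept


def test_select_de_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    rec = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(50)],
            "feature_class": "mRNA",
            "log2_fc": rng.normal(0, 2, 50),
            "fdr": rng.uniform(size=50),
            "direction": "up",
        }
    )
    tight = set(select_de(rec, 1.5, 0.01)["feature_id"])
    loose = set(select_de(rec, 1.0, 0.05)["feature_id"])
    assert tight <= loose


def test_ingest_external_table_requires_columns():
    with pytest.raises(ValueError, match="fdr"):
        ingest_de_table(pd.DataFrame({"feature_id": [], "feature_class": [],
                                      "log2_fc": []}))
    out = ingest_de_table(
        pd.DataFrame({"feature_id": ["a"], "feature_class": ["mRNA"],
                      "log2_fc": [-2.0], "fdr": [0.01]})
    )
    assert out.loc[0, "direction"] == "down"


def test_overlap_identical_and_disjoint_sets():
    same = overlap_de_sets({"a": {"x", "y"}, "b": {"x", "y"}})
    assert same["common"] == {"x", "y"}
    disj = overlap_de_sets({"a": {"x"}, "b": {"y"}})
    assert disj["common"] == set()
    assert disj["regions"][frozenset(["a"])] == 1


def test_overlap_regions_match_bruteforce():
    rng = np.random.default_rng(5)
    universe = [f"g{i}" for i in range(40)]
    sets = {
        label: {g for g in universe if rng.random() < 0.4}
        for label in ("c1", "c2", "c3", "c4")
    }
    out = overlap_de_sets(sets)
    # brute force: classify every gene by its exact membership pattern
    tally = {}
    for g in universe:
        members = frozenset(l for l, s in sets.items() if g in s)
        if members:
            tally[members] = tally.get(members, 0) + 1
    for combo, count in out["regions"].items():
        assert count == tally.get(combo, 0)
    assert sum(out["regions"].values()) == sum(tally.values())


def test_contrasts_built_from_annotations(fixture_study):
    contrasts = contrasts_from_study(fixture_study.study)
    assert sorted(contrasts) == ["colon_M0N", "colon_M1N", "rectal_M0N", "rectal_M1N"]
    c = contrasts["colon_M1N"]
    assert len(c.group_a) == 20 and len(c.group_b) == 30


def test_planted_de_recovered_in_fixture(fixture_study, pipeline_result):
    # planted 4-fold features should be nearly all selected, right direction
    truth = fixture_study.truth.de_directions["colon_M0N"]
    sel = pipeline_result.de_selected["colon_M0N"]
    found = dict(zip(sel["feature_id"], sel["direction"]))
    hits = sum(1 for f, d in truth.items() if found.get(f) == d)
    assert hits / len(truth) >= 0.9
    sets = de_sets_by_class(sel)
    assert set(fixture_study.truth.lncrna_biomarkers) <= sets["lncRNA"]
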