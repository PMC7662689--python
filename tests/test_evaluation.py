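"""ROC, Kaplan-Meier/log-rank, correlation and over-representation analysis."""

import numpy as np
import pandas as pd
import pytest

from lcenet.evaluation import correlate_pair, gene_set_ora, km_logrank, roc_auc


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),   # perfect separation
        ([0.9, 0.8, 0.2, 0.1], [0, 1, 0, 1], 0.25),  # 1 of 4 concordant pairs
        ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),   # midrank ties
    ],
)
def test_auc_known_values(scores, labels, expected):
    res = roc_auc(scores, labels)
    assert res.auc == pytest.approx(expected)
    assert res.fpr[0] == 0 and res.tpr[0] == 0
    assert res.fpr[-1] == 1 and res.tpr[-1] == 1


def test_auc_single_class_error():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_auc_symmetry_property():
    rng = np.random.default_rng(23)
    for _ in range(100):
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.normal(size=n)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == \
            pytest.approx(1.0)


def _records(times, events, expr):
    return pd.DataFrame({"time": times, "event": events, "expression": expr},
                        index=[f"s{i}" for i in range(len(times))])


def test_logrank_identical_strata_is_null():
    # expression splits the cohort into two strata with identical outcomes
    rec = _records([5, 8, 5, 8], [1, 1, 1, 1], [1, 2, 9, 10])
    res = km_logrank(rec)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_hand_computed_four_deaths():
    # high stratum dies at t=1,2; low at t=9,10; no censoring.
    # Hand tally: O-E = 0.5 + 2/3, V = 0.25 + 2/9 -> chi2 = (7/6)^2 / (17/36)
    rec = _records([1, 2, 9, 10], [1, 1, 1, 1], [10, 9, 1, 2])
    res = km_logrank(rec)
    chi2 = (7 / 6) ** 2 / (17 / 36)
    assert res.statistic == pytest.approx(chi2, rel=1e-6)
    assert set(res.strata[["s0", "s1"]]) == {"high"}
    assert set(res.strata[["s2", "s3"]]) == {"low"}


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(29)
    times = rng.exponential(100, size=40)
    rec = _records(times, np.ones(40, dtype=int), rng.normal(size=40))
    res = km_logrank(rec)
    for name in ("high", "low"):
        sub_times = np.sort(rec.loc[res.strata == name, "time"].to_numpy())
        curve = res.curves[name]
        for t, s in zip(curve["time"], curve["survival"]):
            emp = (sub_times > t + 1e-12).mean()
            assert s == pytest.approx(emp, abs=1e-9)


def test_km_undefined_p_without_events():
    rec = _records([5, 6, 7, 8], [0, 0, 0, 0], [1, 2, 3, 4])
    res = km_logrank(rec)
    assert np.isnan(res.p_value)
    assert set(res.curves) == {"high", "low"}


def test_km_split_fractions():
    rec = _records(np.arange(10.0), np.ones(10, dtype=int), np.arange(10.0))
    res = km_logrank(rec, upper_fraction=0.3, lower_fraction=0.3)
    assert (res.strata == "high").sum() == 3
    assert (res.strata == "low").sum() == 3
    assert (res.strata == "mid").sum() == 4
    with pytest.raises(ValueError):
        km_logrank(rec, upper_fraction=0.7, lower_fraction=0.7)


def test_correlation_known_values():
    assert correlate_pair([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
    r, _ = correlate_pair([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)


def test_correlation_null_is_small():
    rng = np.random.default_rng(31)
    x = rng.normal(size=1000)
    y = rng.permutation(x)
    r, p = correlate_pair(x, y)
    assert abs(r) < 0.1


def test_correlation_zero_variance_undefined_not_error():
    r, p = correlate_pair([1, 1, 1], [1, 2, 3])
    assert np.isnan(r) and np.isnan(p)


def test_ora_known_combinatorics():
    universe = {f"g{i}" for i in range(20)}
    gene_set = {f"g{i}" for i in range(5)}
    query = {"g0", "g1", "g2", "g3", "g10"}  # overlap 4
    res = gene_set_ora(query, universe, {"s": gene_set})
    assert res[0].overlap == 4
    assert res[0].p_value == pytest.approx(76 / 15504)


def test_ora_degenerate_overlaps():
    universe = {"a", "b", "c"}
    full = gene_set_ora(universe, universe, {"s": universe})
    assert full[0].p_value == pytest.approx(1.0)  # forced outcome
    disjoint = gene_set_ora({"a"}, universe, {"s": {"b", "c"}})
    assert disjoint[0].overlap == 0
    assert disjoint[0].p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gene_set_ora({"a"}, set(), {"s": {"a"}})


def test_ora_detects_planted_pathway(fixture_study, pipeline_result):
    study = fixture_study.study
    universe = set(study.counts.index[study.feature_class == "mRNA"])
    sel = pipeline_result.de_selected["colon_M0N"]
    query = set(sel.loc[sel["feature_class"] == "mRNA", "feature_id"])
    res = gene_set_ora(query, universe, fixture_study.gene_sets)
    assert res[0].name == "planted_pathway"
    assert res[0].adj_p < 0.05
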