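"""Ontology classifier: partition semantics, scheme agreement, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from flowerhabit.ontology import (
    FloweringHabitCall,
    FloweringHabitClassifier,
    Thresholds,
    classify_arrays,
    classify_carrotomics,
    classify_grin_baseline,
    summarize_collection,
    trait_dictionary,
)

percent = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


@pytest.mark.parametrize(
    "emm60,emm100,category,subcategory",
    [
        (0.0, 0.0, "biennial", "none"),
        (90.0, 95.0, "annual", "uniformly_early_annual"),
        (10.0, 90.0, "annual", "uniformly_late_annual"),
        (50.0, 90.0, "annual", "non_uniform_annual"),
        (5.0, 12.0, "mixture", "predominantly_biennial"),
        (30.0, 60.0, "mixture", "other_mixture"),
        # boundary semantics: annual strictly > 85, low band <= 15
        (85.0, 85.0, "mixture", "other_mixture"),
        (15.0, 15.0, "mixture", "predominantly_biennial"),
        (15.0, 85.1, "annual", "uniformly_late_annual"),
        (15.1, 86.0, "annual", "non_uniform_annual"),
        (0.0, 0.5, "mixture", "predominantly_biennial"),
        (16.0, 10.0, "mixture", "other_mixture"),  # senesced early annuals
        (100.0, 100.0, "annual", "uniformly_early_annual"),
    ],
)
def test_two_timepoint_classification(emm60, emm100, category, subcategory):
    call = classify_carrotomics(emm60, emm100)
    assert (call.category, call.subcategory) == (category, subcategory)


@pytest.mark.parametrize(
    "emm100,category",
    [(0.0, "biennial"), (100.0, "annual"), (61.4, "mixture"), (0.01, "mixture"), (99.99, "mixture")],
)
def test_baseline_classification(emm100, category):
    assert classify_grin_baseline(emm100).category == category


def test_out_of_range_rejected():
    with pytest.raises(ValueError):
        classify_carrotomics(-1.0, 50.0)
    with pytest.raises(ValueError):
        classify_carrotomics(50.0, 101.0)
    with pytest.raises(ValueError):
        classify_grin_baseline(100.5)


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        Thresholds(t_low=90, t_high=85)
    with pytest.raises(ValueError):
        Thresholds(t_low=0, t_high=85)


def test_call_consistency_enforced():
    with pytest.raises(ValueError):
        FloweringHabitCall("x", "carrotomics", "annual", "predominantly_biennial", 5, 10)
    with pytest.raises(ValueError):
        FloweringHabitCall("x", "grin_baseline", "mixture", "other_mixture", 5, 10)


@settings(deadline=None, max_examples=300)
@given(e60=percent, e100=percent)
def test_partition_total_and_disjoint(e60, e100):
    """Every point of [0,100]^2 gets exactly one valid (category, subcategory)."""
    cat, sub = classify_arrays([e60], [e100])
    call = FloweringHabitCall("x", "carrotomics", str(cat[0]), str(sub[0]), e60, e100)
    assert call.category in ("biennial", "mixture", "annual")
    assert (call.subcategory == "none") == (call.category == "biennial")


@settings(deadline=None, max_examples=200)
@given(e60=percent, e100=percent)
def test_biennial_sets_agree_between_schemes(e60, e100):
    """Both schemes demand literal 0% at 100 DAS for a biennial call."""
    full = classify_carrotomics(e60, e100).category == "biennial"
    base = classify_grin_baseline(e100).category == "biennial"
    assert full == base


def test_raising_t_low_grows_predominantly_biennial():
    rng = np.random.default_rng(0)
    e60 = rng.uniform(0, 100, 500)
    e100 = rng.uniform(0, 100, 500)
    sets = []
    for lo in (10.0, 15.0, 25.0):
        _, sub = classify_arrays(e60, e100, Thresholds(t_low=lo))
        sets.append(frozenset(np.flatnonzero(sub == "predominantly_biennial")))
    assert sets[0] <= sets[1] <= sets[2]
    oth = []
    for lo in (10.0, 15.0, 25.0):
        _, sub = classify_arrays(e60, e100, Thresholds(t_low=lo))
        oth.append(frozenset(np.flatnonzero(sub == "other_mixture")))
    assert oth[2] <= oth[1] <= oth[0]


def test_classifier_estimator_interface():
    clf = FloweringHabitClassifier(t_low=15, t_high=85)
    clf2 = clone(clf).fit()
    X = np.array([[0.0, 0.0], [90.0, 95.0], [5.0, 12.0]])
    assert list(clf2.predict(X)) == ["biennial", "annual", "mixture"]
    assert list(clf2.predict_subcategory(X)) == [
        "none", "uniformly_early_annual", "predominantly_biennial",
    ]
    df = pd.DataFrame({"accession_id": ["a", "b"], "emm60": [0.0, 30.0], "emm100": [0.0, 60.0]})
    calls = clf2.classify_frame(df)
    assert list(calls["category"]) == ["biennial", "mixture"]
    base = FloweringHabitClassifier(scheme="grin_baseline").fit()
    assert list(base.predict(df)) == ["biennial", "mixture"]
    assert clf.get_params()["t_low"] == 15


def test_summary_percentages_match_printed_arithmetic():
    """29.49% of 668 for 197 biennials; 23.95% for 160 predominantly biennial."""
    calls = _synthetic_calls(biennial=197, pred=160, other=250, early=5, late=6, nonuni=50)
    s = summarize_collection(calls)
    assert s.denominator == 668
    assert s.category_percents["biennial"] == 29.49
    assert s.subcategory_percents["predominantly_biennial"] == 23.95
    assert s.subcategory_percents["other_mixture"] == 37.43
    assert s.category_percents["annual"] == 9.13  # 61/668 = 9.1317...
    assert s.subcategory_percents["non_uniform_annual"] == 7.49
    assert s.category_counts["mixture"] == 410
    # subcategory counts sum to parent category counts
    assert s.subcategory_counts["predominantly_biennial"] + s.subcategory_counts[
        "other_mixture"
    ] == s.category_counts["mixture"]
    assert sum(s.category_counts.values()) == s.denominator


def test_summary_all_biennial_and_empty_error():
    calls = _synthetic_calls(biennial=10)
    s = summarize_collection(calls)
    assert s.category_percents["biennial"] == 100.0
    assert all(v == 0 for v in s.subcategory_counts.values())
    assert s.n_flowering_100 == 0
    with pytest.raises(ValueError):
        summarize_collection(pd.DataFrame(columns=["scheme", "category", "subcategory", "emm60", "emm100"]))


def test_trait_dictionary_layout():
    d = trait_dictionary()
    assert {"trait", "definition", "scale", "timepoints_das"} <= set(d.columns)
    assert "predominantly_biennial" in set(d["trait"])


def _synthetic_calls(biennial=0, pred=0, other=0, early=0, late=0, nonuni=0):
    rows = []

    def add(n, cat, sub, e60, e100):
        for _ in range(n):
            rows.append(
                {"accession_id": f"a{len(rows)}", "scheme": "carrotomics",
                 "category": cat, "subcategory": sub, "emm60": e60, "emm100": e100}
            )

    add(biennial, "biennial", "none", 0.0, 0.0)
    add(pred, "mixture", "predominantly_biennial", 0.0, 10.0)
    add(other, "mixture", "other_mixture", 20.0, 50.0)
    add(early, "annual", "uniformly_early_annual", 90.0, 95.0)
    add(late, "annual", "uniformly_late_annual", 5.0, 90.0)
    add(nonuni, "annual", "non_uniform_annual", 50.0, 90.0)
    return pd.DataFrame(rows)
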