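"""ANOVA decompositions, variance components, heritability formulas."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from flowerhabit.simulate import simulate_gaussian_trial
from flowerhabit.varcomp import (
    HeritabilityEstimator,
    VarianceComponentEstimator,
    anova_multi_year,
    anova_single_year,
    estimate_varcomp,
    h2_multi,
    h2_single,
    stars,
)


def test_toy_anova_exact(toy_anova_frame):
    tab = anova_single_year(toy_anova_frame)
    assert tab.loc["accession", "SS"] == pytest.approx(1600.0, abs=1e-9)
    assert tab.loc["block", "SS"] == pytest.approx(150.0, abs=1e-9)
    assert tab.loc["residual", "SS"] == pytest.approx(0.0, abs=1e-9)
    assert tab.loc["accession", "df"] == 2
    assert tab.loc["block", "df"] == 1
    assert tab.loc["residual", "df"] == 2


def test_constant_response_gives_zero_ss(toy_anova_frame):
    obs = toy_anova_frame.assign(pct100=42.0)
    tab = anova_single_year(obs)
    assert tab.loc["accession", "SS"] == pytest.approx(0.0, abs=1e-9)
    assert np.isnan(tab.loc["accession", "F"]) or tab.loc["accession", "F"] == 0.0


def test_type3_equals_sequential_on_balanced_data(balanced_random_frame):
    """Under balance the drop-term (Type III) and sequential decompositions agree."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    one_year = balanced_random_frame[balanced_random_frame["year"] == "Y1"]
    mine = anova_single_year(one_year)
    fit = smf.ols("pct100 ~ C(accession_id, Sum) + C(block, Sum)", data=one_year).fit()
    seq = sm.stats.anova_lm(fit, typ=1)
    assert mine.loc["accession", "SS"] == pytest.approx(seq.loc["C(accession_id, Sum)", "sum_sq"])
    assert mine.loc["block", "SS"] == pytest.approx(seq.loc["C(block, Sum)", "sum_sq"])
    assert mine.loc["residual", "SS"] == pytest.approx(seq.loc["Residual", "sum_sq"])


def test_type3_matches_statsmodels_on_unbalanced_data(balanced_random_frame):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    one_year = balanced_random_frame[balanced_random_frame["year"] == "Y1"].iloc[:-1]
    mine = anova_single_year(one_year)
    fit = smf.ols("pct100 ~ C(accession_id, Sum) + C(block, Sum)", data=one_year).fit()
    t3 = sm.stats.anova_lm(fit, typ=3)
    assert mine.loc["accession", "SS"] == pytest.approx(t3.loc["C(accession_id, Sum)", "sum_sq"])
    assert mine.loc["block", "SS"] == pytest.approx(t3.loc["C(block, Sum)", "sum_sq"])
    assert mine.loc["accession", "F"] == pytest.approx(t3.loc["C(accession_id, Sum)", "F"])


def test_multi_year_terms_and_replication(balanced_random_frame):
    tab = anova_multi_year(balanced_random_frame)
    assert set(tab.index) == {"accession", "year", "accession:year", "block_in_year", "residual"}
    a, ny, r = 8, 3, 2
    assert tab.loc["accession", "df"] == a - 1
    assert tab.loc["year", "df"] == ny - 1
    assert tab.loc["accession:year", "df"] == (a - 1) * (ny - 1)
    assert tab.loc["block_in_year", "df"] == ny * (r - 1)
    assert tab["df"].sum() == len(balanced_random_frame) - 1

    # duplicating one year's data as a second identical year: no year or GxY signal
    one = balanced_random_frame[balanced_random_frame["year"] == "Y1"]
    dup = pd.concat([one, one.assign(year="Y2")], ignore_index=True)
    tab2 = anova_multi_year(dup)
    assert tab2.loc["year", "SS"] == pytest.approx(0.0, abs=1e-9)
    assert tab2.loc["accession:year", "SS"] == pytest.approx(0.0, abs=1e-9)


def test_accession_ss_invariant_to_year_relabeling(balanced_random_frame):
    tab = anova_multi_year(balanced_random_frame)
    relabeled = balanced_random_frame.copy()
    swap = {"Y1": "Y2", "Y2": "Y3", "Y3": "Y1"}
    relabeled["year"] = relabeled["year"].map(swap)
    tab2 = anova_multi_year(relabeled)
    assert tab.loc["accession", "SS"] == pytest.approx(tab2.loc["accession", "SS"])


def test_planted_gxy_is_detected():
    """Strong GxY (Vgy = 4 Ve) should be significant at alpha=0.001 almost always."""
    hits = 0
    n_rep = 100
    for s in range(n_rep):
        sim = simulate_gaussian_trial(30, 2, 2, vg=2.0, vgy=4.0, verror=1.0, seed=1000 + s)
        tab = anova_multi_year(sim)
        hits += tab.loc["accession:year", "p"] <= 0.001
    assert hits / n_rep >= 0.95


def test_single_year_anova_errors(toy_anova_frame):
    with pytest.raises(ValueError):
        anova_single_year(toy_anova_frame[toy_anova_frame["block"] == 1])  # 1 block
    with pytest.raises(ValueError):
        anova_single_year(toy_anova_frame[toy_anova_frame["accession_id"] == "A"])
    with pytest.raises(ValueError):
        anova_multi_year(toy_anova_frame)  # single year


def test_ems_solution_from_mean_squares(balanced_random_frame):
    """MoM components reproduce (MS_g - MS_e)/r etc. from the balanced table."""
    one_year = balanced_random_frame[balanced_random_frame["year"] == "Y1"]
    tab = anova_single_year(one_year)
    c = estimate_varcomp(one_year, scope="single_year", method="ems_mom")
    r = 2
    expected_vg = (tab.loc["accession", "MS"] - tab.loc["residual", "MS"]) / r
    assert c.vg == pytest.approx(max(expected_vg, 0.0))
    assert c.verror == pytest.approx(tab.loc["residual", "MS"])

    multi = estimate_varcomp(balanced_random_frame, scope="multi_year", method="ems_mom")
    mtab = anova_multi_year(balanced_random_frame)
    exp_vgy = (mtab.loc["accession:year", "MS"] - mtab.loc["residual", "MS"]) / r
    exp_vg = (mtab.loc["accession", "MS"] - mtab.loc["accession:year", "MS"]) / (r * 3)
    assert multi.vgy == pytest.approx(max(exp_vgy, 0.0))
    assert multi.vg == pytest.approx(max(exp_vg, 0.0))


def test_negative_components_truncate_with_flag():
    obs = pd.DataFrame(
        {
            "accession_id": ["A", "A", "B", "B"],
            "year": ["Y1"] * 4,
            "block": [1, 2, 1, 2],
            "pct60": [0.0] * 4,
            "pct100": [0.0, 10.0, 10.0, 0.0],  # accession means equal; MS_g < MS_e
        }
    )
    c = estimate_varcomp(obs, scope="single_year", method="ems_mom")
    assert c.vg == 0.0
    assert "vg" in c.truncated


def test_ems_requires_balance(balanced_random_frame):
    with pytest.raises(ValueError):
        estimate_varcomp(balanced_random_frame.iloc[:-1], method="ems_mom")


def test_reml_matches_mom_on_balanced_replicates():
    for s in range(3):
        sim = simulate_gaussian_trial(80, 2, 2, vg=8, vgy=2, verror=4, seed=50 + s)
        mom = estimate_varcomp(sim, method="ems_mom", env_terms="fixed")
        reml = estimate_varcomp(sim, method="reml", env_terms="fixed")
        for name in ("vg", "vgy", "verror"):
            assert getattr(reml, name) == pytest.approx(getattr(mom, name), rel=1e-6)


def test_generic_reml_close_to_balanced_solution():
    """Dropping one plot barely moves the REML solution from the balanced one."""
    sim = simulate_gaussian_trial(40, 2, 2, vg=8, vgy=2, verror=4, seed=77)
    balanced = estimate_varcomp(sim, method="reml", env_terms="fixed")
    unbal = estimate_varcomp(sim.iloc[:-1], method="reml", env_terms="fixed")
    assert unbal.vg == pytest.approx(balanced.vg, rel=0.2)
    assert unbal.verror == pytest.approx(balanced.verror, rel=0.2)


def test_h2_formula_values():
    assert h2_single(9, 2, 2).h2 == pytest.approx(0.9)
    assert h2_multi(8, 2, 4, 2, 2).h2 == pytest.approx(0.8)
    assert h2_single(0, 5, 2).h2 == 0.0
    assert h2_single(3, 0, 2).h2 == 1.0
    assert h2_multi(8, 0, 0, 2, 2).h2 == 1.0
    # algebraic limit: with Vgy = 0 and one year the multi-year denominator
    # collapses to the single-year one
    vg, ve, r = 8.0, 4.0, 2
    assert h2_single(vg, ve, r).h2 == pytest.approx(vg / (vg + 0.0 / 1 + ve / (1 * r)))


def test_h2_errors():
    with pytest.raises(ValueError):
        h2_single(0, 0, 2)
    with pytest.raises(ValueError):
        h2_single(-1, 2, 2)
    with pytest.raises(ValueError):
        h2_multi(8, 2, 4, 1, 2)
    with pytest.raises(ValueError):
        h2_multi(8, -2, 4, 2, 2)


def test_h2_scale_invariance_and_monotonicity():
    sim = simulate_gaussian_trial(60, 2, 2, vg=8, vgy=2, verror=4, seed=3)
    h = HeritabilityEstimator(method="ems_mom", env_terms="fixed").fit(sim).H2_
    scaled = sim.copy()
    scaled[["pct60", "pct100"]] = scaled[["pct60", "pct100"]] * 3.0
    h_scaled = HeritabilityEstimator(method="ems_mom", env_terms="fixed").fit(scaled).H2_
    assert h_scaled == pytest.approx(h, rel=1e-9)
    # monotone in the formula
    assert h2_multi(10, 2, 4, 2, 2).h2 > h2_multi(8, 2, 4, 2, 2).h2
    assert h2_multi(8, 4, 4, 2, 2).h2 < h2_multi(8, 2, 4, 2, 2).h2
    assert h2_multi(8, 2, 8, 2, 2).h2 < h2_multi(8, 2, 4, 2, 2).h2


def test_estimator_interfaces():
    sim = simulate_gaussian_trial(50, 2, 2, vg=8, vgy=2, verror=4, seed=9)
    est = clone(HeritabilityEstimator(method="reml")).fit(sim)
    assert 0.0 <= est.H2_ <= 1.0
    assert est.n_years_ == 2 and est.n_reps_ == 2
    vc = clone(VarianceComponentEstimator(method="ems_mom")).fit(sim)
    assert vc.vg_ >= 0 and vc.verror_ > 0
    assert vc.get_params()["method"] == "ems_mom"


def test_stars_legend():
    assert stars(0.0005) == "***"
    assert stars(0.005) == "**"
    assert stars(0.05) == "*"
    assert stars(0.2) == "NS"
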