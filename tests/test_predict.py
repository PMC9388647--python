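"""Risk prediction scores: AUC, PRAUC, Gini, top-variable selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xwasmeta.predict import (fit_risk_model, gini_coefficient,
                              latest_survey_per_country, lorenz_curve,
                              pr_auc, roc_auc, select_top_variables)
from xwasmeta.types import SurveyDataset


def _auc_oracle(y, s):
    """Brute-force concordance over all positive-negative pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _prauc_oracle(y, s):
    """Exhaustive threshold sweep over descending unique scores."""
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        sel = s >= t
        precision = y[sel].mean()
        recall = y[sel].sum() / y.sum()
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def _gini_oracle(p):
    """Mean absolute pairwise difference over twice the scaled mean."""
    n = len(p)
    return np.abs(p[:, None] - p[None, :]).sum() / (2 * n * n * p.mean())


def test_roc_auc_example_and_oracles():
    y = np.array([1, 0, 1, 0])
    s = np.array([0.9, 0.8, 0.3, 0.2])
    assert roc_auc(y, s) == pytest.approx(0.75)
    assert roc_auc(y, s) == pytest.approx(_auc_oracle(y, s))


def test_roc_auc_perfect_separation_and_ties():
    y = np.array([0, 0, 1, 1])
    assert roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
    s = np.array([0.5, 0.5, 0.5, 0.5])
    assert roc_auc(y, s) == pytest.approx(0.5)  # all tied: chance level


def test_roc_auc_matches_pair_counting_on_random_data():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, n).astype(float)
        if y.min() == y.max():
            continue
        s = rng.choice(np.linspace(0, 1, 7), n)  # heavy ties
        assert roc_auc(y, s) == pytest.approx(_auc_oracle(y, s), abs=1e-12)


def test_roc_auc_rejects_single_class():
    with pytest.raises(ValueError):
        roc_auc(np.ones(5), np.arange(5.0))


@given(st.floats(0.5, 3.0), st.floats(-1.0, 1.0))
def test_roc_auc_invariant_under_increasing_transforms(scale, shift):
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 50).astype(float)
    y[:2] = [0, 1]
    s = rng.random(50)
    assert roc_auc(y, np.exp(scale * s) + shift) == pytest.approx(
        roc_auc(y, s))


def test_pr_auc_example_matches_threshold_sweep_oracle():
    y = np.array([1, 0, 1, 0])
    s = np.array([0.9, 0.8, 0.3, 0.2])
    assert pr_auc(y, s) == pytest.approx(_prauc_oracle(y, s), abs=1e-12)
    # oracle value: 0.5*1.0 + 0.5*(2/3)
    assert pr_auc(y, s) == pytest.approx(0.5 + 0.5 * 2 / 3)


def test_pr_auc_all_positive_is_one_and_no_positive_rejected():
    assert pr_auc(np.ones(4), np.array([0.1, 0.5, 0.5, 0.9])) == 1.0
    with pytest.raises(ValueError):
        pr_auc(np.zeros(4), np.arange(4.0))


def test_pr_auc_matches_oracle_on_random_data():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, n).astype(float)
        if y.sum() == 0:
            continue
        s = rng.choice(np.linspace(0, 1, 9), n)
        assert pr_auc(y, s) == pytest.approx(_prauc_oracle(y, s), abs=1e-12)


def test_random_scorer_calibration():
    """Uniform scores: AUC near 1/2, PRAUC near the outcome prevalence."""
    rng = np.random.default_rng(3)
    for prev in (0.01, 0.061, 0.25):
        n = 40000
        y = (rng.random(n) < prev).astype(float)
        s = rng.random(n)
        se = np.sqrt(prev * (1 - prev) / n)
        assert roc_auc(y, s) == pytest.approx(0.5, abs=0.02)
        assert pr_auc(y, s) == pytest.approx(y.mean(), abs=3 * se + 0.002)


# ----------------------------------------------------------------------
# Gini / Lorenz

def test_gini_constant_risk_is_zero():
    assert gini_coefficient(np.full(50, 0.2)) == pytest.approx(0.0)


def test_gini_two_point_hand_computation():
    # (0, 1): sum|pi-pj| = 2, 2 n^2 pbar = 4 -> G = 0.5
    assert gini_coefficient(np.array([0.0, 1.0])) == pytest.approx(0.5)


def test_gini_scale_invariance_and_double_sum_oracle():
    rng = np.random.default_rng(4)
    p = rng.random(200) ** 2
    g = gini_coefficient(p)
    assert g == pytest.approx(_gini_oracle(p), abs=1e-12)
    assert gini_coefficient(2 * p) == pytest.approx(g, abs=1e-12)


def test_gini_equals_one_minus_twice_lorenz_area():
    rng = np.random.default_rng(5)
    p = rng.gamma(2.0, 1.0, 500)
    lor = lorenz_curve(p)
    # trapezoidal Lorenz integral including the (0, 0) anchor
    xs = np.r_[0.0, lor["population_share"].to_numpy()]
    ys = np.r_[0.0, lor["risk_share"].to_numpy()]
    area = np.trapezoid(ys, xs)
    assert gini_coefficient(p) == pytest.approx(1 - 2 * area, abs=2e-3)


def test_gini_rejects_degenerate_input():
    with pytest.raises(ValueError):
        gini_coefficient(np.zeros(10))
    with pytest.raises(ValueError):
        gini_coefficient(np.array([-0.1, 0.5]))


def test_gini_increases_as_risk_concentrates():
    """Stronger effects concentrate predicted risk in fewer people."""
    rng = np.random.default_rng(6)
    from scipy.special import expit

    x = rng.normal(size=5000)
    ginis = [gini_coefficient(expit(-2 + b * x)) for b in (0.2, 1.0, 2.5)]
    assert ginis[0] < ginis[1] < ginis[2]


# ----------------------------------------------------------------------
# variable selection and the country risk model

def _discovery():
    rows = []
    for i, (r2, ident, nc) in enumerate([
            (0.004, True, 29), (0.003, True, 29), (0.003, True, 29),
            (0.002, True, 12), (0.005, False, 29)]):
        rows.append(dict(variable=f"v{i}", sex="female", identified=ident,
                         mean_r2=r2, p=1e-8, n_countries_assessed=nc,
                         beta=0.4, i2=50.0))
    return pd.DataFrame(rows)


def test_select_top_requires_presence_in_all_countries():
    got = select_top_variables(_discovery(), k=2,
                               countries=[f"C{i}" for i in range(29)],
                               sex="female")
    assert got == ["v0", "v1"]  # ranked by mean R2; v4 not identified


def test_select_top_tie_breaks_lexicographically_and_warns_when_short():
    disc = _discovery()
    disc.loc[disc.variable == "v2", "mean_r2"] = 0.003  # tie with v1
    got = select_top_variables(disc, k=3,
                               countries=[f"C{i}" for i in range(29)])
    assert got == ["v0", "v1", "v2"]
    with pytest.warns(UserWarning, match="eligible"):
        short = select_top_variables(disc, k=10,
                                     countries=[f"C{i}" for i in range(29)])
    assert short == ["v0", "v1", "v2"]


def _prediction_survey(n=2000, seed=0, frac_missing=0.0):
    rng = np.random.default_rng(seed)
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.normal(size=n)
    from scipy.special import expit

    y = (rng.random(n) < expit(-2.5 + 1.2 * x1 + 0.6 * x2)).astype(float)
    if frac_missing:
        x1[rng.random(n) < frac_missing] = np.nan
    df = pd.DataFrame({
        "hiv": y, "weight": np.ones(n), "cluster": np.arange(n) % 50,
        "stratum": np.zeros(n, dtype=int), "hhid": np.arange(n),
        "line": np.ones(n, dtype=int), "wealth": np.ones(n), "age": np.ones(n),
        "rural": np.zeros(n), "x1": x1, "x2": x2,
    })
    return SurveyDataset(survey_id=f"P-2015-female", country="P", year=2015,
                         sex="female", data=df)


def test_risk_model_scores_beat_chance_on_informative_variables():
    rep = fit_risk_model(_prediction_survey(), ["x1", "x2"])
    assert rep is not None
    assert rep.n == 2000 and rep.n_cases + rep.n_controls == rep.n
    assert rep.auc > 0.6
    assert rep.prauc > rep.prevalence
    assert 0 < rep.gini < 1
    assert np.all((rep.probabilities > 0) & (rep.probabilities < 1))


def test_risk_model_complete_case_restriction():
    rep = fit_risk_model(_prediction_survey(frac_missing=0.2, seed=1),
                         ["x1", "x2"])
    assert rep is not None
    assert rep.n < 2000  # incomplete rows dropped


def test_risk_model_skips_when_too_few_cases():
    sv = _prediction_survey(n=300, seed=2)
    sv.data.loc[sv.data["hiv"] == 1, "hiv"] = 0  # wipe out the cases
    assert fit_risk_model(sv, ["x1", "x2"]) is None


def test_latest_survey_selection_prefers_max_year():
    a = _prediction_survey(n=300, seed=3)
    b = _prediction_survey(n=300, seed=4)
    b.year = 2020
    b.survey_id = "P-2020-female"
    latest = latest_survey_per_country([a, b], "female")
    assert latest["P"].year == 2020
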