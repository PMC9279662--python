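"""Risk models, discrimination, calibration, nomogram, KM and Table-style
cohort comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rectomics import (
    RiskModelSpec,
    build_nomogram,
    c_index,
    cohort_compare,
    fit_risk_model,
    hosmer_lemeshow,
    km_stratify,
    roc_auc,
    youden_cutoff,
)
from rectomics.models import (
    encode_design,
    feature_clinical_heatmap,
    fisher_exact_2xk,
    nomogram_probability,
)


# -- logistic fits --------------------------------------------------------

def test_single_binary_covariate_recovers_log_odds_ratio():
    # 2x2 table: exposed 30/10, unexposed 20/40
    rows = (
        [{"x": 1, "os_5yr": 1}] * 30 + [{"x": 1, "os_5yr": 0}] * 10
        + [{"x": 0, "os_5yr": 1}] * 20 + [{"x": 0, "os_5yr": 0}] * 40
    )
    table = pd.DataFrame(rows)
    spec = RiskModelSpec(name="custom", covariates=("x",))
    fitted = fit_risk_model(spec, table)
    lor = np.log((30 / 10) / (20 / 40))
    assert fitted.coefficients["x"] == pytest.approx(lor, abs=1e-4)
    assert fitted.intercept == pytest.approx(np.log(20 / 40), abs=1e-4)


def test_null_covariates_give_small_coefficients(rng):
    n = 2000
    table = pd.DataFrame({
        "x": rng.normal(size=n),
        "os_5yr": (rng.random(n) < 0.7).astype(int),
    })
    fitted = fit_risk_model(RiskModelSpec("custom", ("x",)), table)
    assert abs(fitted.coefficients["x"]) < 0.15


def test_perfect_separation_raises_without_flag():
    table = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0],
                          "os_5yr": [0, 0, 0, 0, 1, 1, 1, 1]})
    spec = RiskModelSpec("custom", ("x",))
    with pytest.raises(RuntimeError, match="separation"):
        fit_risk_model(spec, table)
    fitted = fit_risk_model(spec, table, allow_penalized=True)
    assert fitted.penalized
    assert fitted.coefficients["x"] > 0


def test_categorical_encoding_uses_reference_levels():
    table = pd.DataFrame({"stage": ["IIA", "IIB", "IIIC"]})
    X = encode_design(table, ("stage",))
    assert "stage[IIA]" not in X.columns  # reference level
    assert X.loc[0].sum() == 0
    assert X.loc[2, "stage[IIIC]"] == 1


# -- discrimination -------------------------------------------------------

def brute_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_perfect_and_tied():
    auc, lo, hi = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=100)
    assert auc == 1.0
    assert lo <= auc <= hi
    assert c_index(np.ones(10), [0, 1] * 5) == 0.5


def test_auc_matches_pair_counting_oracle(rng):
    for _ in range(5):
        n = 150
        scores = rng.normal(size=n)
        scores[rng.random(n) < 0.3] = scores[0]  # force ties
        labels = (rng.random(n) < 0.4).astype(int)
        auc, *_ = roc_auc(scores, labels, n_boot=10)
        assert auc == pytest.approx(brute_auc(scores, labels), abs=1e-12)
        assert c_index(scores, labels) == pytest.approx(auc, abs=1e-12)


def test_null_scores_give_chance_auc(rng):
    scores = rng.normal(size=500)
    labels = (rng.random(500) < 0.5).astype(int)
    auc, *_ = roc_auc(scores, labels, n_boot=10)
    # 95% null band for AUC at n1 ~ n0 ~ 250
    assert abs(auc - 0.5) < 1.96 * np.sqrt(501 / (12 * 250 * 250))


def test_bootstrap_ci_brackets_estimate(rng):
    scores = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 140)])
    labels = np.array([1] * 60 + [0] * 140)
    auc, lo, hi = roc_auc(scores, labels, n_boot=500, seed=5)
    assert lo <= auc <= hi
    assert 0.5 < lo and hi < 1.0
    assert roc_auc(scores, labels, n_boot=500, seed=5) == (auc, lo, hi)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


# -- calibration ----------------------------------------------------------

def test_hosmer_lemeshow_perfectly_balanced_ties():
    pred = np.full(100, 0.5)
    obs = np.array([0, 1] * 50)
    chi2, p, _ = hosmer_lemeshow(pred, obs)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


def test_hosmer_lemeshow_rejects_anticalibrated(rng):
    truth = rng.uniform(0.1, 0.9, 1000)
    obs = (rng.random(1000) < truth).astype(float)
    chi2, p, _ = hosmer_lemeshow(1 - truth, obs)
    assert p < 0.001


def test_hosmer_lemeshow_calibration_table(rng):
    pred = rng.uniform(0.1, 0.9, 2000)
    obs = (rng.random(2000) < pred).astype(float)
    _, p, table = hosmer_lemeshow(pred, obs)
    assert len(table) == 10
    np.testing.assert_allclose(table["mean_pred"], table["observed_rate"], atol=0.12)


# -- nomogram -------------------------------------------------------------

def _fitted_toy(rng):
    n = 300
    table = pd.DataFrame({
        "cea": rng.uniform(0, 100, n),
        "lnr": rng.uniform(0, 0.8, n),
        "rad_score": rng.uniform(0, 1, n),
    })
    eta = -1 + 0.02 * table["cea"] - 2 * table["lnr"] + 3 * table["rad_score"]
    table["os_5yr"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    spec = RiskModelSpec("custom", ("cea", "lnr", "rad_score"))
    return fit_risk_model(spec, table), table


def test_nomogram_scales_and_roundtrip(rng):
    fitted, table = _fitted_toy(rng)
    nomo = build_nomogram(fitted, table)
    max_pts = max(s["max_points"] for s in nomo["predictors"].values())
    assert max_pts == pytest.approx(100.0)
    direct = fitted.predict(table)
    via_points = nomogram_probability(nomo, table, fitted)
    np.testing.assert_allclose(via_points, direct, atol=1e-9)


def test_nomogram_reference_patient_probability(rng):
    fitted, table = _fitted_toy(rng)
    nomo = build_nomogram(fitted, table)
    ref_prob = 1 / (1 + np.exp(-nomo["eta_reference"]))
    # a patient sitting at every reference level collects zero points
    ref_row = {}
    for col, s in nomo["predictors"].items():
        ref_row[col] = s["ref"]
    ref_row["os_5yr"] = 0
    prob = fitted.predict(pd.DataFrame([ref_row]))
    assert prob[0] == pytest.approx(ref_prob, abs=1e-12)


# -- KM / risk groups -----------------------------------------------------

def test_youden_cutoff_maximizes_j():
    scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    t = youden_cutoff(scores, labels)
    assert 0.3 < t <= 0.7


def test_km_no_events_reported_not_applicable():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    months = np.array([70.0, 80.0, 90.0, 100.0])
    events = np.zeros(4, bool)
    res = km_stratify(scores, months, events, cutoff=0.5)
    assert res["logrank_p"] is None
    assert "not applicable" in res["note"]


def test_km_equals_one_minus_ecdf_without_censoring(rng):
    months = rng.uniform(5, 59, 40)
    events = np.ones(40, bool)
    scores = np.concatenate([np.zeros(20), np.ones(20)])
    res = km_stratify(scores, months, events, cutoff=0.5)
    km = res["curves"]["high_risk"]
    t_sorted = np.sort(months[:20])
    surv = km.survival_function_at_times(t_sorted).to_numpy()
    ecdf = np.arange(1, 21) / 20
    np.testing.assert_allclose(surv, 1 - ecdf, atol=1e-10)


def test_km_separates_prognostic_scores(rng):
    n = 200
    os_group = rng.random(n) < 0.7
    months = np.where(os_group, rng.uniform(60, 121, n), rng.uniform(5, 59, n))
    scores = np.clip(os_group * 0.5 + rng.normal(0, 0.2, n), 0, 1)
    cutoff = youden_cutoff(scores, os_group.astype(int))
    res = km_stratify(scores, months, ~os_group, cutoff)
    assert res["logrank_p"] < 1e-6


def test_km_tiny_group_rejected():
    with pytest.raises(ValueError, match="< 2 patients"):
        km_stratify(np.array([0.1, 0.9, 0.9, 0.9]), np.array([10.0, 70, 70, 70]),
                    np.array([True, False, False, False]), cutoff=0.5)


# -- cohort comparison ----------------------------------------------------

def brute_fisher_2x2(a, b, c, d):
    """Two-sided Fisher via full hypergeometric enumeration."""
    from math import comb
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = comb(col1, a) * comb(n - col1, row1 - a) / comb(n, row1)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p = comb(col1, x) * comb(n - col1, row1 - x) / comb(n, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_2x2_matches_enumeration_and_scipy(rng):
    for _ in range(10):
        t = rng.integers(1, 40, size=4)
        ours = fisher_exact_2xk(t.reshape(2, 2))
        oracle = brute_fisher_2x2(*t)
        scipy_p = stats.fisher_exact(t.reshape(2, 2)).pvalue
        assert ours == pytest.approx(oracle, abs=1e-10)
        assert ours == pytest.approx(scipy_p, abs=1e-8)


def test_fisher_2xk_extreme_and_uniform_tables():
    assert fisher_exact_2xk(np.array([[20, 0, 0], [0, 20, 20]])) < 1e-6
    assert fisher_exact_2xk(np.array([[5, 5, 5], [5, 5, 5]])) == pytest.approx(1.0)


def test_reference_gender_table_p_rounds_to_printed_value():
    # primary-cohort gender 2x2 (57,9 / 31,17)
    p = fisher_exact_2xk(np.array([[57, 9], [31, 17]]))
    assert round(p, 2) == 0.01


def test_cohort_compare_identical_groups(rng):
    n = 200
    table = pd.DataFrame({
        "age": np.tile(rng.normal(60, 10, n // 2), 2),
        "gender": ["male", "female"] * (n // 2),
        "os_5yr": [0] * (n // 2) + [1] * (n // 2),
    })
    out = cohort_compare(table, continuous=("age",), categorical=("gender",))
    age = out[out.variable == "age"].iloc[0]
    assert age.statistic == pytest.approx(0.0, abs=1e-12)
    assert age.p == pytest.approx(1.0, abs=1e-9)
    gender = out[out.variable == "gender"].iloc[0]
    assert gender.p == pytest.approx(1.0, abs=1e-9)


def test_heatmap_self_correlation_and_rank_invariance(rng):
    f = pd.DataFrame({"a": rng.normal(size=50)})
    clin = pd.DataFrame({"a": f["a"], "b": rng.normal(size=50), "c": np.ones(50)})
    rho = feature_clinical_heatmap(f, clin)
    assert rho.loc["a", "a"] == pytest.approx(1.0)
    assert np.isnan(rho.loc["a", "c"])  # constant masked
    clin2 = clin.assign(b=np.exp(clin["b"]))  # monotone transform
    rho2 = feature_clinical_heatmap(f, clin2)
    assert rho2.loc["a", "b"] == pytest.approx(rho.loc["a", "b"], abs=1e-12)
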