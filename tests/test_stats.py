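"""Association statistics: closed-form oracles, null calibration, power,
threshold and grouping rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from braincog.datatypes import CohortTable
from braincog.errors import ConfigurationError
from braincog.stats import (
    age_slope,
    ancova_group,
    ancova_interaction,
    bonferroni_threshold,
    classify_amyloid,
    education_split,
    remove_twins,
)


def _cohort_frame(n, rng, **extra):
    base = {
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "cohort": "T",
        "site": "s",
        "age": rng.uniform(50, 80, n),
        "sex": rng.choice(["male", "female"], n),
        "diagnosis": "HC",
    }
    base.update(extra)
    return CohortTable(pd.DataFrame(base))


# -- age slope ---------------------------------------------------------------


def test_exact_linear_projection_gives_slope_two_and_zero_p():
    age = np.linspace(50, 80, 30)
    r = age_slope(2.0 * age, age)
    assert r.estimate == pytest.approx(2.0, abs=1e-10)
    assert r.p_value < 1e-200


def test_age_slope_matches_normal_equations_to_ten_digits():
    rng = np.random.default_rng(0)
    age = rng.uniform(50, 80, 60)
    y = 0.3 * age + rng.standard_normal(60)
    r = age_slope(y, age)
    X = np.column_stack([np.ones(60), age])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (60 - 2)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    p = 2 * sps.t.sf(abs(t), 60 - 2)
    assert abs(r.estimate - beta[1]) < 1e-10
    assert abs(r.se - se) < 1e-10
    assert abs(r.statistic - t) < 1e-10
    assert abs(r.p_value - p) < 1e-12


def test_age_slope_null_p_uniform():
    rng = np.random.default_rng(1)
    ps = []
    for _ in range(500):
        age = rng.uniform(50, 80, 100)
        ps.append(age_slope(rng.standard_normal(100), age).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# -- ANCOVA group ------------------------------------------------------------


def test_ancova_f_and_p_match_rss_oracle():
    rng = np.random.default_rng(2)
    n = 80
    cohort = _cohort_frame(n, rng)
    group = rng.choice(["g1", "g2", "g3"], n)
    y = 0.02 * cohort.df["age"].to_numpy() + rng.standard_normal(n)
    r = ancova_group(y, group, cohort, covariates=("age", "sex"))

    age = cohort.df["age"].to_numpy()
    sex = (cohort.df["sex"] == "female").astype(float).to_numpy()
    Xr = np.column_stack([np.ones(n), age, sex])
    d = np.column_stack([(group == "g2").astype(float), (group == "g3").astype(float)])
    Xf = np.column_stack([Xr, d])

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ beta
        return e @ e

    F = ((rss(Xr) - rss(Xf)) / 2) / (rss(Xf) / (n - Xf.shape[1]))
    p = sps.f.sf(F, 2, n - Xf.shape[1])
    assert abs(r.statistic - F) < 1e-10
    assert abs(r.p_value - p) < 1e-12
    assert r.n_used == n


def test_ancova_null_p_uniform_with_shared_age_effect():
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(300):
        n = 60
        cohort = _cohort_frame(n, rng)
        group = rng.choice(["a", "b"], n)
        y = 0.05 * cohort.df["age"].to_numpy() + rng.standard_normal(n)
        ps.append(ancova_group(y, group, cohort, covariates=("age",)).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_one_sd_group_offset_detected_at_corrected_threshold():
    rng = np.random.default_rng(4)
    hits = 0
    n_sim = 100
    thr = bonferroni_threshold(0.05, 14)
    for _ in range(n_sim):
        n = 300
        cohort = _cohort_frame(n, rng)
        group = np.r_[["a"] * (n // 2), ["b"] * (n // 2)]
        y = 0.05 * cohort.df["age"].to_numpy() + rng.standard_normal(n)
        y[n // 2 :] += 1.0  # one residual-sd offset
        hits += ancova_group(y, group, cohort, covariates=("age", "sex")).p_value < thr
    assert hits >= 0.9 * n_sim


def test_confounded_group_design_rejected():
    rng = np.random.default_rng(5)
    n = 40
    cohort = _cohort_frame(n, rng, sex=["male"] * (n // 2) + ["female"] * (n // 2))
    group = np.r_[["a"] * (n // 2), ["b"] * (n // 2)]  # group == sex
    with pytest.raises(ConfigurationError, match="singular|confounded"):
        ancova_group(rng.standard_normal(n), group, cohort, covariates=("sex",))


# -- interaction -------------------------------------------------------------


def test_interaction_null_uniform_and_relabel_invariant():
    rng = np.random.default_rng(6)
    ps = []
    for _ in range(200):
        n = 60
        cohort = _cohort_frame(n, rng)
        group = rng.choice(["a", "b"], n)
        age = cohort.df["age"].to_numpy()
        y = 0.1 * age + rng.standard_normal(n)  # equal slopes
        ps.append(ancova_interaction(y, group, age, cohort).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01

    n = 80
    cohort = _cohort_frame(n, rng)
    group = rng.choice(["a", "b"], n)
    age = cohort.df["age"].to_numpy()
    y = 0.1 * age + rng.standard_normal(n)
    p1 = ancova_interaction(y, group, age, cohort).p_value
    swapped = np.where(group == "a", "b", "a")
    p2 = ancova_interaction(y, swapped, age, cohort).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_planted_slope_difference_detected():
    rng = np.random.default_rng(7)
    hits = 0
    n_sim = 60
    for _ in range(n_sim):
        n_per = 300
        cohort = _cohort_frame(2 * n_per, rng)
        group = np.r_[["a"] * n_per, ["b"] * n_per]
        age = cohort.df["age"].to_numpy()
        slopes = np.where(group == "a", 1.0, 0.2)
        y = slopes * age + 5.0 * rng.standard_normal(2 * n_per)
        hits += ancova_interaction(y, group, age, cohort).p_value < 0.05
    assert hits >= 0.9 * n_sim


# -- thresholds, amyloid, education, twins ----------------------------------


def test_bonferroni_threshold_values():
    thr = bonferroni_threshold(0.05, 14)
    assert thr == pytest.approx(0.05 / 14)
    assert thr < 0.004  # the printed corrected threshold bound
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.04, 2) == pytest.approx(0.02)
    with pytest.raises(ConfigurationError):
        bonferroni_threshold(0.05, 0)


def test_amyloid_threshold_strictly_greater_than_20():
    out = classify_amyloid([25.0, 15.0, 20.0])
    assert list(out) == ["positive", "negative", "negative"]


def test_education_split_uses_healthy_median_only():
    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": ["A", "B", "C", "D"],
                "cohort": "T",
                "site": "s",
                "age": [60.0] * 4,
                "sex": ["male"] * 4,
                "diagnosis": ["HC", "HC", "HC", "AD"],
                "education": [10.0, 12.0, 14.0, 20.0],
            }
        )
    )
    out = education_split([13.0, 12.0, 11.0], cohort)
    assert list(out) == ["above", "below", "below"]  # HC median 12; ties below
    # AD education (20) must not shift the median
    out2 = education_split([13.0], cohort)
    assert out2[0] == "above"


def test_twin_removal_keeps_lexicographically_first():
    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": ["Z9", "A1", "M5"],
                "cohort": "T",
                "site": "s",
                "age": [60.0] * 3,
                "sex": ["male"] * 3,
                "diagnosis": ["HC"] * 3,
                "twin_pair": ["T1", "T1", ""],
            }
        )
    )
    kept = remove_twins(cohort)
    assert sorted(kept.subject_ids) == ["A1", "M5"]
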