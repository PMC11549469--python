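"""Score orientation, hemisphere averaging, ICV correction and the
fit/apply preprocessing contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from braincog.datatypes import CohortTable, FeatureBlock
from braincog.errors import ConfigurationError, FormatError
from braincog.preprocess import (
    apply_preprocess,
    average_hemispheres,
    drop_sparse_features,
    fit_preprocess,
    icv_correct,
    orient_scores,
)
from braincog.synthetic import SimulationConfig, simulate_cohort
from conftest import make_block


# -- orientation -------------------------------------------------------------


def test_orientation_negates_only_negative_tests():
    block = FeatureBlock(
        ["S0"], ["rt", "accuracy"], np.array([[300.0, 0.8]]), "cognition"
    )
    out = orient_scores(block, {"rt": "negative", "accuracy": "positive"})
    assert out.values[0, 0] == -300.0
    assert out.values[0, 1] == 0.8


def test_orientation_preserves_missing_and_requires_full_map():
    block = FeatureBlock(["S0"], ["rt"], np.array([[np.nan]]), "cognition")
    out = orient_scores(block, {"rt": "negative"})
    assert np.isnan(out.values[0, 0])
    with pytest.raises(ConfigurationError, match="without orientation"):
        orient_scores(block, {})


def test_orientation_makes_better_performers_score_higher():
    """After orientation every test mean is higher in a planted
    better-performing subgroup, whatever the raw polarity."""
    rng = np.random.default_rng(0)
    n = 200
    ability = np.r_[np.zeros(n // 2), np.ones(n // 2)]  # second half better
    acc = 0.5 + 0.3 * ability + 0.05 * rng.standard_normal(n)
    rt = 400 - 100 * ability + 10 * rng.standard_normal(n)  # lower rt = better
    block = FeatureBlock(
        [f"S{i}" for i in range(n)], ["acc", "rt"], np.column_stack([acc, rt]), "cognition"
    )
    out = orient_scores(block, {"acc": "positive", "rt": "negative"})
    better, worse = out.values[n // 2 :], out.values[: n // 2]
    assert (better.mean(axis=0) > worse.mean(axis=0)).all()


# -- hemisphere averaging ----------------------------------------------------


def test_paired_hemispheres_average():
    block = FeatureBlock(
        ["S0"], ["S.C._left", "S.C._right"], np.array([[2.0, 4.0]]), "brain"
    )
    out = average_hemispheres(block)
    assert out.feature_labels == ["S.C."]
    assert out.values[0, 0] == 3.0


def test_one_side_missing_uses_available_side_both_missing_stays_missing():
    block = FeatureBlock(
        ["S0", "S1"],
        ["S.C._left", "S.C._right"],
        np.array([[np.nan, 4.0], [np.nan, np.nan]]),
        "brain",
    )
    out = average_hemispheres(block)
    assert out.values[0, 0] == 4.0
    assert np.isnan(out.values[1, 0])


def test_127_labels_with_63_pairs_yield_64_features():
    """63 bilateral sulci plus one left-only sulcus collapse to 64 unique
    measurements."""
    labels = []
    for j in range(63):
        labels += [f"sulcus{j:02d}_left", f"sulcus{j:02d}_right"]
    labels.append("sulcus63_left")  # left-only, no right homolog
    assert len(labels) == 127
    rng = np.random.default_rng(1)
    block = FeatureBlock(["S0", "S1"], labels, rng.standard_normal((2, 127)), "brain")
    out = average_hemispheres(block)
    assert out.n_features == 64
    assert "sulcus63_left" in out.feature_labels  # unpaired kept as-is


def test_duplicate_base_label_is_format_error():
    block = FeatureBlock(
        ["S0"], ["a_left", "a_right", "a"], np.ones((1, 3)), "brain"
    )
    with pytest.raises(FormatError, match="duplicate"):
        average_hemispheres(block)


# -- sparse-feature exclusion ------------------------------------------------


def test_sparse_drop_thresholds_strictly():
    vals = np.ones((10, 3))
    vals[:6, 0] = np.nan  # 60% missing -> dropped
    vals[:5, 1] = np.nan  # exactly 50% -> kept under the strict rule
    block = make_block(vals)
    out, dropped = drop_sparse_features(block, 0.5)
    assert dropped == ["f0"]
    assert out.feature_labels == ["f1", "f2"]


def test_64_features_with_3_sparse_leave_61():
    rng = np.random.default_rng(2)
    vals = rng.standard_normal((40, 64))
    vals[:30, [5, 17, 40]] = np.nan  # 75% missing in three sulci
    out, dropped = drop_sparse_features(make_block(vals), 0.5)
    assert len(dropped) == 3
    assert out.n_features == 61


# -- ICV correction ----------------------------------------------------------


def test_icv_correction_formula():
    assert icv_correct(4000.0, 1.5e6, 1.5e6) == 4000.0
    assert icv_correct(4000.0, 3.0e6, 1.5e6) == 2000.0


@given(factor=st.floats(0.1, 10.0))
def test_icv_correction_invariant_to_common_icv_rescaling(factor):
    hv, icv, mean_icv = 4100.0, 1.4e6, 1.55e6
    a = icv_correct(hv, icv, mean_icv)
    b = icv_correct(hv, icv * factor, mean_icv * factor)
    assert np.isclose(a, b, rtol=1e-12)


# -- fit/apply ---------------------------------------------------------------


def _tiny_tables():
    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": ["A", "B", "C"],
                "cohort": "T",
                "site": "s",
                "age": [50.0, 60.0, 70.0],
                "sex": ["male", "female", "male"],
                "diagnosis": ["HC", "HC", "HC"],
            }
        )
    )
    brain = FeatureBlock(
        ["A", "B", "C"], ["b0", "b1"], np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]]),
        "brain",
    )
    cog = FeatureBlock(
        ["A", "B", "C"], ["c0"], np.array([[0.0], [1.0], [2.0]]), "cognition"
    )
    return cohort, brain, cog


def test_impute_mean_from_fit_cohort():
    cohort, brain, cog = _tiny_tables()
    params = fit_preprocess(brain, cog, cohort, ["A", "B", "C"])
    assert params.brain.impute_means[0] == 2.0  # mean of [1, ., 3]


def test_apply_on_fit_cohort_gives_zero_mean_unit_sd(planted_cohort):
    cohort, brain, cog, _ = planted_cohort
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cog, cohort, ids)
    X = apply_preprocess(brain, cohort, params)
    assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_heldout_subject_at_fit_mean_maps_to_zero_row(planted_cohort):
    cohort, brain, cog, _ = planted_cohort
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cog, cohort, ids)
    mean_profile = np.nanmean(brain.reorder(ids).values, axis=0)
    newcomer = FeatureBlock(["NEW"], brain.feature_labels, mean_profile[None, :], "brain")
    new_cohort = CohortTable(cohort.df.iloc[:1].assign(subject_id="NEW"))
    row = apply_preprocess(newcomer, new_cohort, params)
    assert np.allclose(row, 0.0, atol=1e-9)


def test_residualize_exact_linear_feature():
    cohort, brain, cog = _tiny_tables()
    age = cohort.df["age"].to_numpy()
    lin = FeatureBlock(["A", "B", "C"], ["b0"], 2.0 * age[:, None], "brain")
    params = fit_preprocess(lin, cog, cohort, ["A", "B", "C"], residualize=True)
    assert np.isclose(params.brain.residual_coefs[1, 0], 2.0, atol=1e-9)
    filled = 2.0 * age[:, None]
    X = np.column_stack([np.ones(3), age, (cohort.df["sex"] == "female").astype(float)])
    residuals = filled - X @ params.brain.residual_coefs
    assert np.abs(residuals).max() < 1e-9


def test_residual_coefficients_match_normal_equations(planted_cohort):
    cohort, brain, cog, _ = planted_cohort
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cog, cohort, ids, residualize=True)
    filled = np.where(
        np.isnan(brain.reorder(ids).values),
        params.brain.impute_means,
        brain.reorder(ids).values,
    )
    age = cohort.df["age"].to_numpy(dtype=float)
    sex = (cohort.df["sex"].to_numpy() == "female").astype(float)
    X = np.column_stack([np.ones(len(age)), age, sex])
    oracle = np.linalg.solve(X.T @ X, X.T @ filled)
    assert np.allclose(params.brain.residual_coefs, oracle, atol=1e-12)


def test_residualization_removes_planted_age_effect():
    cfg = SimulationConfig(n_subjects=500, beta_age=0.8, mode_strength=1.0, seed=9)
    cohort, brain, cog, _ = simulate_cohort(cfg)
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cog, cohort, ids, residualize=True)
    X = apply_preprocess(brain, cohort, params)
    age = cohort.df["age"].to_numpy(dtype=float)
    agez = (age - age.mean()) / age.std(ddof=1)
    corr = np.abs(X.T @ agez / (len(age) - 1))
    assert corr.max() <= 0.05


def test_refit_on_preprocessed_output_is_idempotent(planted_cohort):
    cohort, brain, cog, _ = planted_cohort
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cog, cohort, ids)
    X = apply_preprocess(brain, cohort, params)
    again = FeatureBlock(ids, brain.feature_labels, X, "brain")
    params2 = fit_preprocess(again, cog, cohort, ids)
    assert np.allclose(params2.brain.feature_means, 0.0, atol=1e-12)
    assert np.allclose(params2.brain.feature_sds, 1.0, atol=1e-12)


def test_imputation_never_changes_observed_entries(planted_cohort):
    cohort, brain, cog, _ = planted_cohort
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cog, cohort, ids)
    X = apply_preprocess(brain, cohort, params)
    vals = brain.reorder(ids).values
    observed = ~np.isnan(vals)
    reconstructed = X * params.brain.feature_sds + params.brain.feature_means
    assert np.allclose(reconstructed[observed], vals[observed], atol=1e-9)
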