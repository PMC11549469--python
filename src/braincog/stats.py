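"""Association statistics between projections and risk factors.

Covers the study's exact model structure: a two-sided Wald t-test for the
age slope (OLS), ANCOVAs for group effects (nested-model F-test of the
group factor over covariates), group-by-age interaction ANCOVAs, the
Bonferroni family threshold (0.05 over 14 tests -> p < 0.004), amyloid
status thresholding at 20 centiloids, and the healthy-median education
split.  Twin pairs are reduced to one member before any ANCOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .datatypes import CohortTable
from .errors import ConfigurationError

__all__ = [
    "AssociationResult",
    "age_slope",
    "ancova_group",
    "ancova_interaction",
    "bonferroni_threshold",
    "classify_amyloid",
    "education_split",
    "remove_twins",
]


@dataclass
class AssociationResult:
    """One fitted association: estimate, test statistic and p-value."""

    term: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    model: str
    covariates: list = field(default_factory=list)
    n_used: int = 0


def age_slope(projection, age) -> AssociationResult:
    """OLS slope of a projection on age with a two-sided Wald t-test."""
    projection = np.asarray(projection, dtype=float)
    age = np.asarray(age, dtype=float)
    if projection.size != age.size or projection.size < 4:
        raise ConfigurationError("need equal-length vectors with n >= 4")
    X = sm.add_constant(age)
    fit = sm.OLS(projection, X).fit()
    return AssociationResult(
        term="age",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        model="wald_age",
        covariates=[],
        n_used=int(fit.nobs),
    )


def remove_twins(cohort: CohortTable) -> CohortTable:
    """Keep the lexicographically first subject_id of each twin pair."""
    df = cohort.df
    if "twin_pair" not in df.columns:
        return cohort
    pair = df["twin_pair"].astype(str).replace({"nan": "", "None": ""})
    has_pair = pair.ne("") & pair.notna()
    keep = np.ones(len(df), dtype=bool)
    for label in pair[has_pair].unique():
        members = df.loc[pair.eq(label), "subject_id"].astype(str).sort_values()
        drop_ids = members.iloc[1:]
        keep &= ~df["subject_id"].astype(str).isin(drop_ids)
    return CohortTable(df.loc[keep].reset_index(drop=True))


def _covariate_columns(df: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "sex":
            cols.append((df["sex"].to_numpy() == "female").astype(float))
        else:
            cols.append(pd.to_numeric(df[cov]).to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def _nested_f(y, X_reduced, X_full, df_diff):
    fit_r = sm.OLS(y, X_reduced).fit()
    fit_f = sm.OLS(y, X_full).fit()
    rss_r, rss_f = fit_r.ssr, fit_f.ssr
    df_resid = fit_f.df_resid
    F = ((rss_r - rss_f) / df_diff) / (rss_f / df_resid)
    p = float(sps.f.sf(F, df_diff, df_resid))
    return fit_f, float(F), p


def ancova_group(
    projection,
    group,
    cohort: CohortTable,
    covariates=("age", "sex"),
    drop_twins: bool = True,
) -> AssociationResult:
    """ANCOVA group effect: nested-model F-test over the covariates.

    ``projection`` and ``group`` align with ``cohort`` rows.  Subjects with
    a missing group label are excluded; one of each twin pair is removed
    first.  Extra continuous covariates (e.g. a polygenic risk score named
    in ``covariates``) are read from the cohort table.
    """
    df = cohort.df.copy()
    df["_proj"] = np.asarray(projection, dtype=float)
    df["_group"] = pd.Series(np.asarray(group, dtype=object), index=df.index)
    sub = CohortTable(df)
    if drop_twins:
        sub = remove_twins(sub)
    data = sub.df
    ok = data["_group"].notna() & data["_group"].astype(str).ne("")
    for cov in covariates:
        col = data[cov] if cov != "sex" else data["sex"]
        ok &= col.notna()
    data = data.loc[ok]
    levels = sorted(data["_group"].astype(str).unique())
    if len(levels) < 2 or data["_group"].value_counts().min() < 2:
        raise ConfigurationError("group needs >= 2 levels with >= 2 subjects each")

    y = data["_proj"].to_numpy(dtype=float)
    C = _covariate_columns(data, covariates)
    X_reduced = np.column_stack([np.ones(len(data)), C])
    dummies = np.column_stack(
        [(data["_group"].astype(str) == lev).to_numpy(float) for lev in levels[1:]]
    )
    X_full = np.column_stack([X_reduced, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ConfigurationError("singular design: group confounded with covariates")
    fit_f, F, p = _nested_f(y, X_reduced, X_full, dummies.shape[1])
    two_level = len(levels) == 2
    return AssociationResult(
        term="group:" + "/".join(levels),
        estimate=float(fit_f.params[-1]) if two_level else float("nan"),
        se=float(fit_f.bse[-1]) if two_level else float("nan"),
        statistic=F,
        p_value=p,
        model="ancova",
        covariates=list(covariates),
        n_used=len(data),
    )


def ancova_interaction(
    projection,
    group,
    age,
    cohort: CohortTable,
    covariates=("sex",),
    drop_twins: bool = True,
) -> AssociationResult:
    """Group-by-age interaction: F-test of the interaction terms.

    Model: projection ~ covariates + group + age + group x age; the
    interaction block is tested against the additive model.
    """
    df = cohort.df.copy()
    df["_proj"] = np.asarray(projection, dtype=float)
    df["_group"] = pd.Series(np.asarray(group, dtype=object), index=df.index)
    df["_age"] = np.asarray(age, dtype=float)
    sub = CohortTable(df)
    if drop_twins:
        sub = remove_twins(sub)
    data = sub.df
    ok = data["_group"].notna() & data["_group"].astype(str).ne("")
    data = data.loc[ok]
    levels = sorted(data["_group"].astype(str).unique())
    if len(levels) < 2 or data["_group"].value_counts().min() < 2:
        raise ConfigurationError("group needs >= 2 levels with >= 2 subjects each")

    y = data["_proj"].to_numpy(dtype=float)
    a = data["_age"].to_numpy(dtype=float)
    C = _covariate_columns(data, covariates)
    dummies = np.column_stack(
        [(data["_group"].astype(str) == lev).to_numpy(float) for lev in levels[1:]]
    )
    X_add = np.column_stack([np.ones(len(data)), C, dummies, a])
    inter = dummies * a[:, None]
    X_full = np.column_stack([X_add, inter])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ConfigurationError("singular design for interaction model")
    fit_f, F, p = _nested_f(y, X_add, X_full, inter.shape[1])
    two_level = len(levels) == 2
    return AssociationResult(
        term="age x group:" + "/".join(levels),
        estimate=float(fit_f.params[-1]) if two_level else float("nan"),
        se=float(fit_f.bse[-1]) if two_level else float("nan"),
        statistic=F,
        p_value=p,
        model="ancova_interaction",
        covariates=list(covariates),
        n_used=len(data),
    )


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 14) -> float:
    """Family-wise threshold alpha / n_tests (0.05 / 14 ~= 0.00357 < 0.004)."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    return alpha / n_tests


def classify_amyloid(centiloid) -> np.ndarray:
    """Amyloid status from centiloid value: positive iff strictly > 20 CL."""
    cl = np.asarray(centiloid, dtype=float)
    if not np.isfinite(cl).all():
        raise ConfigurationError("centiloid values must be finite")
    out = np.where(cl > 20.0, "positive", "negative")
    return out if out.ndim else str(out)


def education_split(education, cohort: CohortTable) -> np.ndarray:
    """Above/below the healthy-participant median education.

    The median is computed over HC subjects only; values strictly above it
    are "above", ties and lower values are "below".
    """
    edu = np.asarray(education, dtype=float)
    hc = (cohort.df["diagnosis"].to_numpy() == "HC") & ~np.isnan(
        pd.to_numeric(cohort.df["education"], errors="coerce").to_numpy(dtype=float)
    )
    if not hc.any():
        raise ConfigurationError("no healthy subject with education available")
    median = float(
        np.median(pd.to_numeric(cohort.df["education"]).to_numpy(dtype=float)[hc])
    )
    return np.where(edu > median, "above", "below")
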