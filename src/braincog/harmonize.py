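"""Empirical-Bayes location/scale batch harmonization (parametric ComBat).

Removes additive and multiplicative site/scanner effects from brain
features while preserving declared biological covariates (age, sex,
diagnosis).  This follows the canonical parametric formulation from the
genomics literature: per-feature least squares with site indicators
constrained to a weighted zero sum, standardization by the pooled residual
sd, then empirical-Bayes shrinkage of per-site location (normal prior) and
scale (inverse-gamma prior, moment-matched) via iterative conditional
estimation.

Missing entries are handled by per-feature complete-case fitting and
adjusted only where observed, the minimal extension of the complete-data
formulation.  Sites with three or fewer subjects are excluded from fitting
(with a warning).  With a single site the model is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CohortTable, FeatureBlock
from .errors import AlignmentError, ConfigurationError

__all__ = ["CombatModel", "fit_combat", "apply_combat"]

DEFAULT_COVARIATES = ("age", "sex", "diagnosis")


@dataclass
class CombatModel:
    """Fitted ComBat parameters.

    ``grand_alpha`` (p,) per-feature intercept; ``beta`` (c, p) covariate
    coefficients; ``gamma_star`` / ``delta_star`` (n_sites, p) EB site
    location / variance; ``pooled_sd`` (p,) residual scale; ``site_list``
    the sites seen at fit time.  ``identity`` marks the single-site case.
    """

    feature_labels: list[str]
    covariates: tuple
    site_list: list[str]
    grand_alpha: np.ndarray
    beta: np.ndarray
    gamma_star: np.ndarray
    delta_star: np.ndarray
    pooled_sd: np.ndarray
    identity: bool = False
    eb: bool = True
    n_iter: int = 0
    dx_levels: tuple = ()


def _covariate_matrix(
    cohort: CohortTable, covariates, dx_levels=None
) -> tuple[np.ndarray, list[str], tuple]:
    """Design columns for the preserved covariates.

    ``dx_levels`` fixes which diagnosis indicators to emit (non-HC levels
    present at fit time), so apply-time designs match the fitted model.
    """
    cols, names = [], []
    for cov in covariates:
        if cov == "age":
            cols.append(cohort.df["age"].to_numpy(dtype=float))
            names.append("age")
        elif cov == "sex":
            cols.append(cohort.sex_indicator())
            names.append("sex")
        elif cov == "diagnosis":
            dx = cohort.df["diagnosis"].to_numpy()
            if dx_levels is None:
                dx_levels = tuple(l for l in ("MCI", "AD") if (dx == l).any())
            for level in dx_levels:
                cols.append((dx == level).astype(float))
                names.append(f"dx_{level}")
        else:
            cols.append(pd.to_numeric(cohort.df[cov]).to_numpy(dtype=float))
            names.append(cov)
    if dx_levels is None:
        dx_levels = ()
    if not cols:
        return np.empty((cohort.n_subjects, 0)), [], dx_levels
    return np.column_stack(cols), names, dx_levels


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def fit_combat(
    block: FeatureBlock,
    cohort: CohortTable,
    covariates=DEFAULT_COVARIATES,
    eb: bool = True,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CombatModel:
    """Fit the harmonization model on a feature block.

    Parameters
    ----------
    block, cohort
        Feature block and aligned metadata (aligned internally by id).
    covariates
        Biological covariates to preserve; ``diagnosis`` expands to MCI/AD
        indicators against the HC reference.
    eb
        Empirical-Bayes shrinkage of site effects.  ``eb=False`` uses the
        raw per-site estimates (exact per-site standardization of the
        residuals), useful for closed-form checks.
    """
    block = block.reorder(cohort.subject_ids)
    sites_all = cohort.df["site"].astype(str).to_numpy()
    counts = pd.Series(sites_all).value_counts()
    site_list = sorted(counts.index[counts > 3])
    dropped_sites = sorted(set(counts.index) - set(site_list))
    if dropped_sites:
        warnings.warn(
            f"excluding sites with <= 3 subjects: {dropped_sites}", stacklevel=2
        )
    if not site_list:
        raise ConfigurationError("no site has more than 3 subjects")
    keep = np.isin(sites_all, site_list)
    Y = block.values[keep]
    sites = sites_all[keep]
    sub_cohort = CohortTable(cohort.df.loc[keep].reset_index(drop=True))
    X, cov_names, dx_levels = _covariate_matrix(sub_cohort, covariates)
    n, p = Y.shape
    n_sites = len(site_list)

    if n_sites == 1:
        return CombatModel(
            feature_labels=list(block.feature_labels),
            covariates=tuple(covariates),
            site_list=site_list,
            grand_alpha=np.zeros(p),
            beta=np.zeros((X.shape[1], p)),
            gamma_star=np.zeros((1, p)),
            delta_star=np.ones((1, p)),
            pooled_sd=np.ones(p),
            identity=True,
            eb=eb,
            dx_levels=dx_levels,
        )

    site_idx = np.searchsorted(np.array(site_list), sites)
    B = np.zeros((n, n_sites))
    B[np.arange(n), site_idx] = 1.0
    design = np.column_stack([B, X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfigurationError(
            "collinear design: covariates confounded with site indicators"
        )

    observed = ~np.isnan(Y)
    grand_alpha = np.zeros(p)
    beta = np.zeros((X.shape[1], p))
    pooled_sd = np.zeros(p)
    Z = np.full_like(Y, np.nan)
    n_site_feat = np.zeros((n_sites, p))
    gamma_hat = np.zeros((n_sites, p))
    delta_hat = np.ones((n_sites, p))

    for j in range(p):
        m = observed[:, j]
        nj = int(m.sum())
        Dj = design[m]
        if np.linalg.matrix_rank(Dj) < Dj.shape[1]:
            raise ConfigurationError(
                f"feature {block.feature_labels[j]!r}: singular design on complete cases"
            )
        coef, *_ = np.linalg.lstsq(Dj, Y[m, j], rcond=None)
        site_coef, cov_coef = coef[:n_sites], coef[n_sites:]
        w = np.bincount(site_idx[m], minlength=n_sites) / nj
        grand_alpha[j] = w @ site_coef
        beta[:, j] = cov_coef
        fitted = Dj @ coef
        var_pooled = np.mean((Y[m, j] - fitted) ** 2)
        if var_pooled <= 0:
            raise ConfigurationError(
                f"feature {block.feature_labels[j]!r}: zero residual variance"
            )
        pooled_sd[j] = np.sqrt(var_pooled)
        stand_mean = grand_alpha[j] + design[m, n_sites:] @ cov_coef
        Z[m, j] = (Y[m, j] - stand_mean) / pooled_sd[j]
        for s in range(n_sites):
            ms = m & (site_idx == s)
            ns = int(ms.sum())
            if ns < 2:
                raise ConfigurationError(
                    f"feature {block.feature_labels[j]!r}: fewer than 2 observations "
                    f"at site {site_list[s]!r}"
                )
            n_site_feat[s, j] = ns
            gamma_hat[s, j] = Z[ms, j].mean()
            delta_hat[s, j] = Z[ms, j].var(ddof=1)

    if not eb:
        return CombatModel(
            feature_labels=list(block.feature_labels),
            covariates=tuple(covariates),
            site_list=site_list,
            grand_alpha=grand_alpha,
            beta=beta,
            gamma_star=gamma_hat,
            delta_star=delta_hat,
            pooled_sd=pooled_sd,
            identity=False,
            eb=False,
            dx_levels=dx_levels,
        )

    # moment-matched parametric priors across features, per site
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    a_prior = (2.0 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    total_iter = 0
    for s in range(n_sites):
        g_new, d_new = gamma_hat[s].copy(), delta_hat[s].copy()
        ns = n_site_feat[s]
        ms = site_idx == s
        for it in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = _postmean(gamma_hat[s], gamma_bar[s], ns, d_old, t2[s])
            sum2 = np.nansum((Z[ms] - g_new[None, :]) ** 2, axis=0)
            d_new = _postvar(sum2, ns, a_prior[s], b_prior[s])
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            if change < tol:
                break
        total_iter += it + 1
        gamma_star[s], delta_star[s] = g_new, d_new

    return CombatModel(
        feature_labels=list(block.feature_labels),
        covariates=tuple(covariates),
        site_list=site_list,
        grand_alpha=grand_alpha,
        beta=beta,
        gamma_star=gamma_star,
        delta_star=delta_star,
        pooled_sd=pooled_sd,
        identity=False,
        eb=True,
        n_iter=total_iter,
        dx_levels=dx_levels,
    )


def apply_combat(block: FeatureBlock, model: CombatModel, cohort: CohortTable) -> FeatureBlock:
    """Adjust a block with a fitted model; missingness is untouched.

    ``y_adj = pooled_sd * (z - gamma_star) / sqrt(delta_star) + alpha + X beta``
    with ``z`` the covariate-standardized residual.  Subjects from sites not
    seen at fit time raise :class:`AlignmentError`.
    """
    block = block.reorder(cohort.subject_ids)
    sub = block.select_features(model.feature_labels)
    if model.identity:
        return FeatureBlock(
            sub.subject_ids, sub.feature_labels, sub.values.copy(), sub.block_kind
        )
    sites = cohort.df["site"].astype(str).to_numpy()
    unknown = sorted(set(sites) - set(model.site_list))
    if unknown:
        raise AlignmentError(f"subjects from sites unseen at fit time: {unknown}")
    site_idx = np.searchsorted(np.array(model.site_list), sites)
    X, _, _ = _covariate_matrix(cohort, model.covariates, model.dx_levels)
    stand_mean = model.grand_alpha[None, :] + X @ model.beta
    Z = (sub.values - stand_mean) / model.pooled_sd[None, :]
    adj = (
        model.pooled_sd[None, :]
        * (Z - model.gamma_star[site_idx])
        / np.sqrt(model.delta_star[site_idx])
        + stand_mean
    )
    adj[np.isnan(sub.values)] = np.nan
    return FeatureBlock(sub.subject_ids, sub.feature_labels, adj, sub.block_kind)
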