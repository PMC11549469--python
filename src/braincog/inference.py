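"""Robustness inference for PLS modes.

Two procedures:

* subject-permutation null — rows of the cognition block are shuffled,
  PLS refitted, and the *first* permuted mode's covariance recorded.  The
  first permuted mode extracts the most covariance a null sample can offer
  and is therefore the strictest null reference for every observed mode.
  p-values use the add-one formula (1 + c) / (1 + N), so the smallest
  attainable p at 1000 permutations is 1/1001 (< 0.001).

* bootstrap loading reliability — subjects are resampled with
  replacement, the full fit (re-imputation, re-standardization, PLS) is
  re-run on each resample, and a feature's loading is deemed reliable when
  its 2.5 and 97.5 percentile loadings share a sign.  Resampled modes are
  aligned to the original (best |correlation| among the first modes, sign
  matched) before accumulating, to avoid sign-flip and mode-swap
  artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datatypes import CohortTable, FeatureBlock
from .errors import ConfigurationError
from .pls import PLSModel, fit_pls
from .preprocess import apply_preprocess, fit_preprocess

__all__ = ["ModeRobustness", "BootstrapLoadings", "permutation_test", "bootstrap_loadings"]


@dataclass
class ModeRobustness:
    """Permutation-null summary: per-mode p and z against the first-mode null."""

    null_cov_first_mode: np.ndarray
    observed_cov: np.ndarray
    p_value: np.ndarray
    z_cov: np.ndarray
    n_perm: int
    seed: int | None


@dataclass
class BootstrapLoadings:
    """Percentile loading intervals and same-sign reliability flags."""

    x_loading: np.ndarray
    y_loading: np.ndarray
    x_lo: np.ndarray
    x_hi: np.ndarray
    y_lo: np.ndarray
    y_hi: np.ndarray
    x_significant: np.ndarray
    y_significant: np.ndarray
    n_boot: int
    seed: int | None
    n_redraws: int = 0


def permutation_test(
    Xb: np.ndarray,
    Yc: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    n_modes: int | None = None,
) -> ModeRobustness:
    """Permutation test of mode robustness.

    Shuffles the cognition block's subjects, refits, and compares each
    observed mode's covariance against the null distribution of the first
    permuted mode.  A mode is robust when ``p < 0.05``.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be at least 100")
    model = fit_pls(Xb, Yc, n_modes=n_modes)
    observed = model.mode_cov
    n = Xb.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = linalg.svdvals(Xb.T @ Yc[perm])[0] / (n - 1)
    sd = null.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("degenerate permutation null (zero spread)")
    p = (1.0 + (null[None, :] >= observed[:, None]).sum(axis=1)) / (n_perm + 1.0)
    z = (observed - null.mean()) / sd
    return ModeRobustness(null, observed, p, z, n_perm, seed)


def _align_mode(model: PLSModel, ref_wx: np.ndarray, ref_wy: np.ndarray):
    """Best-matching mode index and sign vs a reference weight pair.

    Similarity is the sum of within-block dot products of the unit weight
    vectors, so the match is invariant to a global sign flip of either
    data block (which flips both reference and candidate together).
    """
    best_k, best_r = 0, 0.0
    for k in range(min(3, model.n_modes)):
        r = float(ref_wx @ model.x_weights[:, k] + ref_wy @ model.y_weights[:, k])
        if abs(r) > abs(best_r):
            best_k, best_r = k, r
    return best_k, (1.0 if best_r >= 0 else -1.0)


def bootstrap_loadings(
    brain: FeatureBlock,
    cognition: FeatureBlock,
    cohort: CohortTable,
    n_boot: int = 1000,
    seed: int | None = None,
    residualize: bool = False,
    n_align_modes: int = 3,
) -> BootstrapLoadings:
    """Bootstrap reliability of first-mode loadings.

    Blocks are the analysis-ready but unstandardized features (after
    orientation / averaging / harmonization); imputation and
    standardization are re-learned inside every resample.  Resamples that
    produce a zero-variance feature are redrawn (up to 10 times each,
    counted in ``n_redraws``).
    """
    ids = cohort.subject_ids
    params = fit_preprocess(brain, cognition, cohort, ids, residualize=residualize)
    Xb = apply_preprocess(brain, cohort, params)
    Yc = apply_preprocess(cognition, cohort, params)
    n_modes = min(n_align_modes, brain.n_features, cognition.n_features)
    model = fit_pls(Xb, Yc, n_modes=n_modes)
    ref_wx, ref_wy = model.x_weights[:, 0], model.y_weights[:, 0]

    n = len(ids)
    rng = np.random.default_rng(seed)
    boot_x = np.empty((n_boot, brain.n_features))
    boot_y = np.empty((n_boot, cognition.n_features))
    n_redraws = 0
    for b in range(n_boot):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            rs_ids = [f"B{i:06d}" for i in range(n)]
            rs_cohort = CohortTable(
                cohort.df.iloc[idx].assign(subject_id=rs_ids).reset_index(drop=True)
            )
            rs_brain = FeatureBlock(
                rs_ids, brain.feature_labels, brain.values[idx], "brain"
            )
            rs_cog = FeatureBlock(
                rs_ids, cognition.feature_labels, cognition.values[idx], "cognition"
            )
            try:
                rs_params = fit_preprocess(
                    rs_brain, rs_cog, rs_cohort, rs_ids, residualize=residualize
                )
                break
            except ConfigurationError:
                if attempt == 10:
                    raise ConfigurationError(
                        "bootstrap resample kept producing zero-variance features"
                    )
                n_redraws += 1
        Xr = apply_preprocess(rs_brain, rs_cohort, rs_params)
        Yr = apply_preprocess(rs_cog, rs_cohort, rs_params)
        rs_model = fit_pls(Xr, Yr, n_modes=n_modes)
        k, sign = _align_mode(rs_model, ref_wx, ref_wy)
        boot_x[b] = sign * rs_model.x_loadings[:, k]
        boot_y[b] = sign * rs_model.y_loadings[:, k]

    x_lo, x_hi = np.percentile(boot_x, [2.5, 97.5], axis=0)
    y_lo, y_hi = np.percentile(boot_y, [2.5, 97.5], axis=0)
    x_sig = ((x_lo > 0) & (x_hi > 0)) | ((x_lo < 0) & (x_hi < 0))
    y_sig = ((y_lo > 0) & (y_hi > 0)) | ((y_lo < 0) & (y_hi < 0))
    return BootstrapLoadings(
        x_loading=model.x_loadings[:, 0],
        y_loading=model.y_loadings[:, 0],
        x_lo=x_lo,
        x_hi=x_hi,
        y_lo=y_lo,
        y_hi=y_hi,
        x_significant=x_sig,
        y_significant=y_sig,
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
    )
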