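"""Canonical two-block partial least squares.

Each mode is the pair of unit weight vectors maximizing the covariance
between the two blocks' latent scores; it is the leading singular pair of
the current deflated cross-covariance matrix.  After extracting a mode,
both blocks are deflated symmetrically (each block regressed on its own
score — the "canonical" variant), so successive score pairs are orthogonal
within each block.

Loadings are Pearson correlations between each original (undeflated,
standardized) measure and its block's latent score.  A deterministic sign
convention flips each mode so the mean brain loading is non-negative
(wider sulci and poorer cognition score positive); ties break toward no
flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import ConfigurationError

__all__ = ["PLSModel", "fit_pls", "project", "loading_correlation"]

_RANK_TOL = 1e-10


@dataclass
class PLSModel:
    """Fitted canonical PLS decomposition.

    Arrays are feature-by-mode (weights, loadings, deflation vectors) or
    subject-by-mode (scores).  ``mode_cov[k]`` is the sample covariance of
    the mode-``k`` score pair; ``sign_flipped[k]`` records the sign
    convention applied post-fit.
    """

    n_modes: int
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    mode_cov: np.ndarray
    sign_flipped: np.ndarray
    x_deflation: np.ndarray
    y_deflation: np.ndarray
    preprocess: object | None = None


def _corr_columns(M: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of M with vector t."""
    Mc = M - M.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (tc**2).sum())
    return (Mc.T @ tc) / denom


def fit_pls(Xb: np.ndarray, Yc: np.ndarray, n_modes: int | None = None) -> PLSModel:
    """Fit canonical PLS on preprocessed (standardized) blocks.

    Parameters
    ----------
    Xb, Yc
        Brain and cognition matrices with equal row counts, columns
        centered (standardization is the caller's preprocessing step).
    n_modes
        Number of modes; defaults to ``min(10, rank of the
        cross-covariance)``.  Requesting more modes than the rank supports
        is an error.
    """
    Xb = np.asarray(Xb, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    if Xb.ndim != 2 or Yc.ndim != 2 or Xb.shape[0] != Yc.shape[0]:
        raise ConfigurationError("blocks must be 2-D with equal row counts")
    if not (np.isfinite(Xb).all() and np.isfinite(Yc).all()):
        raise ConfigurationError("non-finite input; impute before fitting")
    n, p = Xb.shape
    q = Yc.shape[1]
    if n < 3:
        raise ConfigurationError("need at least 3 subjects")

    C0 = Xb.T @ Yc / (n - 1)
    rank = int(np.sum(linalg.svdvals(C0) > _RANK_TOL * max(1.0, linalg.svdvals(C0)[0])))
    if n_modes is None:
        n_modes = min(10, rank)
    if n_modes > min(p, q) or n_modes > rank:
        raise ConfigurationError(
            f"n_modes={n_modes} exceeds the cross-covariance rank ({rank})"
        )

    Xd, Yd = Xb.copy(), Yc.copy()
    wx = np.zeros((p, n_modes))
    wy = np.zeros((q, n_modes))
    tx = np.zeros((n, n_modes))
    ty = np.zeros((n, n_modes))
    px = np.zeros((p, n_modes))
    py = np.zeros((q, n_modes))
    lx = np.zeros((p, n_modes))
    ly = np.zeros((q, n_modes))
    cov = np.zeros(n_modes)
    flipped = np.zeros(n_modes, dtype=bool)

    for k in range(n_modes):
        C = Xd.T @ Yd
        U, s, Vt = linalg.svd(C, full_matrices=False)
        u, v = U[:, 0], Vt[0]
        # deterministic intra-pair orientation before the loading convention
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        t = Xd @ u
        w = Yd @ v
        cov[k] = t @ w / (n - 1)
        p_k = Xd.T @ t / (t @ t)
        q_k = Yd.T @ w / (w @ w)
        Xd = Xd - np.outer(t, p_k)
        Yd = Yd - np.outer(w, q_k)

        load_x = _corr_columns(Xb, t)
        load_y = _corr_columns(Yc, w)
        if load_x.mean() < 0:  # flip so mean brain loading >= 0; ties -> no flip
            u, v, t, w = -u, -v, -t, -w
            p_k, q_k = -p_k, -q_k
            load_x, load_y = -load_x, -load_y
            flipped[k] = True
        wx[:, k], wy[:, k] = u, v
        tx[:, k], ty[:, k] = t, w
        px[:, k], py[:, k] = p_k, q_k
        lx[:, k], ly[:, k] = load_x, load_y

    return PLSModel(
        n_modes=n_modes,
        x_weights=wx,
        y_weights=wy,
        x_scores=tx,
        y_scores=ty,
        x_loadings=lx,
        y_loadings=ly,
        mode_cov=cov,
        sign_flipped=flipped,
        x_deflation=px,
        y_deflation=py,
    )


def project(model: PLSModel, Xb_new: np.ndarray, Yc_new: np.ndarray):
    """Project new (preprocessed) subjects through a fitted model.

    Applies the trained weights with the trained deflation operators
    sequentially, so projecting the training data reproduces the stored
    scores.
    """
    Xd = np.asarray(Xb_new, dtype=float).copy()
    Yd = np.asarray(Yc_new, dtype=float).copy()
    if Xd.shape[1] != model.x_weights.shape[0] or Yd.shape[1] != model.y_weights.shape[0]:
        raise ConfigurationError("new data feature counts do not match the model")
    n = Xd.shape[0]
    xs = np.zeros((n, model.n_modes))
    ys = np.zeros((n, model.n_modes))
    for k in range(model.n_modes):
        t = Xd @ model.x_weights[:, k]
        w = Yd @ model.y_weights[:, k]
        xs[:, k], ys[:, k] = t, w
        Xd = Xd - np.outer(t, model.x_deflation[:, k])
        Yd = Yd - np.outer(w, model.y_deflation[:, k])
    return xs, ys


def loading_correlation(a, b) -> float:
    """Pearson correlation between two loading vectors (length >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ConfigurationError("loading vectors must be equal-length 1-D, length >= 3")
    return float(np.corrcoef(a, b)[0, 1])
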