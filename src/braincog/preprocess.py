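"""Feature preparation: orientation, hemisphere averaging, sparse-feature
exclusion, ICV correction, imputation, residualization and standardization.

Parameters are learned on a declared fitting cohort (typically the healthy
participants) and reused verbatim on held-out subjects (MCI/AD), so that
clinical subjects are projected through a model trained on healthy data.

Pipeline order is fixed: orient -> hemisphere-average -> sparse-drop ->
harmonize (separate module) -> impute -> (optional) residualize ->
standardize.  Imputation replaces missing entries by the fit-cohort mean;
residualization removes per-feature least-squares age + sex predictions;
standardization centers and scales to unit variance (sample sd, ddof=1)
using fit-cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CohortTable, FeatureBlock
from .errors import ConfigurationError, FormatError

__all__ = [
    "BlockParams",
    "PreprocessParams",
    "orient_scores",
    "average_hemispheres",
    "drop_sparse_features",
    "icv_correct",
    "fit_preprocess",
    "apply_preprocess",
]

_HEMI_SUFFIXES = (("_left", 5), ("_right", 6))


def orient_scores(block: FeatureBlock, orientation_map: dict) -> FeatureBlock:
    """Sign cognitive tests so that more positive always means better.

    Tests mapped to ``"negative"`` (error rates, reaction times) are
    negated; tests mapped to ``"positive"`` are unchanged.  Every test must
    have an entry; missingness is preserved (NaN stays NaN under negation).
    """
    missing = [f for f in block.feature_labels if f not in orientation_map]
    if missing:
        raise ConfigurationError(f"tests without orientation entry: {missing[:5]}")
    bad = {f: o for f, o in orientation_map.items() if o not in ("positive", "negative")}
    if bad:
        raise ConfigurationError(f"orientations must be positive/negative, got {bad}")
    signs = np.array(
        [-1.0 if orientation_map[f] == "negative" else 1.0 for f in block.feature_labels]
    )
    return FeatureBlock(
        block.subject_ids, block.feature_labels, block.values * signs, block.block_kind
    )


def _split_hemi(label: str):
    for suffix, n in _HEMI_SUFFIXES:
        if label.endswith(suffix):
            return label[:-n], suffix
    return None, None


def average_hemispheres(block: FeatureBlock) -> FeatureBlock:
    """Average left/right homologous measures into one per-sulcus feature.

    Labels follow ``<base>_left`` / ``<base>_right``.  When both sides
    exist the output feature ``<base>`` is their mean (if one side is
    missing the available side is used; both missing stays missing).
    Unpaired labels are kept unchanged.
    """
    bases: dict[str, dict[str, int]] = {}
    for j, label in enumerate(block.feature_labels):
        base, suffix = _split_hemi(label)
        if base is not None:
            sides = bases.setdefault(base, {})
            sides[suffix] = j

    out_labels: list[str] = []
    cols: list[np.ndarray] = []
    done: set[str] = set()
    for j, label in enumerate(block.feature_labels):
        base, suffix = _split_hemi(label)
        if base is None:
            out_labels.append(label)
            cols.append(block.values[:, j])
            continue
        sides = bases[base]
        if len(sides) == 2:
            if base in done:
                continue
            done.add(base)
            pair = block.values[:, [sides["_left"], sides["_right"]]]
            n_seen = (~np.isnan(pair)).sum(axis=1)
            total = np.nansum(pair, axis=1)
            # one side missing -> the available side; both missing -> missing
            col = np.where(n_seen > 0, total / np.maximum(n_seen, 1), np.nan)
            out_labels.append(base)
            cols.append(col)
        else:  # unpaired hemisphere label kept as-is
            out_labels.append(label)
            cols.append(block.values[:, j])
    if len(set(out_labels)) != len(out_labels):
        dup = sorted({l for l in out_labels if out_labels.count(l) > 1})
        raise FormatError(f"duplicate base labels after hemisphere averaging: {dup}")
    return FeatureBlock(
        block.subject_ids, out_labels, np.column_stack(cols), block.block_kind
    )


def drop_sparse_features(block: FeatureBlock, max_missing_frac: float = 0.5):
    """Drop features missing in strictly more than ``max_missing_frac`` of subjects.

    Returns ``(filtered_block, dropped_labels)``.
    """
    if not 0.0 < max_missing_frac < 1.0:
        raise ConfigurationError("max_missing_frac must be in (0, 1)")
    frac = np.isnan(block.values).mean(axis=0)
    keep = frac <= max_missing_frac
    dropped = [f for f, k in zip(block.feature_labels, keep) if not k]
    kept_labels = [f for f, k in zip(block.feature_labels, keep) if k]
    return block.select_features(kept_labels), dropped


def icv_correct(hv, icv, mean_icv):
    """Intracranial-volume correction of a volume measure (mm^3).

    Divides by the subject's ICV and rescales by the cohort-average ICV:
    ``hv / icv * mean_icv``.  Invariant to rescaling all ICVs by a common
    factor.
    """
    hv = np.asarray(hv, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(icv <= 0) or mean_icv <= 0:
        raise ConfigurationError("ICV values must be positive")
    return hv / icv * mean_icv


@dataclass
class BlockParams:
    """Per-block preprocessing parameters, learned on the fit cohort."""

    kept_features: list[str]
    impute_means: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    residual_coefs: np.ndarray | None = None  # (3, p): intercept, age, sex


@dataclass
class PreprocessParams:
    """Preprocessing parameters for both blocks plus the fitting cohort ids."""

    fit_subject_ids: list[str]
    brain: BlockParams
    cognition: BlockParams
    residualize: bool = False
    orientation_map: dict = field(default_factory=dict)


def _design_age_sex(cohort: CohortTable) -> np.ndarray:
    age = cohort.df["age"].to_numpy(dtype=float)
    sex = cohort.sex_indicator()
    return np.column_stack([np.ones(len(age)), age, sex])


def _fit_block(block: FeatureBlock, cohort: CohortTable, fit_ids, residualize: bool) -> BlockParams:
    fit_block = block.reorder(fit_ids)
    values = fit_block.values
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=0)
    too_few = n_obs < 2
    if too_few.any():
        bad = [f for f, t in zip(block.feature_labels, too_few) if t]
        raise ConfigurationError(
            f"features with fewer than 2 observed values on the fit cohort: {bad[:5]}"
        )

    impute_means = np.nanmean(values, axis=0)
    filled = np.where(observed, values, impute_means)

    residual_coefs = None
    if residualize:
        X = _design_age_sex(cohort.subset(fit_ids))
        residual_coefs, *_ = np.linalg.lstsq(X, filled, rcond=None)
        filled = filled - X @ residual_coefs

    means = filled.mean(axis=0)
    sds = filled.std(axis=0, ddof=1)
    zero_var = sds <= 0
    if zero_var.any():
        bad = [f for f, z in zip(block.feature_labels, zero_var) if z]
        raise ConfigurationError(f"zero-variance features on the fit cohort: {bad[:5]}")
    return BlockParams(
        kept_features=list(block.feature_labels),
        impute_means=impute_means,
        feature_means=means,
        feature_sds=sds,
        residual_coefs=residual_coefs,
    )


def fit_preprocess(
    brain: FeatureBlock,
    cognition: FeatureBlock,
    cohort: CohortTable,
    fit_ids,
    residualize: bool = False,
) -> PreprocessParams:
    """Learn imputation, residualization and scaling parameters.

    All statistics (per-feature imputation means, optional least-squares
    intercept + age + sex coefficients, centering means and sample sds)
    are computed from ``fit_ids`` only, so held-out subjects can later be
    transformed with fit-cohort parameters.
    """
    fit_ids = list(fit_ids)
    if not fit_ids:
        raise ConfigurationError("fit_ids must be non-empty")
    return PreprocessParams(
        fit_subject_ids=fit_ids,
        brain=_fit_block(brain, cohort, fit_ids, residualize),
        cognition=_fit_block(cognition, cohort, fit_ids, residualize),
        residualize=residualize,
    )


def apply_preprocess(
    block: FeatureBlock, cohort: CohortTable, params: PreprocessParams
) -> np.ndarray:
    """Transform a block with stored parameters: impute -> residualize -> scale.

    ``block`` may contain held-out subjects; it must carry at least the
    features kept at fit time.  Returns the standardized numeric matrix in
    the block's subject order.
    """
    bp = params.brain if block.block_kind == "brain" else params.cognition
    sub = block.select_features(bp.kept_features)
    values = sub.values
    filled = np.where(np.isnan(values), bp.impute_means, values)
    if params.residualize:
        if bp.residual_coefs is None:
            raise ConfigurationError("params fitted without residual coefficients")
        X = _design_age_sex(cohort.subset(block.subject_ids))
        filled = filled - X @ bp.residual_coefs
    return (filled - bp.feature_means) / bp.feature_sds
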