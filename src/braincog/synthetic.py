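"""Synthetic cohort generator with planted ground truth.

The generator emulates the statistical structure of multi-site aging
cohorts: a single dominant latent mode shared between a brain-morphometry
block (sulcal widths, mm) and a cognition block (test scores, oriented so
positive = better), driven by age, sex, diagnosis (HC/MCI/AD) and amyloid
status; additive and multiplicative site batch effects; an education effect
on cognition; and missing-completely-at-random entries.  Ground truth
(planted weight vectors, latent scores, batch parameters) is returned so
that downstream mode-recovery, harmonization and inference stages can be
tested without any real data.

The latent score for subject *i* is

    l_i = beta_age * z(age_i) + beta_sex * female_i + beta_mci * MCI_i
          + beta_ad * AD_i + beta_amyloid * Abeta+_i + eps_i,   eps ~ N(0, 1)

brain entries follow the batch-effect generative model the harmonization
stage assumes,

    b_ij = baseline_j + s * sqrt(p) * l_i * w_brain_j + gamma_site(i),j
           + delta_site(i),j * N(0, 1)

and cognition entries (positive = better performance)

    c_ik = baseline_k - s * sqrt(q) * l_i * w_cog_k
           + beta_educ * z(educ_i) + N(0, 1)

with ``s = mode_strength``, unit-norm planted weight vectors and ``p`` /
``q`` the feature counts; the sqrt factor makes ``mode_strength`` the
average per-feature signal-to-noise against the unit feature noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CohortTable, FeatureBlock
from .errors import ConfigurationError

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_cohort"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a mid-life single-site cohort: ages uniform on 49-73
    years, 74% female, 61 brain features (64 sulci minus 3 sparse ones),
    15 cognitive tests, 3.5% missing entries, and a latent mode driven
    mostly by age with HC < MCI < AD shifts along it.  Effect sizes are in
    standardized units of the latent score.
    """

    n_subjects: int = 200
    n_brain: int = 61
    n_cog: int = 15
    age_range: tuple[float, float] = (49.0, 73.0)
    frac_female: float = 0.74
    n_sites: int = 1
    site_shift_sd: float = 0.3
    site_scale_sd: float = 0.15
    frac_mci: float = 0.10
    frac_ad: float = 0.05
    mode_strength: float = 1.0
    beta_age: float = 0.5
    beta_sex: float = 0.2
    beta_dx_mci: float = 0.5
    beta_dx_ad: float = 1.0
    beta_amyloid: float = 0.3
    beta_educ: float = 0.2
    missing_rate: float = 0.035
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_brain", "n_cog", "n_sites"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("frac_female", "frac_mci", "frac_ad", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if self.frac_mci + self.frac_ad > 1.0:
            raise ConfigurationError("frac_mci + frac_ad must not exceed 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range low must be < high, got {self.age_range!r}")
        if lo <= 0:
            raise ConfigurationError("ages must be positive")
        for name in ("site_shift_sd", "site_scale_sd", "mode_strength"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_subjects < 4 * self.n_sites:
            raise ConfigurationError(
                "need at least 4 subjects per site (sites with <=3 subjects are excluded "
                "downstream); increase n_subjects or decrease n_sites"
            )


@dataclass
class SyntheticTruth:
    """Planted parameters enabling recovery tests.

    ``w_brain_true`` / ``w_cog_true`` are unit vectors over features;
    ``latent_scores`` the per-subject latent values; ``site_shifts`` /
    ``site_scales`` the per-site per-brain-feature batch parameters.
    """

    w_brain_true: np.ndarray
    w_cog_true: np.ndarray
    latent_scores: np.ndarray
    site_shifts: np.ndarray
    site_scales: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w_brain_true", "w_cog_true"):
            w = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(w), 1.0):
                raise ConfigurationError(f"{name} must have unit norm")
            setattr(self, name, w)
        self.latent_scores = np.asarray(self.latent_scores, dtype=float)
        if not np.isfinite(self.latent_scores).all():
            raise ConfigurationError("latent scores must be finite")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_cohort(config: SimulationConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    (CohortTable, FeatureBlock, FeatureBlock, SyntheticTruth)
        Metadata table, brain block, cognition block and the planted truth.
        Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    female = rng.random(n) < config.frac_female
    sex = np.where(female, "female", "male")

    dx = rng.choice(
        ["HC", "MCI", "AD"],
        size=n,
        p=[1.0 - config.frac_mci - config.frac_ad, config.frac_mci, config.frac_ad],
    )
    is_mci = dx == "MCI"
    is_ad = dx == "AD"

    # round-robin site assignment guarantees near-equal counts (> 3 each)
    site_idx = rng.permutation(np.resize(np.arange(config.n_sites), n))
    site = np.array([f"site{k + 1}" for k in site_idx])

    # amyloid burden drifts up with age and disease stage
    centiloid = (
        rng.normal(8.0, 18.0, size=n)
        + 0.6 * (age - age.mean())
        + 15.0 * is_mci
        + 30.0 * is_ad
    )
    amyloid_pos = centiloid > 20.0
    amyloid_status = np.where(amyloid_pos, "positive", "negative")

    apoe4 = np.where(rng.random(n) < 0.53, "carrier", "noncarrier")
    education = np.clip(np.round(rng.normal(13.0, 3.0, size=n)), 6, 20)
    prs = rng.standard_normal(n)

    latent = (
        config.beta_age * _zscore(age)
        + config.beta_sex * female.astype(float)
        + config.beta_dx_mci * is_mci.astype(float)
        + config.beta_dx_ad * is_ad.astype(float)
        + config.beta_amyloid * amyloid_pos.astype(float)
        + rng.standard_normal(n)
    )

    # predominantly positive weights (mean 0.5, sd 1 before normalization):
    # the latent process widens most sulci and lowers most test scores, so
    # the mean-loading sign convention aligns the fitted mode with the
    # latent and clinical groups order along it, while the weight spread
    # stays wide enough for informative recovery checks
    w_brain = rng.standard_normal(config.n_brain) + 0.5
    w_brain /= np.linalg.norm(w_brain)
    w_cog = rng.standard_normal(config.n_cog) + 0.5
    w_cog /= np.linalg.norm(w_cog)

    site_shifts = rng.normal(0.0, config.site_shift_sd, size=(config.n_sites, config.n_brain))
    site_scales = np.exp(
        rng.normal(0.0, config.site_scale_sd, size=(config.n_sites, config.n_brain))
    )
    if config.n_sites == 1:
        site_shifts[:] = 0.0
        site_scales[:] = 1.0

    # the sqrt(n_features) factor makes mode_strength the average
    # per-feature signal-to-noise against the unit feature noise, since
    # the planted weight vector has unit norm
    brain_baseline = rng.uniform(1.0, 5.0, size=config.n_brain)  # sulcal widths, mm
    brain = (
        brain_baseline[None, :]
        + config.mode_strength
        * np.sqrt(config.n_brain)
        * np.outer(latent, w_brain)
        + site_shifts[site_idx]
        + site_scales[site_idx] * rng.standard_normal((n, config.n_brain))
    )

    cog_baseline = rng.normal(0.0, 1.0, size=config.n_cog)
    cognition = (
        cog_baseline[None, :]
        - config.mode_strength * np.sqrt(config.n_cog) * np.outer(latent, w_cog)
        + config.beta_educ * _zscore(education)[:, None]
        + rng.standard_normal((n, config.n_cog))
    )

    brain[rng.random(brain.shape) < config.missing_rate] = np.nan
    cognition[rng.random(cognition.shape) < config.missing_rate] = np.nan

    ids = [f"S{i:04d}" for i in range(n)]
    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": ids,
                "cohort": "SIM",
                "site": site,
                "age": age,
                "sex": sex,
                "diagnosis": dx,
                "centiloid": centiloid,
                "amyloid_status": amyloid_status,
                "apoe4": apoe4,
                "education": education,
                "twin_pair": [""] * n,
                "prs": prs,
            }
        )
    )
    brain_block = FeatureBlock(
        ids, [f"sulcus_{j:02d}" for j in range(config.n_brain)], brain, "brain"
    )
    cog_block = FeatureBlock(
        ids, [f"test_{k:02d}" for k in range(config.n_cog)], cognition, "cognition"
    )
    truth = SyntheticTruth(w_brain, w_cog, latent, site_shifts, site_scales)
    return cohort, brain_block, cog_block, truth
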