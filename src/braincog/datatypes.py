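"""Core in-memory containers: the subject metadata table and feature blocks.

A :class:`CohortTable` wraps a pandas DataFrame of per-subject metadata
(demographics, site, diagnosis, biomarker/genetic status).  A
:class:`FeatureBlock` holds a subject x feature numeric matrix for one data
domain (brain morphometry or cognitive test scores) with NaN as the explicit
missing marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

DIAGNOSES = ("HC", "MCI", "AD")
SEXES = ("male", "female")

#: Columns a cohort table must always carry.
REQUIRED_COHORT_COLUMNS = ("subject_id", "cohort", "site", "age", "sex", "diagnosis")

#: Optional columns, written in this order when present.
OPTIONAL_COHORT_COLUMNS = (
    "centiloid",
    "amyloid_status",
    "apoe4",
    "education",
    "twin_pair",
    "prs",
)


@dataclass
class CohortTable:
    """Per-subject metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per subject.  Must contain ``subject_id`` (unique strings),
        ``cohort``, ``site``, ``age`` (> 0 years), ``sex`` (male/female) and
        ``diagnosis`` (HC/MCI/AD).  Optional columns: ``centiloid`` (CL),
        ``amyloid_status`` (positive/negative), ``apoe4``
        (carrier/noncarrier), ``education`` (years), ``twin_pair`` (label
        shared by co-twins), ``prs`` (polygenic risk score).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COHORT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"cohort table missing required column {col!r}")
        ids = df["subject_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise FormatError(f"duplicate subject_id {dup!r} in cohort table")
        if (pd.to_numeric(df["age"], errors="coerce") <= 0).any() or df["age"].isna().any():
            raise FormatError("cohort table contains non-positive or missing age")
        bad_dx = set(df["diagnosis"].dropna().unique()) - set(DIAGNOSES)
        if bad_dx:
            raise FormatError(f"unknown diagnosis labels {sorted(bad_dx)}; expected {DIAGNOSES}")
        bad_sex = set(df["sex"].dropna().unique()) - set(SEXES)
        if bad_sex:
            raise FormatError(f"unknown sex labels {sorted(bad_sex)}; expected {SEXES}")
        self.df = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].astype(str).tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def subset(self, subject_ids) -> "CohortTable":
        """Rows for ``subject_ids``, in the given order."""
        idx = self.df.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise AlignmentError(f"subjects absent from cohort table: {missing[:5]}")
        return CohortTable(idx.loc[list(subject_ids)].reset_index())

    def sex_indicator(self) -> np.ndarray:
        """Sex as a design-matrix column: 0 = male, 1 = female."""
        return (self.df["sex"].to_numpy() == "female").astype(float)


@dataclass
class FeatureBlock:
    """A subject x feature matrix for one data domain.

    ``values`` is a float array with ``NaN`` marking missing entries; rows
    align with ``subject_ids`` and columns with ``feature_labels``.
    ``block_kind`` is ``"brain"`` or ``"cognition"``.
    """

    subject_ids: list[str]
    feature_labels: list[str]
    values: np.ndarray
    block_kind: str = "brain"

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_labels = [str(f) for f in self.feature_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("feature block values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.subject_ids):
            raise FormatError(
                f"row count {n} does not match subject count {len(self.subject_ids)}"
            )
        if p != len(self.feature_labels):
            raise FormatError(
                f"column count {p} does not match label count {len(self.feature_labels)}"
            )
        if len(set(self.feature_labels)) != p:
            raise FormatError("feature labels are not unique")
        if len(set(self.subject_ids)) != n:
            raise FormatError("subject ids are not unique in feature block")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            i, j = np.argwhere(~finite_or_nan)[0]
            raise FormatError(
                f"non-finite value at subject {self.subject_ids[i]!r}, "
                f"feature {self.feature_labels[j]!r}"
            )
        if self.block_kind not in ("brain", "cognition"):
            raise FormatError(f"unknown block_kind {self.block_kind!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.feature_labels)
        out.insert(0, "subject_id", self.subject_ids)
        return out

    def reorder(self, subject_ids) -> "FeatureBlock":
        """Rows reordered to ``subject_ids``; error on any id mismatch."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise AlignmentError(
                f"subjects absent from {self.block_kind} block: {missing[:5]}"
            )
        idx = [pos[s] for s in subject_ids]
        return FeatureBlock(
            list(subject_ids), list(self.feature_labels), self.values[idx], self.block_kind
        )

    def select_features(self, labels) -> "FeatureBlock":
        pos = {f: j for j, f in enumerate(self.feature_labels)}
        missing = [f for f in labels if f not in pos]
        if missing:
            raise FormatError(f"features absent from block: {missing[:5]}")
        idx = [pos[f] for f in labels]
        return FeatureBlock(
            list(self.subject_ids), list(labels), self.values[:, idx], self.block_kind
        )


def align(cohort: CohortTable, *blocks: FeatureBlock):
    """Align feature blocks to the cohort table's subject order.

    Every block must contain exactly the cohort's subjects; a subject present
    in a block but absent from the cohort table (or vice versa) raises
    :class:`AlignmentError`.
    """
    ids = cohort.subject_ids
    id_set = set(ids)
    out = []
    for block in blocks:
        extra = [s for s in block.subject_ids if s not in id_set]
        if extra:
            raise AlignmentError(
                f"{block.block_kind} block contains subjects not in cohort table: {extra[:5]}"
            )
        out.append(block.reorder(ids))
    return tuple(out) if len(out) != 1 else out[0]
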