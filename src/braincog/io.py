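"""CSV readers/writers for cohort tables and feature blocks.

All tables are plain RFC-4180 CSV with a header row and a leading
``subject_id`` column.  Missing feature values are written as empty cells;
on read both the empty string and ``NA`` are accepted as missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CohortTable,
    FeatureBlock,
    OPTIONAL_COHORT_COLUMNS,
    REQUIRED_COHORT_COLUMNS,
)
from .errors import FormatError

MISSING_TOKENS = ("", "NA")


def read_cohort(path) -> CohortTable:
    """Read a cohort metadata table from CSV."""
    df = pd.read_csv(
        path, dtype={"subject_id": str}, keep_default_na=False, na_values=MISSING_TOKENS
    )
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in ("age", "centiloid", "education", "prs"):
        if col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna() & (df[col].astype(str) != "")
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                    f"{col!r}, row {row + 2}"
                )
            df[col] = converted
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    cols = list(REQUIRED_COHORT_COLUMNS) + [
        c for c in OPTIONAL_COHORT_COLUMNS if c in cohort.df.columns
    ]
    cohort.df[cols].to_csv(path, index=False)


def read_block(path, block_kind: str) -> FeatureBlock:
    """Read a subject x feature CSV into a :class:`FeatureBlock`.

    The first column must be ``subject_id``; every other column is a
    feature.  Empty cells and ``NA`` parse as missing; any other
    non-numeric cell raises :class:`FormatError` naming the row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns.empty or df.columns[0] != "subject_id":
        raise FormatError(f"{path}: first column must be 'subject_id'")
    ids = df["subject_id"].tolist()
    labels = [c for c in df.columns if c != "subject_id"]
    values = np.empty((len(ids), len(labels)), dtype=float)
    for j, col in enumerate(labels):
        raw = df[col].str.strip()
        is_missing = raw.isin(MISSING_TOKENS)
        converted = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = converted.isna() & ~is_missing
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, "
                f"row {row + 2}"
            )
        values[:, j] = converted.to_numpy()
    return FeatureBlock(ids, labels, values, block_kind)


def write_block(block: FeatureBlock, path) -> None:
    """Write a feature block to CSV (missing entries as empty cells)."""
    block.to_frame().to_csv(path, index=False, na_rep="")


def write_truth(truth, brain_labels, cog_labels, subject_ids, prefix) -> None:
    """Write the synthetic ground truth as CSV sidecars next to ``prefix``."""
    prefix = Path(prefix)
    pd.DataFrame({"feature": brain_labels, "w_brain_true": truth.w_brain_true}).to_csv(
        prefix.with_name(prefix.name + "_w_brain.csv"), index=False
    )
    pd.DataFrame({"feature": cog_labels, "w_cog_true": truth.w_cog_true}).to_csv(
        prefix.with_name(prefix.name + "_w_cog.csv"), index=False
    )
    pd.DataFrame({"subject_id": subject_ids, "latent": truth.latent_scores}).to_csv(
        prefix.with_name(prefix.name + "_latent.csv"), index=False
    )
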