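"""Tabular containers and I/O conventions shared across the package.

Two kinds of subject-level tables circulate through the pipeline:

* **feature tables** — subjects x regional-imaging-feature matrices whose
  columns carry a three-level annotation ``(modality, region, side)``,
  implemented as a :class:`pandas.MultiIndex`.  Modalities are the four
  regional measures (``fALFF``, ``ReHo``, ``GM_atrophy``, ``GM_density``);
  sides are ``L``/``R``/``mid`` before treated-side mirroring and
  ``TS``/``US``/``mid`` after.
* **clinical tables** — subjects x motor-score matrices with one column per
  MDS-UPDRS-derived score, one table per visit.

Both are plain :class:`pandas.DataFrame` objects; the helpers here construct,
validate and round-trip them as CSV so every stage of the pipeline exchanges
the same on-disk format.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: the four regional imaging measures, in canonical column order
MODALITIES = ("fALFF", "ReHo", "GM_atrophy", "GM_density")

#: the five clinical motor scores, in canonical column order
SCORE_NAMES = (
    "updrs3_total",
    "updrs3_treated_side",
    "rigidity",
    "akinesia",
    "tremor",
)

#: column annotation level names for feature tables
FEATURE_LEVELS = ("modality", "region", "side")

#: lateralized side labels before and after treated-side mirroring
RAW_SIDES = ("L", "R")
FLIPPED_SIDES = ("TS", "US")
MIDLINE = "mid"


def make_feature_table(
    values: np.ndarray,
    columns: Iterable[tuple[str, str, str]],
    subjects: Sequence | None = None,
) -> pd.DataFrame:
    """Assemble a feature table from a matrix and (modality, region, side) tuples."""
    cols = pd.MultiIndex.from_tuples(list(columns), names=FEATURE_LEVELS)
    values = np.asarray(values, dtype=float)
    if subjects is None:
        subjects = pd.RangeIndex(values.shape[0], name="subject")
    df = pd.DataFrame(values, index=pd.Index(subjects, name="subject"), columns=cols)
    validate_feature_table(df)
    return df


def validate_feature_table(table: pd.DataFrame) -> None:
    """Check the feature-table contract: annotated, unique columns."""
    if not isinstance(table.columns, pd.MultiIndex) or table.columns.nlevels != 3:
        raise ValueError(
            "feature table needs a 3-level column MultiIndex (modality, region, side)"
        )
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dupes[:5]}")
    unknown = set(table.columns.get_level_values("modality")) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")


def make_clinical_table(
    values: np.ndarray,
    subjects: Sequence | None = None,
    scores: Sequence[str] = SCORE_NAMES,
) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    if subjects is None:
        subjects = pd.RangeIndex(values.shape[0], name="subject")
    return pd.DataFrame(
        values, index=pd.Index(subjects, name="subject"), columns=list(scores)
    )


def check_aligned(a: pd.DataFrame, b: pd.DataFrame, what: str = "tables") -> None:
    """Require identical subject index and identical columns on two tables."""
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index).tolist()
        only_b = b.index.difference(a.index).tolist()
        raise ValueError(
            f"{what} have mismatched subjects (only in first: {only_a[:5]}, "
            f"only in second: {only_b[:5]})"
        )
    if not a.columns.equals(b.columns):
        only_a = a.columns.difference(b.columns).tolist()
        only_b = b.columns.difference(a.columns).tolist()
        raise ValueError(
            f"{what} have mismatched columns (only in first: {only_a[:5]}, "
            f"only in second: {only_b[:5]})"
        )


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write with a three-row column-annotation header (modality, region, side)."""
    validate_feature_table(table)
    table.to_csv(path)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns.names = FEATURE_LEVELS
    df.index.name = "subject"
    validate_feature_table(df)
    return df


def write_clinical_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def read_clinical_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = "subject"
    return df
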