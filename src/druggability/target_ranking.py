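"""Composite target ranking by min–max fusion of per-method scores.

Each target carries its best per-method raw score (pocket DLID, SiteMap
DScore, SPIDER possibility). Targets missing any method are dropped,
each column is min–max normalized to [0, 1], the three normalized scores
are summed into a composite, and targets are ranked by composite
(descending, ties alphabetical). Targets can be excluded before
selection for stated biological reasons (e.g. early complement-pathway
members whose inhibition would be broadly immunosuppressive).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingScoreError

__all__ = [
    "best_score_per_target",
    "drop_incomplete",
    "minmax_normalize",
    "normalize_scores",
    "composite",
    "rank_and_select",
]

RAW_COLUMNS = ("dlid_raw", "spider_raw", "dscore_raw")
NORM_COLUMNS = ("dlid_norm", "spider_norm", "sitemap_norm")


def best_score_per_target(
    pocket_scores: pd.DataFrame,
    target_col: str = "target",
    score_cols: Sequence[str] = ("dlid", "dscore"),
) -> pd.DataFrame:
    """Per target, the maximum of each score column over its pockets.

    Targets with no scored pockets for a method get NaN. The input has one
    row per pocket; the output one row per target, indexed by target id.
    """
    if pocket_scores.empty:
        return pd.DataFrame(columns=list(score_cols)).rename_axis(target_col)
    return pocket_scores.groupby(target_col)[list(score_cols)].max()


def drop_incomplete(rows: pd.DataFrame, columns: Sequence[str] = RAW_COLUMNS) -> pd.DataFrame:
    """Keep only targets with all raw method scores present."""
    out = rows.dropna(subset=[c for c in columns if c in rows.columns])
    if out.empty and not rows.empty:
        warnings.warn("every row was missing at least one method score", stacklevel=2)
    return out


def minmax_normalize(column: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """(x - min) / (max - min); requires >= 2 values and max > min."""
    values = np.asarray(column, dtype=float)
    if values.size < 2:
        raise DegenerateInputError("min-max normalization needs at least 2 values")
    lo, hi = np.nanmin(values), np.nanmax(values)
    if not hi > lo:
        raise DegenerateInputError("degenerate column: max equals min")
    result = (values - lo) / (hi - lo)
    if isinstance(column, pd.Series):
        return pd.Series(result, index=column.index, name=column.name)
    return result


def normalize_scores(
    rows: pd.DataFrame,
    raw_columns: Sequence[str] = RAW_COLUMNS,
    norm_columns: Sequence[str] = NORM_COLUMNS,
) -> pd.DataFrame:
    """Min–max normalize each raw column and append the composite sum."""
    out = rows.copy()
    for raw, norm in zip(raw_columns, norm_columns):
        out[norm] = minmax_normalize(out[raw])
    out["composite"] = composite(out, norm_columns)
    return out


def composite(rows: pd.DataFrame, norm_columns: Sequence[str] = NORM_COLUMNS) -> pd.Series:
    """Sum of the normalized method scores per target."""
    missing = [c for c in norm_columns if c not in rows.columns]
    if missing:
        raise MissingScoreError(f"missing normalized columns: {missing}")
    block = rows[list(norm_columns)]
    if block.isna().any().any():
        raise MissingScoreError("composite undefined where a normalized score is NaN")
    return block.sum(axis=1)


def rank_and_select(
    rows: pd.DataFrame,
    excluded: Iterable[str] | Mapping[str, str] = (),
    k: int | None = None,
    target_col: str | None = None,
) -> pd.DataFrame:
    """Rank by composite (descending, ties alphabetical) and take the top k.

    ``excluded`` may be a set of target ids or a mapping id -> reason
    (e.g. early classical-complement members excluded on safety grounds);
    excluded targets are removed before selection.
    """
    df = rows.copy()
    if target_col is None:
        target_col = "target"
        if target_col not in df.columns:  # targets live in the index
            df = df.rename_axis(target_col).reset_index()
    if "composite" not in df.columns:
        raise MissingScoreError("rows must carry a 'composite' column")
    excl = set(excluded)
    df = df[~df[target_col].isin(excl)]
    df = df.sort_values(["composite", target_col], ascending=[False, True], kind="mergesort")
    if k is not None:
        if k > len(df):
            raise DegenerateInputError(f"k={k} exceeds {len(df)} non-excluded targets")
        df = df.head(k)
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
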