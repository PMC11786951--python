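"""Post-processing of docking score tables.

Docking produces one binding score (kcal/mol, more negative = stronger)
per (target, molecule). This module applies the likely-binder threshold
(-20 kcal/mol, inclusive), counts hits, reports per-target top-N and best
hits, and finds molecules shared across targets' selected sets — the
cross-target overlap used to spot repurposing candidates hitting more
than one target.

Molecule identifiers in published tables are typographically inconsistent
(``C_15_H_14_N_2_O_2_`` vs ``C15H14N2O2``); ids are canonicalized by
stripping whitespace/underscores and case-folding before any comparison,
while a representative original spelling is kept for display.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "canonical_molecule_id",
    "load_docking_table",
    "filter_hits",
    "best_hit",
    "top_n",
    "cross_target_overlap",
    "OverlapReport",
    "BINDING_THRESHOLD",
]

BINDING_THRESHOLD = -20.0  # kcal/mol; scores at or below are likely binders

_COLUMN_ALIASES = {
    "target": "target", "target_id": "target", "protein": "target",
    "molecule": "molecule", "molecule_id": "molecule", "name": "molecule",
    "drug": "molecule",
    "score": "score", "binding_score": "score", "binding score": "score",
}


def canonical_molecule_id(molecule_id: str) -> str:
    """Strip whitespace and underscores and casefold, for robust matching."""
    return "".join(ch for ch in str(molecule_id) if not ch.isspace() and ch != "_").casefold()


def load_docking_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV docking table into columns target, molecule, score.

    Duplicate (target, molecule) pairs are collapsed to the best (most
    negative) score with a warning. Unparseable scores raise a ValueError
    that names the offending line.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    required = {"target", "molecule", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    scores = pd.to_numeric(df["score"].str.replace("−", "-"), errors="coerce")
    bad = scores.isna() & df["score"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}, line {line}: unparseable score {df.loc[bad.idxmax(), 'score']!r}")
    out = pd.DataFrame({
        "target": df["target"].str.strip(),
        "molecule": df["molecule"].str.strip(),
        "score": scores.astype(float),
    })
    out["molecule_key"] = out["molecule"].map(canonical_molecule_id)
    dup = out.duplicated(subset=["target", "molecule_key"], keep=False)
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate (target, molecule) rows collapsed "
            "to the best score",
            stacklevel=2,
        )
        out = (
            out.sort_values("score", kind="mergesort")
            .drop_duplicates(subset=["target", "molecule_key"], keep="first")
        )
    return out.reset_index(drop=True)


def _ensure_key(records: pd.DataFrame) -> pd.DataFrame:
    if "molecule_key" not in records.columns:
        records = records.assign(molecule_key=records["molecule"].map(canonical_molecule_id))
    return records


def filter_hits(records: pd.DataFrame, threshold: float = BINDING_THRESHOLD) -> pd.DataFrame:
    """Records with binding score <= threshold (order preserved)."""
    return records[records["score"] <= threshold]


def best_hit(records: pd.DataFrame, target: str) -> tuple[str, float]:
    """(molecule, score) of the most negative score for a target.

    Ties are broken alphabetically by canonical molecule id.
    """
    records = _ensure_key(records)
    sub = records[records["target"] == target]
    if sub.empty:
        raise KeyError(f"no docking records for target {target!r}")
    sub = sub.sort_values(["score", "molecule_key"], kind="mergesort")
    row = sub.iloc[0]
    return str(row["molecule"]), float(row["score"])


def top_n(records: pd.DataFrame, target: str, n: int = 10) -> pd.DataFrame:
    """The n most negative scores for a target, ascending by score."""
    records = _ensure_key(records)
    sub = records[records["target"] == target]
    return sub.sort_values(["score", "molecule_key"], kind="mergesort").head(n)


@dataclasses.dataclass
class OverlapReport:
    """Cross-target membership of molecules in each target's selected set."""

    molecule_targets: dict[str, set[str]]  # canonical molecule id -> targets
    display_names: dict[str, str]  # canonical id -> representative spelling
    counts_per_target: dict[str, int]

    @property
    def shared(self) -> list[str]:
        """Canonical ids of molecules selected for >= 2 targets (sorted)."""
        return sorted(m for m, ts in self.molecule_targets.items() if len(ts) >= 2)

    @property
    def shared_display(self) -> list[str]:
        return [self.display_names[m] for m in self.shared]


def cross_target_overlap(
    tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
    mode: str = "top_n",
    n: int = 10,
    threshold: float = BINDING_THRESHOLD,
) -> OverlapReport:
    """Group molecules by the targets whose selected set contains them.

    ``tables`` is either one combined records frame or a mapping
    target -> records. ``mode="top_n"`` selects each target's n best
    scores; ``mode="all_hits"`` selects everything at or below the
    threshold.
    """
    if isinstance(tables, pd.DataFrame):
        combined = _ensure_key(tables)
        per_target = {t: g for t, g in combined.groupby("target")}
    else:
        per_target = {t: _ensure_key(df) for t, df in tables.items()}
    if len(per_target) < 2:
        raise DegenerateInputError("overlap analysis needs at least 2 targets")
    molecule_targets: dict[str, set[str]] = {}
    display: dict[str, str] = {}
    counts: dict[str, int] = {}
    for target, df in per_target.items():
        if mode == "top_n":
            sel = top_n(df, target, n)
        elif mode == "all_hits":
            sel = filter_hits(df, threshold)
        else:
            raise ValueError(f"mode must be 'top_n' or 'all_hits', got {mode!r}")
        counts[target] = len(sel)
        for _, row in sel.iterrows():
            key = row["molecule_key"]
            molecule_targets.setdefault(key, set()).add(target)
            display.setdefault(key, str(row["molecule"]))
    return OverlapReport(molecule_targets, display, counts)
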