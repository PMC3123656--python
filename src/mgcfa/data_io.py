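"""Respondent-level item tables, reverse coding, and group summary statistics.

Estimation consumes per-group summary statistics (mean vector, covariance
matrix, sample size), not raw rows.  Summaries are computed under
pairwise-available-case deletion: each mean uses every observed value of its
item, each covariance entry uses every row where both items are observed,
with an (n_pair - 1) denominator.  With the sub-1% missingness typical of
survey batteries this is indistinguishable from complete-case analysis while
discarding nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_spec import ItemBattery

__all__ = [
    "ItemDataTable",
    "GroupSummary",
    "reverse_code",
    "summarize",
    "summarize_all",
    "load_item_csv",
    "write_item_csv",
    "write_summary",
    "read_summary",
]

GROUP_COLUMN = "group"


@dataclass
class ItemDataTable:
    """Respondent x item responses with a group label per row.

    ``data`` holds one column per battery item (float, NaN = missing) plus a
    leading group column.
    """

    battery: ItemBattery
    data: pd.DataFrame
    #: continuous tables (e.g. simulated latent-response data) skip the
    #: Likert range check
    continuous: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in (GROUP_COLUMN, *self.battery.item_names)
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"table is missing columns: {missing}")
        if self.continuous:
            return
        vals = self.data[list(self.battery.item_names)]
        lo, hi = self.battery.scale_min, self.battery.scale_max
        bad = (vals < lo) | (vals > hi)
        if bad.any().any():
            rows, cols = np.where(bad.to_numpy())
            r, c = rows[0], cols[0]
            raise ValueError(
                f"response out of scale bounds [{lo}, {hi}] at row "
                f"{self.data.index[r]}, item {self.battery.item_names[c]!r}"
            )

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data[GROUP_COLUMN]))

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GroupSummary:
    """Sufficient statistics of one group: covariance S, means xbar, size n."""

    item_names: tuple[str, ...]
    S: np.ndarray
    xbar: np.ndarray
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.xbar = np.asarray(self.xbar, dtype=float)
        p = len(self.item_names)
        if self.S.shape != (p, p):
            raise ValueError(f"S must be {p}x{p}, got {self.S.shape}")
        if self.xbar.shape != (p,):
            raise ValueError(f"xbar must have length {p}")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if np.any(np.diag(self.S) < 0):
            raise ValueError("S has negative diagonal entries")

    @property
    def p(self) -> int:
        return len(self.item_names)


def reverse_code(table: ItemDataTable, items: set[str] | None = None) -> ItemDataTable:
    """Map the listed items through x -> (scale_min + scale_max - x).

    Defaults to the battery's declared reverse-coded items.  Missing entries
    stay missing; applying the operation twice restores the original table.
    """
    if items is None:
        items = set(table.battery.reverse_coded)
    unknown = set(items) - set(table.battery.item_names)
    if unknown:
        raise ValueError(f"unknown items to reverse-code: {sorted(unknown)}")
    out = table.data.copy()
    flip = table.battery.scale_min + table.battery.scale_max
    for item in items:
        out[item] = flip - out[item]
    return ItemDataTable(battery=table.battery, data=out,
                         continuous=table.continuous)


def summarize(table: ItemDataTable, group: str) -> GroupSummary:
    """Pairwise-available-case summary statistics for one group.

    Means use all observed values per item; covariance entry (i, j) uses the
    rows where both items are observed with denominator (n_ij - 1).  The
    sample size carried into the fit function is the group's row count.
    """
    sub = table.data.loc[table.data[GROUP_COLUMN] == group, list(table.battery.item_names)]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} is empty or absent")
    counts = sub.notna().sum()
    dead = counts[counts < 2]
    if len(dead):
        raise ValueError(
            f"items with <2 observed values in group {group!r}: {list(dead.index)}"
        )
    S = sub.cov(min_periods=2).to_numpy()          # pandas: pairwise, n_ij - 1
    xbar = sub.mean().to_numpy()
    return GroupSummary(
        item_names=tuple(table.battery.item_names),
        S=S, xbar=xbar, n=len(sub), label=str(group),
    )


def summarize_all(table: ItemDataTable) -> list[GroupSummary]:
    return [summarize(table, g) for g in table.groups]


def load_item_csv(path: str | Path, battery: ItemBattery) -> ItemDataTable:
    """Read a ``group,<item...>`` CSV into a validated ItemDataTable.

    Missing responses may be empty cells or NA tokens; any non-missing entry
    must be an integer within the battery's scale bounds.
    """
    df = pd.read_csv(path, na_values=["NA", "na", ""])
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in (GROUP_COLUMN, *battery.item_names) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    items = list(battery.item_names)
    vals = df[items].apply(pd.to_numeric, errors="coerce")
    # entries that were present but not numeric
    newly_nan = vals.isna() & df[items].notna()
    if newly_nan.any().any():
        rows, cols = np.where(newly_nan.to_numpy())
        raise ValueError(
            f"{path}: non-numeric entry at row {rows[0]}, item {items[cols[0]]!r}"
        )
    nonint = vals.notna() & (vals != vals.round())
    if nonint.any().any():
        rows, cols = np.where(nonint.to_numpy())
        raise ValueError(
            f"{path}: non-integer entry at row {rows[0]}, item {items[cols[0]]!r}"
        )
    out = pd.DataFrame({GROUP_COLUMN: df[GROUP_COLUMN].astype(str)})
    for c in items:
        out[c] = vals[c]
    lo, hi = battery.scale_min, battery.scale_max
    bad = (vals < lo) | (vals > hi)
    if bad.any().any():
        rows, cols = np.where(bad.to_numpy())
        raise ValueError(
            f"{path}: value out of range [{lo}, {hi}] at row {rows[0]}, "
            f"item {items[cols[0]]!r}"
        )
    return ItemDataTable(battery=battery, data=out)


def write_item_csv(table: ItemDataTable, path: str | Path) -> None:
    df = table.data.copy()
    # keep integers readable where nothing is missing
    df.to_csv(path, index=False, na_rep="NA")


def write_summary(summary: GroupSummary, path: str | Path) -> None:
    """Serialize a GroupSummary to JSON (covariance row-major)."""
    payload = {
        "label": summary.label,
        "item_names": list(summary.item_names),
        "n": int(summary.n),
        "means": summary.xbar.tolist(),
        "covariance": summary.S.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_summary(path: str | Path) -> GroupSummary:
    payload = json.loads(Path(path).read_text())
    return GroupSummary(
        item_names=tuple(payload["item_names"]),
        S=np.asarray(payload["covariance"], dtype=float),
        xbar=np.asarray(payload["means"], dtype=float),
        n=int(payload["n"]),
        label=payload.get("label", ""),
    )
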