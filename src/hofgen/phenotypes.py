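"""Weekly hatch-of-fertile phenotype records and data editing.

A phenotype table is a pandas DataFrame with one row per hen-week:

    hen_id, mate_id, pou, age_week, egg_age, eggs_set, eggs_fertile,
    eggs_hatched, hof

``pou`` is the contemporary group (birds from 3 successive weeks of
hatches reared together), ``age_week`` the hen's age in weeks when her
eggs hatched, ``egg_age`` the mean storage age (days) of the eggs set
that week.  Hatch of fertile is always computed, never read:
%HoF = 100 * hatched / fertile, undefined when no egg was fertile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "compute_hof", "validate_table", "apply_editing"]

REQUIRED_COLUMNS = (
    "hen_id",
    "mate_id",
    "pou",
    "age_week",
    "egg_age",
    "eggs_set",
    "eggs_fertile",
    "eggs_hatched",
)


def compute_hof(eggs_hatched, eggs_fertile):
    """Percent hatch of fertile: 100 * hatched / fertile.

    Returns NaN where no egg was fertile.  Raises if hatched exceeds
    fertile (an impossible record).
    """
    hatched = np.asarray(eggs_hatched, dtype=float)
    fertile = np.asarray(eggs_fertile, dtype=float)
    if np.any(hatched > fertile):
        raise ValueError("eggs_hatched exceeds eggs_fertile")
    if np.any(hatched < 0) or np.any(fertile < 0):
        raise ValueError("egg counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(fertile > 0, 100.0 * hatched / np.where(fertile > 0, fertile, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def validate_table(table: pd.DataFrame, check_counts: bool = True) -> pd.DataFrame:
    """Check the invariants of a phenotype table; return the table.

    ``check_counts=False`` skips the hof == 100*hatched/fertile identity
    (the Gaussian simulator stores a continuous hof that is not an
    integer-count ratio).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    t = table
    if (t["eggs_hatched"] > t["eggs_fertile"]).any():
        bad = t.index[t["eggs_hatched"] > t["eggs_fertile"]][0]
        raise ValueError(f"row {bad}: eggs_hatched > eggs_fertile")
    if (t["eggs_fertile"] > t["eggs_set"]).any():
        bad = t.index[t["eggs_fertile"] > t["eggs_set"]][0]
        raise ValueError(f"row {bad}: eggs_fertile > eggs_set")
    if (t[["eggs_set", "eggs_fertile", "eggs_hatched"]] < 0).any().any():
        raise ValueError("negative egg counts")
    if check_counts and "hof" in t.columns:
        fertile = t["eggs_fertile"] > 0
        expect = 100.0 * t.loc[fertile, "eggs_hatched"] / t.loc[fertile, "eggs_fertile"]
        if not np.allclose(t.loc[fertile, "hof"], expect, atol=1e-8):
            raise ValueError("hof inconsistent with 100*hatched/fertile")
    return table


def apply_editing(
    table: pd.DataFrame,
    min_records: int = 5,
    year_window: tuple | None = None,
) -> pd.DataFrame:
    """Apply the standard edits to a weekly phenotype table.

    In order:

    1. drop hen-weeks with no egg set (no possible chick output; HoF
       undefined);
    2. if ``year_window=(start, end)`` is given and the table has a
       ``year`` column, drop records outside the window and remove
       entirely any hen whose records overlap the window start (hens
       with records from before the window);
    3. drop all records of hens left with fewer than ``min_records``
       weekly records (early deaths carry too little information).

    Returns a copy; an empty result is allowed.
    """
    t = table.copy()
    t = t[t["eggs_set"] > 0]
    if year_window is not None and "year" in t.columns:
        start, end = year_window
        overlapping = t.loc[t["year"] < start, "hen_id"].unique()
        t = t[~t["hen_id"].isin(overlapping)]
        t = t[(t["year"] >= start) & (t["year"] <= end)]
    counts = t.groupby("hen_id")["hen_id"].transform("size")
    t = t[counts >= min_records]
    return t.reset_index(drop=True)
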