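"""Reading and writing the delimited text tables the pipeline exchanges.

Count tables are headered delimited text with columns ``cell_id, count`` and
optional ``gene, strain, replicate`` annotations; paired tables carry
``cell_id, count_a, count_b``.  Tab is the default delimiter throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .information import PairedCounts

__all__ = [
    "read_counts",
    "write_counts",
    "read_paired_counts",
    "write_paired_counts",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _as_int_counts(series: pd.Series, path, col) -> np.ndarray:
    values = series.to_numpy()
    bad = ~np.isfinite(values.astype(float)) if values.dtype.kind == "f" else np.zeros(len(values), bool)
    if bad.any() or (values.astype(float) != np.floor(values.astype(float))).any():
        row = int(np.argmax(bad | (values.astype(float) != np.floor(values.astype(float)))))
        raise ValueError(f"{path}: non-integer value in column '{col}' at data row {row}")
    out = values.astype(np.int64)
    if (out < 0).any():
        row = int(np.argmax(out < 0))
        raise ValueError(f"{path}: negative count in column '{col}' at data row {row}")
    return out


def read_counts(path, sep: str = "\t") -> np.ndarray:
    """Counts from a headered table with at least ``cell_id`` and ``count``."""
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ["cell_id", "count"], path)
    return _as_int_counts(df["count"], path, "count")


def write_counts(path, counts, cell_ids=None, sep: str = "\t", **annotations) -> None:
    counts = np.asarray(counts, dtype=np.int64)
    if cell_ids is None:
        cell_ids = [f"cell_{i:05d}" for i in range(len(counts))]
    df = pd.DataFrame({"cell_id": cell_ids, "count": counts})
    for key, value in annotations.items():
        df[key] = value
    df.to_csv(path, sep=sep, index=False)


def read_paired_counts(path, sep: str = "\t", labels: dict | None = None) -> PairedCounts:
    """Paired counts from a table with ``cell_id, count_a, count_b``."""
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ["cell_id", "count_a", "count_b"], path)
    if df[["count_a", "count_b"]].isna().any().any():
        row = int(df[["count_a", "count_b"]].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: unpaired (missing) count at data row {row}")
    x = _as_int_counts(df["count_a"], path, "count_a")
    y = _as_int_counts(df["count_b"], path, "count_b")
    return PairedCounts(x, y, labels or {})


def write_paired_counts(path, paired: PairedCounts, cell_ids=None, sep: str = "\t") -> None:
    if cell_ids is None:
        cell_ids = [f"cell_{i:05d}" for i in range(len(paired))]
    pd.DataFrame(
        {"cell_id": cell_ids, "count_a": paired.x, "count_b": paired.y}
    ).to_csv(path, sep=sep, index=False)
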