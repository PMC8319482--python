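"""Reading and writing the tabular spatial-count dataset.

CSV schema: header columns ``id, u, v, y1, y2, x1..xq`` (``q`` inferred from
the header).  Counts must be non-negative integers; coordinates and
predictors finite.  An intercept column is prepended on load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import SpatialDataset

logger = logging.getLogger(__name__)

__all__ = ["SchemaError", "read_dataset", "write_dataset"]


class SchemaError(ValueError):
    """The input file does not match the expected dataset schema."""


def _predictor_columns(columns) -> list[str]:
    xs = sorted((c for c in columns if c.startswith("x") and c[1:].isdigit()),
                key=lambda c: int(c[1:]))
    expected = [f"x{i}" for i in range(1, len(xs) + 1)]
    if xs != expected:
        raise SchemaError(f"predictor columns must be x1..xq, found {xs}")
    return xs


def read_dataset(path: str | Path, min_rows: int = 2) -> SpatialDataset:
    """Load and validate a dataset CSV into a :class:`SpatialDataset`."""
    df = pd.read_csv(path)
    required = ["id", "u", "v", "y1", "y2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    xcols = _predictor_columns(df.columns)
    if not xcols:
        raise SchemaError("no predictor columns x1..xq found")
    use = df[required + xcols]
    if use.isna().any().any():
        row = int(use.isna().any(axis=1).idxmax())
        col = use.columns[use.isna().any().to_numpy()][0]
        raise SchemaError(f"missing value at row {row}, column {col!r}")
    for col in ("y1", "y2"):
        vals = df[col].to_numpy()
        frac = np.modf(vals.astype(float))[0]
        if np.any(frac != 0):
            row = int(np.nonzero(frac != 0)[0][0])
            raise SchemaError(f"non-integer count at row {row}, column {col!r}")
        if np.any(vals < 0):
            row = int(np.nonzero(vals < 0)[0][0])
            raise SchemaError(f"negative count at row {row}, column {col!r}")
    numeric = df[["u", "v"] + xcols].to_numpy(dtype=float)
    if not np.all(np.isfinite(numeric)):
        raise SchemaError("coordinates and predictors must be finite")
    if len(df) < min_rows:
        raise SchemaError(f"need at least {min_rows} rows, got {len(df)}")
    if len(df) < 10:
        logger.warning("dataset has only %d rows; local fits may be unstable", len(df))
    X = np.column_stack([np.ones(len(df)), df[xcols].to_numpy(dtype=float)])
    return SpatialDataset(ids=df["id"].to_numpy(),
                          coords=df[["u", "v"]].to_numpy(dtype=float),
                          y1=df["y1"].to_numpy(), y2=df["y2"].to_numpy(), X=X)


def write_dataset(dataset: SpatialDataset, path: str | Path) -> None:
    """Write a dataset back to the standard CSV schema."""
    q = dataset.q
    df = pd.DataFrame({"id": dataset.ids,
                       "u": dataset.coords[:, 0], "v": dataset.coords[:, 1],
                       "y1": dataset.y1, "y2": dataset.y2})
    for j in range(1, q + 1):
        df[f"x{j}"] = dataset.X[:, j]
    df.to_csv(path, index=False)
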