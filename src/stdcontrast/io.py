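"""Reading long-format ANCOVA tables and serializing result records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ancova import ANCOVAData

__all__ = ["read_ancova_table", "write_records", "read_records"]


def read_ancova_table(path, delimiter: str | None = None) -> ANCOVAData:
    """Read a delimiter-separated table with header ``group, y, x1..xP``.

    The delimiter is sniffed when not given. Non-numeric or missing values
    in the response/covariate columns are rejected with row numbers
    (1-based, counting the header as row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "group" not in cols or "y" not in cols:
        raise ValueError(f"{path}: expected columns 'group', 'y', 'x1'..'xP', got {cols}")
    xcols = [c for c in cols if c.startswith("x") and c[1:].isdigit()]
    xcols.sort(key=lambda c: int(c[1:]))
    if not xcols:
        raise ValueError(f"{path}: no covariate columns x1..xP found")
    if [int(c[1:]) for c in xcols] != list(range(1, len(xcols) + 1)):
        raise ValueError(f"{path}: covariate columns must be consecutive x1..xP, got {xcols}")

    numeric = df[["y"] + xcols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | df["group"].isna()
    if bad.any():
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(bad.to_numpy())[:10])
        raise ValueError(f"{path}: missing or non-numeric values at row(s) {rows}")
    return ANCOVAData(
        group=df["group"].to_numpy(),
        y=numeric["y"].to_numpy(dtype=float),
        x=numeric[xcols].to_numpy(dtype=float),
    )


def write_records(records: list[dict], path) -> None:
    """Write result records as JSON lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_records(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
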