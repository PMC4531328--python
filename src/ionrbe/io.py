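"""Typed CSV table I/O.

All tables are plain CSV with explicit headers and a decimal point (no
locale).  Each documented schema is a named column set; reading validates
the header and every cell, reporting the row/column coordinates of any
offending value, and writing uses 12 significant digits so a write -> read
round trip is lossless at that precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table"]

#: Documented schemas: required columns, then optional ones.
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "calibration": (("x", "y"), ("weight",)),
    "z_calibration": (("z", "let_u"), ("weight",)),
    "survival": (("dose", "sf"), ("weight", "rep")),
    "let_grid": (("let",), ()),
    "curve": (("let", "alpha_h", "beta_h", "rbe"), ()),
    "scaling": (("let", "efficiency", "alpha_h", "beta_h"), ()),
    "isoeffect": (("m", "d_h", "total_dose"), ()),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV table and validate it against a named schema.

    Raises ``ValueError`` for an unknown schema, missing/extra columns, or
    non-numeric cells (named by row and column).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {', '.join(SCHEMAS)}")
    required, optional = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    extra = [c for c in cols if c not in required + optional]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {', '.join(missing)}")
        if extra:
            parts.append(f"extra columns: {', '.join(extra)}")
        raise ValueError(f"table does not match schema {schema!r} ({'; '.join(parts)})")
    out = {}
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell at row {row + 1}, column {col!r}: {df[col].iloc[row]!r}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(f"empty cell at row {row + 1}, column {col!r}")
        out[col] = vals.astype(float)
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a table as CSV at 12 significant digits.

    When ``schema`` is given the frame's columns are validated against it
    first, so malformed output is caught at the producer.
    """
    if schema is not None:
        if schema not in SCHEMAS:
            raise ValueError(f"unknown schema {schema!r}; known: {', '.join(SCHEMAS)}")
        required, optional = SCHEMAS[schema]
        missing = [c for c in required if c not in df.columns]
        extra = [c for c in df.columns if c not in required + optional]
        if missing or extra:
            raise ValueError(
                f"frame does not match schema {schema!r} "
                f"(missing: {missing}, extra: {extra})"
            )
    df.to_csv(path, index=False, float_format="%.12g")
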