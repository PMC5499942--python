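"""Tabular input/output with schema validation.

All pipeline inputs and outputs are plain CSV tables.  ``load_table``
validates column presence, coercible dtypes and finiteness so malformed
recordings fail loudly with the offending column or row named.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["load_table", "write_table", "TAIL_SCHEMA", "PHOTON_SCHEMA", "ROI_SCHEMA"]

#: column name -> required dtype kind ("f" float, "i" integer, "O" string)
TAIL_SCHEMA = {
    "larva_id": "O",
    "trial_id": "O",
    "frame": "i",
    "angle_deg": "f",
}
PHOTON_SCHEMA = {
    "larva_id": "O",
    "trial_id": "O",
    "time_ms": "i",
    "photon_count": "i",
}
ROI_SCHEMA = {"roi_id": "O", "frame": "i", "f": "f", "dv_raw": "f"}


def load_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Load a CSV table and validate it against a column schema.

    Raises ``ValueError`` naming the first missing column, or the row
    index of the first non-finite value in a numeric column.  Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col, kind in schema.items():
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
        if kind in ("f", "i"):
            values = pd.to_numeric(df[col], errors="coerce")
            bad = ~np.isfinite(values.to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-finite value in column {col!r} at row {row}"
                )
            df[col] = values.astype(int) if kind == "i" else values.astype(float)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV, creating parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
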