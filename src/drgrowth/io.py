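"""Plate CSV reading/writing and result export.

The plate CSV is long format with columns
``cell_line, replicate, time_h, conc, conc_index, well, absorbance,
is_background, is_control``; ``conc`` may be linear or log10 (see
``conc_is_log10``), the internal canonical form is log10.  Missing absorbance
values are permitted and skipped; non-numeric entries raise with the
offending line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .plates import PLATE_COLUMNS, RawPlateSet

__all__ = ["read_plate_csv", "write_plate_csv", "write_results", "read_legacy_table"]


def read_plate_csv(path, conc_is_log10: bool = True) -> RawPlateSet:
    """Load a plate CSV into a validated :class:`RawPlateSet`."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("absorbance", "conc"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            lines = [i + 2 for i in df.index[bad]]  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} on lines {lines}")
        df[col] = coerced
    if not conc_is_log10:
        pos = df["conc"] > 0
        df.loc[pos, "conc"] = np.log10(df.loc[pos, "conc"])
        df.loc[~pos & df["conc"].notna(), "conc"] = np.nan
    return RawPlateSet(df[PLATE_COLUMNS])


def write_plate_csv(raw: RawPlateSet, path) -> None:
    raw.records[PLATE_COLUMNS].to_csv(path, index=False)


def write_results(stats_frames, csv_path, json_path=None) -> None:
    """Write tidy per-statistic results as CSV and optionally a JSON report."""
    table = pd.concat(list(stats_frames), ignore_index=True)
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = table.to_dict(orient="records")
        Path(json_path).write_text(json.dumps(payload, indent=2, default=float))


def read_legacy_table(path) -> pd.DataFrame:
    """Load a legacy growth-inhibition table.

    Columns: ``compound, cell_line, T0_h, t_h, model`` ({D|R}), then one
    column per concentration whose header is the log10 concentration.
    """
    df = pd.read_csv(path)
    meta = ["compound", "cell_line", "T0_h", "t_h", "model"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: legacy table missing columns {missing}")
    conc_cols = [c for c in df.columns if c not in meta]
    try:
        ladder = np.asarray([float(c) for c in conc_cols])
    except ValueError as err:
        raise ValueError(f"{path}: concentration column headers must be numeric") from err
    if not np.all(np.diff(ladder) > 0):
        raise ValueError(f"{path}: concentration ladder must be strictly increasing")
    return df
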