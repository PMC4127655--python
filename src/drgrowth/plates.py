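"""Well-level plate data containers for 96-well proliferation assays.

A :class:`RawPlateSet` holds long-format absorbance records indexed by
(replicate ``k``, exposure time ``t`` in hours, concentration index ``i``,
well ``l``).  Index ``i = 0`` is the untreated control; ``i = 1..I`` map to a
strictly increasing log10 concentration ladder.  Background wells (medium
only, no cells) carry ``is_background = True`` and pin the additive plate
background in the pre-processing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLATE_COLUMNS", "RawPlateSet", "ColourCorrection"]

PLATE_COLUMNS = [
    "cell_line",
    "replicate",
    "time_h",
    "conc",
    "conc_index",
    "well",
    "absorbance",
    "is_background",
    "is_control",
]


@dataclass
class RawPlateSet:
    """Validated long-format plate records plus the concentration ladder.

    ``records`` columns follow :data:`PLATE_COLUMNS`; ``conc`` is the log10
    concentration (NaN for the untreated control and for background wells).
    """

    records: pd.DataFrame
    concentrations: np.ndarray = field(default=None)  # log10 ladder, index 1..I

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"plate records missing columns: {missing}")
        rec = self.records.copy()
        rec["is_background"] = rec["is_background"].astype(bool)
        rec["is_control"] = rec["is_control"].astype(bool)
        rec = rec.dropna(subset=["absorbance"]).reset_index(drop=True)
        if rec.empty:
            raise ValueError("plate set contains no usable absorbance records")
        self.records = rec

        drugged = rec[~rec["is_background"] & ~rec["is_control"]]
        if self.concentrations is None:
            ladder = (
                drugged[["conc_index", "conc"]]
                .drop_duplicates()
                .sort_values("conc_index")
            )
            if ladder["conc_index"].duplicated().any():
                raise ValueError("conc_index maps to more than one concentration")
            self.concentrations = ladder["conc"].to_numpy(dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.concentrations) and not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentration ladder must be strictly increasing")

        for (k, t), plate in rec.groupby(["replicate", "time_h"]):
            if not plate["is_background"].any():
                raise ValueError(f"plate (replicate={k}, time={t}) has no background wells")
            if not (~plate["is_background"]).any():
                raise ValueError(f"plate (replicate={k}, time={t}) has only background wells")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.records["time_h"].unique())

    @property
    def replicates(self) -> np.ndarray:
        return np.sort(self.records["replicate"].unique())

    @property
    def conc_indices(self) -> np.ndarray:
        """Concentration indices present among cell-bearing wells (0 = control)."""
        cells = self.records[~self.records["is_background"]]
        return np.sort(cells["conc_index"].unique())

    def subset_times(self, times) -> "RawPlateSet":
        """Restrict to plates at the given exposure times."""
        keep = self.records["time_h"].isin(list(times))
        if not keep.any():
            raise ValueError(f"no plates at times {times}")
        return RawPlateSet(self.records[keep].reset_index(drop=True), self.concentrations)


@dataclass(frozen=True)
class ColourCorrection:
    """Per-concentration excess absorbance of a coloured drug.

    Estimated from cell-free background plates and subtracted from the raw
    absorbance of drugged cell wells before any model fitting.  Values are
    floored at zero (a drug cannot remove absorbance).
    """

    values: dict[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", {int(i): max(float(v), 0.0) for i, v in self.values.items()}
        )


def apply_colour_correction(raw: RawPlateSet, cc: ColourCorrection) -> RawPlateSet:
    """Subtract drug-colour absorbance from drugged cell wells.

    Untreated controls and background wells (both drug-free) are unchanged.
    Corrected absorbance may go negative; only final pre-processed estimates
    are floored.
    """
    rec = raw.records.copy()
    drugged = ~rec["is_background"] & ~rec["is_control"]
    indices = rec.loc[drugged, "conc_index"].unique()
    missing = [int(i) for i in indices if int(i) not in cc.values]
    if missing:
        raise ValueError(f"colour correction missing concentration indices {sorted(missing)}")
    corr = rec.loc[drugged, "conc_index"].map(lambda i: cc.values[int(i)])
    rec.loc[drugged, "absorbance"] = rec.loc[drugged, "absorbance"] - corr
    return RawPlateSet(rec, raw.concentrations)
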