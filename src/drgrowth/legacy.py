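"""Re-analysis of legacy growth-inhibition tables under the time-free G-model.

Large historical screens store D-model (net-difference) or R-model (relative
count) values at a fixed exposure time.  Given each line's doubling time,
those values transform exactly to the time-free G-model; isotonic regression
and linear interpolation then yield a corrected GI50 that is comparable
across cell lines with different growth rates.  The uncorrected GI50 (D- or
R-model value at 0.5) is reported alongside for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .curves import DoseResponseCurve, isotonic_decreasing
from .models import d_to_g, r_to_g
from .summaries import stat_from_curve

__all__ = ["transform_legacy_row", "transform_legacy_table"]


def transform_legacy_row(
    values, concentrations, model: str, T0: float, t: float
):
    """Corrected G-curve and GI50 for one legacy dose-response series.

    Returns ``(curve, gi50, gi50_uncorrected)`` where both statistics are
    :class:`~drgrowth.summaries.CurveStat` tuples with censoring flags.
    """
    values = np.asarray(values, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 2:
        raise ValueError("legacy series needs >= 2 finite values")
    values, conc = values[ok], conc[ok]
    if model == "D":
        g_vals = d_to_g(values, t, T0)
        uncorrected = DoseResponseCurve(
            model="D", grid=conc, raw=isotonic_decreasing(values), t_ref=t,
            growth_scale=1.0,
        )
        gi50_unc = stat_from_curve(uncorrected, 0.5)
    elif model == "R":
        g_vals = r_to_g(values, t, T0)
        uncorrected = DoseResponseCurve(
            model="R", grid=conc, raw=isotonic_decreasing(values), t_ref=t
        )
        gi50_unc = stat_from_curve(uncorrected, 0.5)
    else:
        raise ValueError(f"legacy model must be 'D' or 'R', got {model!r}")
    # transformed G values live on the rate scale divided by T0 on the growth
    # branch already; isotonize the G values directly (monotone transform of a
    # monotone quantity), with the branchwise map folded in via growth_scale=1
    curve = DoseResponseCurve(
        model="G", grid=conc, raw=isotonic_decreasing(np.asarray(g_vals, dtype=float)),
        T0_ref=T0, growth_scale=1.0,
    )
    gi50 = stat_from_curve(curve, 0.5)
    return curve, gi50, gi50_unc


def transform_legacy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the G-model correction to every row of a legacy table.

    ``table`` as produced by :func:`drgrowth.io.read_legacy_table`.  Rows with
    missing doubling time are skipped with a warning.  Returns one row per
    input row with corrected and uncorrected GI50 and censoring flags.
    """
    meta = ["compound", "cell_line", "T0_h", "t_h", "model"]
    conc_cols = [c for c in table.columns if c not in meta]
    ladder = np.asarray([float(c) for c in conc_cols])
    out = []
    for idx, row in table.iterrows():
        if not np.isfinite(row["T0_h"]):
            warnings.warn(f"row {idx}: missing doubling time, skipped", stacklevel=2)
            continue
        _, gi50, gi50_unc = transform_legacy_row(
            row[conc_cols].to_numpy(dtype=float), ladder, str(row["model"]),
            float(row["T0_h"]), float(row["t_h"]),
        )
        out.append(
            dict(compound=row["compound"], cell_line=row["cell_line"],
                 T0_h=row["T0_h"], t_h=row["t_h"], model=row["model"],
                 GI50=gi50.value, GI50_censored=gi50.censored or "",
                 GI50_uncorrected=gi50_unc.value,
                 GI50_uncorrected_censored=gi50_unc.censored or "")
        )
    return pd.DataFrame(out)
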