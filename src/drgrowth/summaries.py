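"""Summary statistics (GI50, TGI, LC48, AUC0) and parametric-bootstrap intervals.

All threshold statistics are read off the piecewise-linear monotone curve:
the smallest concentration at which the curve equals the threshold, linearly
inverted within the bracketing segment.  Thresholds the curve never crosses
are censored at the nearest ladder endpoint.  ``AUC_q`` is the area between
the curve and the level ``q`` where the curve exceeds ``q``, on the percent
scale over log10 concentration (trapezoidal, with exact crossing points
inserted).

Confidence intervals come from a conditional parametric bootstrap: plate sets
are regenerated from the fitted pre-processing model (plate effects held
fixed, technical noise redrawn from the fitted power-variance law), the
workflow is re-run without outlier rejection, and percentile intervals are
taken over the replicate statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .curves import DoseResponseCurve, g_curve
from .growthfit import fit_growth
from .preprocess import ConvergenceWarning, PreprocessedAbsorbance, fit_plate_model

__all__ = [
    "CurveStat",
    "SummaryStatistics",
    "stat_from_curve",
    "auc",
    "g_summaries",
    "summaries_for_d_r",
    "bootstrap_summaries",
    "G_THRESHOLDS",
    "D_THRESHOLDS",
    "R_THRESHOLDS",
]

G_THRESHOLDS = {"GI50": 0.5, "TGI": 0.0, "LC48": -1.0 / 48.0}
D_THRESHOLDS = {"GI50D": 0.5, "TGID": 0.0, "LC50D": -0.5}
R_THRESHOLDS = {"GI25R": 0.75, "GI50R": 0.5, "GI75R": 0.25}


class CurveStat(NamedTuple):
    """A concentration statistic with its censoring state (None, 'low' or 'high')."""

    value: float
    censored: str | None = None


@dataclass
class SummaryStatistics:
    """Named concentration statistics plus AUC for one curve, with optional CIs."""

    model: str
    stats: dict[str, CurveStat]
    auc0: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    censored_fraction: dict[str, float] = field(default_factory=dict)
    n_bootstrap: int = 0

    def to_frame(self, cell_line: str = "") -> pd.DataFrame:
        """Tidy one-row-per-statistic table (estimate, lower, upper, censored)."""
        rows = []
        entries = dict(self.stats)
        if self.auc0 is not None:
            entries["AUC0"] = CurveStat(self.auc0, None)
        for name, st in entries.items():
            lo, hi = self.ci.get(name, (math.nan, math.nan))
            rows.append(
                dict(cell_line=cell_line, model=self.model, statistic=name,
                     estimate=st.value, lower=lo, upper=hi,
                     censored=st.censored or "")
            )
        return pd.DataFrame(rows)


def stat_from_curve(curve: DoseResponseCurve, threshold: float) -> CurveStat:
    """Smallest log10 concentration where the curve equals ``threshold``.

    The inversion happens on the precursor scale (exact for the branchwise
    model maps).  A curve entirely below the threshold is censored low at
    ``c_1`` (the drug already acts at the lowest dose); entirely above,
    censored high at ``c_I``.
    """
    thr = curve.raw_threshold(threshold)
    y = curve.raw
    c = curve.grid
    if y[0] < thr:
        return CurveStat(float(c[0]), "low")
    if y[-1] > thr:
        return CurveStat(float(c[-1]), "high")
    # first index where the non-increasing curve has dropped to the threshold
    j = int(np.argmax(y <= thr))
    if y[j] == thr or j == 0:
        return CurveStat(float(c[j]), None)
    frac = (y[j - 1] - thr) / (y[j - 1] - y[j])
    return CurveStat(float(c[j - 1] + frac * (c[j] - c[j - 1])), None)


def auc(curve: DoseResponseCurve, q: float = 0.0) -> float:
    """Percent-scale area above level ``q`` and below the curve over log10 c.

    ``integral of max(100*curve(c) - 100*q, 0)`` between the ladder endpoints.
    Model-map kinks (the TGI point) and ``q``-crossings are inserted as exact
    nodes so the trapezoid rule is exact for the piecewise-linear curve.
    """
    nodes = list(curve.grid)
    for target in {curve.raw_threshold(q), 0.0 if curve.model in ("G", "D") else None} - {None}:
        y, c = curve.raw, curve.grid
        for j in range(len(c) - 1):
            y0, y1 = y[j], y[j + 1]
            if (y0 - target) * (y1 - target) < 0:
                nodes.append(c[j] + (y0 - target) / (y0 - y1) * (c[j + 1] - c[j]))
    nodes = np.unique(np.asarray(nodes, dtype=float))
    vals = np.maximum(100.0 * (curve(nodes) - q), 0.0)
    return float(np.trapezoid(vals, nodes))


def g_summaries(curve: DoseResponseCurve, lc_t: float = 48.0) -> SummaryStatistics:
    """GI50, TGI, LC(t) and AUC0 of a growth-model curve."""
    if curve.model != "G":
        raise ValueError("g_summaries expects a G-model curve")
    thresholds = dict(G_THRESHOLDS)
    thresholds[f"LC{lc_t:g}"] = -1.0 / lc_t
    stats = {name: stat_from_curve(curve, thr) for name, thr in thresholds.items()}
    return SummaryStatistics(model="G", stats=stats, auc0=auc(curve, 0.0))


def summaries_for_d_r(curve: DoseResponseCurve) -> SummaryStatistics:
    """Conventional summary thresholds for the D and R models.

    D: curve values 0.5, 0 and -0.5; R: 0.75, 0.5 and 0.25.
    """
    if curve.model == "D":
        thresholds = D_THRESHOLDS
    elif curve.model == "R":
        thresholds = R_THRESHOLDS
    else:
        raise ValueError("summaries_for_d_r expects a D- or R-model curve")
    stats = {name: stat_from_curve(curve, thr) for name, thr in thresholds.items()}
    out = SummaryStatistics(model=curve.model, stats=stats)
    if curve.model == "D":
        out.auc0 = auc(curve, 0.0)
    return out


def g_summaries_from_preprocessed(pre: PreprocessedAbsorbance, lc_t: float = 48.0):
    """Growth fit -> G curve -> summary statistics, returning all three."""
    fit = fit_growth(pre)
    curve = g_curve(fit)
    return fit, curve, g_summaries(curve, lc_t=lc_t)


def _plate_effect_law(pre: PreprocessedAbsorbance):
    """Lognormal law of the plate effects implied by the fitted delta/beta.

    The per-time gauge constraint centres log(delta) at zero within each time,
    so the scale spread is estimated with the per-time means removed (degrees
    of freedom = plates - times).  Returns (sigma_log_delta, mu_log_beta,
    sigma_log_beta); scales are 0 when not estimable (single plate per time)
    or when a fitted effect is non-positive.
    """
    dvals = pre.delta.to_numpy(dtype=float)
    bvals = pre.beta.to_numpy(dtype=float)
    times = pre.delta.index.get_level_values("time_h").to_numpy(dtype=float)
    n_times = len(np.unique(times))
    sd_ld, df_ld = 0.0, 0
    if np.all(dvals > 0) and len(dvals) - n_times >= 1:
        logd = np.log(dvals)
        centred = logd - np.array(
            [logd[np.isclose(times, t)].mean() for t in times]
        )
        df_ld = len(dvals) - n_times
        sd_ld = math.sqrt(float(np.sum(centred**2)) / df_ld)
    if np.all(bvals > 0):
        logb = np.log(bvals)
        mu_lb = float(np.mean(logb))
        sd_lb = float(np.std(logb, ddof=1)) if len(bvals) > 1 else 0.0
    else:
        mu_lb, sd_lb = math.nan, 0.0
    return sd_ld, df_ld, mu_lb, sd_lb


def _simulate_from_fit(
    pre: PreprocessedAbsorbance,
    rng: np.random.Generator,
    resample_plate_effects: bool = True,
    law=None,
) -> pd.DataFrame:
    """Draw one plate set from the fitted pre-processing model (all wells).

    With ``resample_plate_effects`` the multiplicative and additive plate
    effects are redrawn from the lognormal law estimated off the fitted
    delta/beta, so the replicate carries fresh between-plate (and hence
    between-time scale) noise; otherwise the fitted effects are held fixed and
    only technical noise is redrawn.
    """
    rec = pre.records
    plates = list(pre.delta.index)
    if resample_plate_effects:
        sd_ld, df_ld, mu_lb, sd_lb = law if law is not None else _plate_effect_law(pre)
        if df_ld >= 1 and sd_ld > 0:
            # propagate the sampling uncertainty of the few-df scale estimate
            sd_rep = sd_ld * math.sqrt(df_ld / rng.chisquare(df_ld))
        else:
            sd_rep = sd_ld
        delta = {p: math.exp(rng.normal(0.0, sd_rep)) for p in plates}
        if math.isnan(mu_lb):
            beta = {p: float(pre.beta.loc[p]) for p in plates}
        else:
            beta = {p: math.exp(rng.normal(mu_lb, sd_lb)) for p in plates}
    else:
        delta = {p: float(pre.delta.loc[p]) for p in plates}
        beta = {p: float(pre.beta.loc[p]) for p in plates}

    key = list(zip(rec["replicate"], rec["time_h"]))
    b = np.array([beta[p] for p in key])
    d = np.array([delta[p] for p in key])
    is_cell = ~rec["is_background"].to_numpy(dtype=bool)
    a = np.zeros(len(rec))
    cols = set(pre.alpha.columns)
    for r in np.flatnonzero(is_cell):
        i = int(rec["conc_index"].iat[r])
        t = rec["time_h"].iat[r]
        a[r] = pre.alpha.loc[t, i] if i in cols else np.nan
    m = b + np.where(is_cell, d * a, 0.0)
    keep = np.isfinite(m)
    sd = np.maximum(np.abs(m[keep]), 1e-6) ** pre.xi * pre.sigma
    out = rec.loc[keep].copy()
    out["absorbance"] = m[keep] + rng.normal(0.0, 1.0, size=keep.sum()) * sd
    return out.reset_index(drop=True)


def bootstrap_summaries(
    pre_fit: PreprocessedAbsorbance,
    J: int = 200,
    seed: int | np.random.Generator | None = None,
    lc_t: float = 48.0,
    max_failure_fraction: float = 0.2,
    resample_plate_effects: bool = True,
) -> SummaryStatistics:
    """Point estimates with percentile bootstrap confidence intervals.

    For each of ``J`` replicates a plate set is generated from the fitted
    pre-processing model, pre-processed *without* outlier rejection, passed
    through the growth fit and the G-model curve, and summarised.  The 2.5%
    and 97.5% percentiles of the replicate statistics form the intervals.
    Censored replicate statistics enter the percentiles at their endpoint
    values; the censoring fraction is reported alongside.

    ``resample_plate_effects`` (default) redraws the plate effects from their
    fitted lognormal law in every replicate, which is what gives the
    intervals frequentist coverage against repetitions of the whole
    experiment; with ``False`` the plate effects are conditioned on and the
    intervals reflect technical noise only.
    """
    if J < 2:
        raise ValueError("bootstrap needs J >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    law = _plate_effect_law(pre_fit) if resample_plate_effects else None
    _, _, point = g_summaries_from_preprocessed(pre_fit, lc_t=lc_t)

    names = list(point.stats) + ["AUC0"]
    draws: dict[str, list[float]] = {n: [] for n in names}
    cens: dict[str, int] = {n: 0 for n in names}
    failures = 0
    warm = pre_fit.start_values()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(J):
            rec = _simulate_from_fit(pre_fit, rng, resample_plate_effects, law)
            try:
                boot_pre = fit_plate_model(rec, floor=pre_fit.floor, start=warm)
                boot_pre.concentrations = pre_fit.concentrations
                _, _, summ = g_summaries_from_preprocessed(boot_pre, lc_t=lc_t)
            except Exception:
                failures += 1
                continue
            for n, st in summ.stats.items():
                draws[n].append(st.value)
                if st.censored:
                    cens[n] += 1
            draws["AUC0"].append(summ.auc0)
    if failures > max_failure_fraction * J:
        raise RuntimeError(f"{failures}/{J} bootstrap replicates failed to converge")
    if failures:
        warnings.warn(f"{failures}/{J} bootstrap replicates failed and were dropped",
                      ConvergenceWarning, stacklevel=2)
    n_ok = J - failures
    point.ci = {
        n: tuple(np.percentile(np.asarray(v), [2.5, 97.5])) for n, v in draws.items() if v
    }
    point.censored_fraction = {n: cens[n] / n_ok for n in point.stats}
    point.n_bootstrap = n_ok
    return point
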