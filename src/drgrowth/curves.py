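"""Monotone (isotonic) dose-response curves for the G, D and R models.

Both the G- and D-models have a singularity at total growth inhibition, so the
isotonic fit is applied to a smooth precursor -- the net growth rates
``Gamma_i = 1/Tc_i`` for G, the relative net changes
``Delta_i = (N(t,c_i) - N0)/N0`` for D -- and the branchwise model map is
applied afterwards.  Curves are piecewise linear in log10 concentration
between the fitted grid values and are never extrapolated beyond the ladder:
thresholds not bracketed by the curve are reported as censored at the nearest
endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

from .growthfit import GrowthFit
from .preprocess import ConvergenceWarning, PreprocessedAbsorbance

__all__ = ["DoseResponseCurve", "isotonic_decreasing", "g_curve", "d_curve", "r_curve"]


def isotonic_decreasing(y, w=None) -> np.ndarray:
    """Weighted least-squares non-increasing fit by pool-adjacent-violators.

    Solves min sum w_i (gamma_i - y_i)^2 subject to gamma_1 >= ... >= gamma_I;
    pooled blocks carry their (weighted) mean.  Weights default to equal, the
    plain square norm.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0 or not np.all(np.isfinite(y)):
        raise ValueError("isotonic_decreasing requires at least one finite value "
                         "and no missing entries")
    if w is not None:
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    return isotonic_regression(y, weights=w, increasing=False).x


@dataclass
class DoseResponseCurve:
    """Piecewise-linear monotone dose-response curve over log10 concentration.

    ``raw`` holds the isotonized precursor values at ``grid`` (net rates for
    G, relative net changes for D, relative counts for R); ``values`` applies
    the branchwise model map.  Linear interpolation is performed on the
    precursor scale, which makes the mapped curve exactly the branchwise image
    of a piecewise-linear function (continuous across the TGI kink).
    """

    model: str
    grid: np.ndarray
    raw: np.ndarray
    T0_ref: float | None = None
    t_ref: float | None = None
    growth_scale: float = field(default=1.0)  # multiplies raw on the growth branch

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.grid.size != self.raw.size:
            raise ValueError("grid and values must have equal length")
        if self.grid.size < 2:
            raise ValueError("a dose-response curve needs at least 2 concentrations")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.raw) > 1e-12):
            raise ValueError("curve values must be non-increasing")

    def _map(self, raw):
        raw = np.asarray(raw, dtype=float)
        if self.model == "R":
            out = raw
        else:
            out = np.where(raw >= 0, self.growth_scale * raw, raw)
        return out[()] if out.ndim == 0 else out

    @property
    def values(self) -> np.ndarray:
        """Model-scale curve values at the grid points."""
        return self._map(self.raw)

    def raw_threshold(self, threshold: float) -> float:
        """Map a model-scale threshold onto the precursor scale."""
        if self.model == "R":
            return threshold
        return threshold / self.growth_scale if threshold >= 0 else threshold

    def __call__(self, c):
        """Evaluate the curve at log10 concentration(s) within [c_1, c_I]."""
        c = np.asarray(c, dtype=float)
        if np.any(c < self.grid[0] - 1e-12) or np.any(c > self.grid[-1] + 1e-12):
            raise ValueError("curve is not extrapolated beyond the concentration ladder")
        out = self._map(np.interp(c, self.grid, self.raw))
        return out[()] if out.ndim == 0 else out


def g_curve(fit: GrowthFit) -> DoseResponseCurve:
    """Growth-model curve: isotonized net rates scaled by the doubling time.

    ``G(c) = T0_hat * gamma(c)`` on the growth branch (gamma >= 0) and
    ``gamma(c)`` on the decay branch.
    """
    ok = np.isfinite(fit.inv_Tc)
    if ok.sum() < 2:
        raise ValueError("g_curve needs net rates at >= 2 concentrations")
    gamma = isotonic_decreasing(fit.inv_Tc[ok])
    return DoseResponseCurve(
        model="G",
        grid=fit.concentrations[ok],
        raw=gamma,
        T0_ref=fit.T0_hat,
        growth_scale=fit.T0_hat,
    )


def _alpha_series(pre: PreprocessedAbsorbance, t: float):
    series = pre.alpha_at(t)
    if 0 not in series.index:
        raise ValueError("curve estimation needs the untreated control (index 0)")
    drug = series.drop(0)
    ok = drug.notna().to_numpy()
    idx = drug.index.to_numpy(dtype=int)[ok]
    vals = drug.to_numpy(dtype=float)[ok]
    return float(series[0]), idx, vals


def d_curve(pre: PreprocessedAbsorbance, t: float) -> DoseResponseCurve:
    """Difference-model curve at exposure time ``t``.

    The initial count (on the absorbance scale) is the untreated control at
    the earliest pre-processed time; the precursor ``Delta_i = (alpha_ti -
    alpha_0)/alpha_0`` is isotonized and mapped branchwise: divided by the
    untreated net change while non-negative (growth branch), identity on the
    decay branch.
    """
    t0 = float(pre.alpha.index.min())
    alpha00 = float(pre.alpha_at(t0)[0])
    if alpha00 <= pre.floor:
        warnings.warn("initial-count estimate sits at the absorbance floor",
                      ConvergenceWarning, stacklevel=2)
    alpha_t0, idx, vals = _alpha_series(pre, t)
    delta = (vals - alpha00) / alpha00
    delta0 = (alpha_t0 - alpha00) / alpha00
    if delta0 <= 0:
        warnings.warn("untreated series did not grow; D-model growth branch degenerate",
                      ConvergenceWarning, stacklevel=2)
        delta0 = np.nan
    return DoseResponseCurve(
        model="D",
        grid=pre.concentrations[idx - 1],
        raw=isotonic_decreasing(delta),
        T0_ref=None,
        t_ref=float(t),
        growth_scale=1.0 / delta0,
    )


def r_curve(pre: PreprocessedAbsorbance, t: float) -> DoseResponseCurve:
    """Relative-count curve at exposure time ``t``: isotonized ``alpha_ti / alpha_t0``."""
    alpha_t0, idx, vals = _alpha_series(pre, t)
    return DoseResponseCurve(
        model="R",
        grid=pre.concentrations[idx - 1],
        raw=isotonic_decreasing(vals / alpha_t0),
        t_ref=float(t),
    )
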