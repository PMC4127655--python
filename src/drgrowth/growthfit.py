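"""Estimation of doubling time and kill halving times from pre-processed absorbance.

The summarised absorbance at exposure time ``t`` and concentration index ``i``
is modelled as

    alpha_ti = alpha0 * 2**(t * (Ts0 - s_i * Tsc_i**2)),

where ``alpha0`` estimates ``gamma * N0`` (proportionality factor times seeded
count), ``s_i`` is 0 for the untreated control and 1 otherwise, and the
parameterisations ``T0 = 1/Ts0`` and ``Tc_dagger_i = 1/Tsc_i**2`` keep the
kill halving times positive.  The fit is ordinary (unweighted) nonlinear least
squares on the pre-processed values -- the heteroscedastic raw noise has
already been absorbed in the first stage.  Net times follow as
``1/Tc_i = 1/T0 - 1/Tc_dagger_i`` (negative reciprocal = net decay).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .preprocess import ConvergenceWarning, PreprocessedAbsorbance

__all__ = ["GrowthFit", "DegenerateGrowthError", "fit_growth"]


class DegenerateGrowthError(ValueError):
    """The untreated series shows no net growth (fitted doubling time <= 0).

    Growth-based dose-response statistics are undefined in this case: GI50 is
    the concentration doubling the doubling time and TGI the concentration
    cancelling growth, neither of which exists without growth.
    """

_LN2 = math.log(2.0)


@dataclass
class GrowthFit:
    """Fitted growth/kill parameters on the absorbance scale.

    ``inv_Tc[i]`` is the net growth rate ``1/Tc`` for concentration index
    ``i = 1..I`` (NaN where the concentration was unusable); ``censored``
    marks concentrations whose absorbance sat at the pre-processing floor at
    every time point, where the kill rate is only bounded from below.
    """

    alpha0: float
    T0_hat: float
    Tdagger_hat: np.ndarray
    inv_Tc: np.ndarray
    concentrations: np.ndarray
    times_used: np.ndarray
    residual_sd: float
    censored: np.ndarray

    @property
    def Tc_hat(self) -> np.ndarray:
        """Net doubling/halving times ``1/(1/T0 - 1/Tc_dagger)`` (signed; inf at TGI)."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.inv_Tc


def fit_growth(pre: PreprocessedAbsorbance) -> GrowthFit:
    """Nonlinear least-squares fit of the two-(or more-)time growth model."""
    table = pre.alpha
    times = table.index.to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError("growth fit needs pre-processed absorbance at >= 2 times")
    if 0 not in table.columns:
        raise ValueError("growth fit needs the untreated control series (index 0)")
    control = table[0].to_numpy(dtype=float)
    if np.isnan(control).sum() > len(times) - 2:
        raise ValueError("untreated control must be usable at >= 2 times")

    # absorbance summaries sitting at the pre-processing floor are left-censored:
    # feeding them to least squares as exact values drags the shared alpha0/T0
    # down, so they are excluded here and handled per concentration below
    floored = pre.floored if pre.floored is not None else table.isna() & False
    ok_table = table.notna() & ~floored

    drug_cols = [c for c in table.columns if c != 0]
    usable = [c for c in drug_cols if int(ok_table[c].sum()) >= 2]
    t1, t2 = times[0], times[-1]

    # closed-form, scale-free starting values from first/last log2 slopes
    a1, a2 = control[0], control[-1]
    ts0_0 = (math.log2(a2) - math.log2(a1)) / (t2 - t1)
    if ts0_0 <= 0:
        warnings.warn("untreated absorbance did not increase; doubling time at bound",
                      ConvergenceWarning, stacklevel=2)
        ts0_0 = 1e-4
    alpha0_0 = a1 / 2.0 ** (t1 * ts0_0)
    tsc_0 = []
    for c in usable:
        col = table[c].to_numpy(dtype=float)
        ok = ok_table[c].to_numpy(dtype=bool)
        slope = (math.log2(col[ok][-1]) - math.log2(col[ok][0])) / (
            times[ok][-1] - times[ok][0]
        )
        tsc_0.append(math.sqrt(max(ts0_0 - slope, 1e-8)))

    # residual layout: one entry per usable (finite, unfloored) table cell
    cols, tvals, svals, avals = [], [], [], []
    col_pos = {c: j for j, c in enumerate(usable)}
    for ti, t in enumerate(times):
        for c in [0, *usable]:
            v = table.loc[table.index[ti], c]
            if np.isfinite(v) and bool(ok_table.loc[table.index[ti], c]):
                tvals.append(t)
                svals.append(0.0 if c == 0 else 1.0)
                cols.append(-1 if c == 0 else col_pos[c])
                avals.append(float(v))
    tvals = np.asarray(tvals)
    svals = np.asarray(svals)
    cols = np.asarray(cols)
    avals = np.asarray(avals)

    n_c = len(usable)

    def unpack(p):
        return p[0], p[1], p[2:]

    def model(p):
        alpha0, ts0, tsc = unpack(p)
        kill = np.zeros_like(tvals)
        sel = cols >= 0
        kill[sel] = tsc[cols[sel]] ** 2
        return alpha0 * np.exp(_LN2 * tvals * (ts0 - svals * kill))

    def resid(p):
        return model(p) - avals

    def jac(p):
        alpha0, ts0, tsc = unpack(p)
        m = model(p)
        J = np.zeros((len(avals), 2 + n_c))
        J[:, 0] = m / alpha0
        J[:, 1] = m * _LN2 * tvals
        sel = np.flatnonzero(cols >= 0)
        J[sel, 2 + cols[sel]] = -m[sel] * _LN2 * tvals[sel] * 2.0 * tsc[cols[sel]]
        return J

    x0 = np.concatenate([[alpha0_0, ts0_0], tsc_0])
    sol = least_squares(resid, x0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        warnings.warn(f"growth fit did not converge: {sol.message}",
                      ConvergenceWarning, stacklevel=2)
    alpha0, ts0, tsc = unpack(sol.x)
    if ts0 <= 0:
        raise DegenerateGrowthError(
            "untreated series shows no net growth; growth-based statistics undefined"
        )
    T0_hat = 1.0 / ts0
    dof = max(len(avals) - len(sol.x), 1)
    residual_sd = math.sqrt(2.0 * sol.cost / dof)

    I = len(pre.concentrations)
    inv_Tc = np.full(I, np.nan)
    Tdagger = np.full(I, np.nan)
    censored = np.zeros(I, dtype=bool)
    for c in usable:
        j = col_pos[c]
        kill = tsc[j] ** 2
        inv_Tc[c - 1] = ts0 - kill
        with np.errstate(divide="ignore"):
            Tdagger[c - 1] = np.inf if kill == 0 else 1.0 / kill
    # concentrations floored out of the joint fit: the floor only bounds the
    # decay, so report the least-steep rate consistent with it, flagged censored
    for c in drug_cols:
        if c in usable or int(table[c].notna().sum()) == 0:
            continue
        col = table[c].to_numpy(dtype=float)
        ok = ok_table[c].to_numpy(dtype=bool)
        if ok.any():
            t_ref, a_ref = times[ok][0], col[ok][0]
        else:
            t_ref, a_ref = 0.0, alpha0
        t_fl = times[np.isfinite(col) & ~ok][-1]
        if t_fl <= t_ref:
            continue
        rate = (math.log2(pre.floor) - math.log2(a_ref)) / (t_fl - t_ref)
        inv_Tc[c - 1] = rate
        Tdagger[c - 1] = 1.0 / (ts0 - rate) if ts0 > rate else math.inf
        censored[c - 1] = True

    return GrowthFit(
        alpha0=float(alpha0),
        T0_hat=float(T0_hat),
        Tdagger_hat=Tdagger,
        inv_Tc=inv_Tc,
        concentrations=np.asarray(pre.concentrations, dtype=float),
        times_used=times,
        residual_sd=residual_sd,
        censored=censored,
    )
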