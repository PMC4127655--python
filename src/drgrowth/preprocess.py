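"""Model-based pre-processing of raw plate absorbance.

Each well absorbance is modelled as

    Y_ktil = delta_kt * alpha_ti + beta_kt + eps_ktil,

where ``delta_kt`` is a multiplicative inter-plate effect, ``beta_kt`` the
additive plate background (pinned by the medium-only background wells, whose
mean is ``beta_kt`` alone), ``alpha_ti`` the summarised absorbance for
concentration index ``i`` at exposure time ``t``, and the technical error is
heteroscedastic: ``eps ~ N(0, |mean|**(2*xi) * sigma**2)``.

Fitting alternates closed-form weighted least-squares updates of the bilinear
mean parameters (a Gauss-Seidel sweep over alpha, beta and delta blocks, which
monotonically decreases the weighted residual sum of squares) with
profile-maximum-likelihood updates of the variance pair (xi, sigma), i.e. an
iteratively reweighted scheme.  The delta * alpha product is only identified
up to a per-time scale; the constraint is configurable (geometric mean of
delta equal to 1 at each time, or delta = 1 on the first replicate's plate).
Downstream growth-rate ratios do not depend on the constraint in the absence
of noise.

Outlier rejection standardises residuals by the fitted heteroscedastic SD
``|mean|**xi * sigma``, drops wells beyond a threshold (default 3 SD), refits,
and repeats (default twice).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .plates import RawPlateSet

__all__ = [
    "PreprocessedAbsorbance",
    "ConvergenceWarning",
    "fit_plate_model",
    "preprocess",
    "colour_correction_from_background_plates",
    "DEFAULT_FLOOR",
]

DEFAULT_FLOOR = 0.025
_MEAN_CLIP = 1e-6  # |fitted| floor inside weights and the variance likelihood
_XI_MAX = 5.0


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PreprocessedAbsorbance:
    """Result of the plate-model fit.

    ``alpha`` is a (time x concentration-index) table of summarised absorbance
    estimates, floored at ``floor``; ``floored`` marks entries at the floor and
    NaN entries mark concentrations whose wells were all rejected as outliers.
    ``fitted`` holds the per-record fitted means of the accepted model (NaN for
    records excluded as outliers), which together with (xi, sigma) defines the
    generative model used by the parametric bootstrap.
    """

    alpha: pd.DataFrame
    delta: pd.Series
    beta: pd.Series
    xi: float
    sigma: float
    outlier_mask: np.ndarray
    floor: float
    records: pd.DataFrame
    fitted: np.ndarray
    concentrations: np.ndarray
    converged: bool = True
    floored: pd.DataFrame = field(default=None)

    @property
    def times(self) -> np.ndarray:
        return self.alpha.index.to_numpy(dtype=float)

    def alpha_at(self, time: float) -> pd.Series:
        """Summarised absorbance per concentration index at one exposure time."""
        idx = np.flatnonzero(np.isclose(self.alpha.index.to_numpy(dtype=float), time))
        if idx.size == 0:
            raise KeyError(f"no pre-processed absorbance at time {time}")
        return self.alpha.iloc[idx[0]]

    def start_values(self) -> dict:
        """Parameter dictionary usable to warm-start a refit (e.g. bootstrap)."""
        alpha = {
            (t, int(i)): float(v)
            for t, row in self.alpha.iterrows()
            for i, v in row.items()
            if np.isfinite(v)
        }
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "delta": {k: float(v) for k, v in self.delta.items()},
            "alpha": alpha,
            "xi": self.xi,
            "sigma": self.sigma,
        }

    def standardized_residuals(self) -> np.ndarray:
        """Residuals of accepted records divided by their fitted SD ``|m|**xi * sigma``."""
        keep = ~self.outlier_mask
        m = self.fitted[keep]
        r = self.records["absorbance"].to_numpy(dtype=float)[keep] - m
        sd = np.maximum(np.abs(m), _MEAN_CLIP) ** self.xi * max(self.sigma, 1e-300)
        return r / sd


def _design(records: pd.DataFrame):
    """Integer codes for plates (replicate, time), alpha groups (time, conc_index)."""
    y = records["absorbance"].to_numpy(dtype=float)
    plate_key = list(zip(records["replicate"], records["time_h"]))
    plate_codes, plate_index = pd.factorize(pd.Index(plate_key), sort=True)
    is_cell = ~records["is_background"].to_numpy(dtype=bool)
    alpha_key = [
        (t, i) for t, i in zip(records["time_h"], records["conc_index"])
    ]
    if is_cell.any():
        alpha_codes_all, alpha_index = pd.factorize(
            pd.Index(alpha_key)[is_cell], sort=True
        )
    else:
        alpha_codes_all, alpha_index = np.array([], dtype=int), []
    alpha_codes = np.full(len(records), -1, dtype=int)
    alpha_codes[is_cell] = alpha_codes_all
    plate_time = np.asarray([t for (_, t) in plate_index], dtype=float)
    alpha_time = np.asarray([t for (t, _) in alpha_index], dtype=float)
    return y, plate_codes, plate_index, plate_time, is_cell, alpha_codes, alpha_index, alpha_time


def _fit_core(records: pd.DataFrame, delta_constraint: str, tol: float, max_iter: int,
              start: dict | None = None):
    """IRLS fit of the plate model on the given (already filtered) records.

    ``start`` may carry warm-start values (``beta``/``delta`` per plate key,
    ``alpha`` per (time, conc_index) key, ``xi``, ``sigma``) from a previous
    fit on a superset of the records.
    """
    (
        y,
        plate,
        plate_index,
        plate_time,
        is_cell,
        acode,
        alpha_index,
        alpha_time,
    ) = _design(records)
    n_plates = len(plate_index)
    n_alpha = len(alpha_index)
    n = len(y)
    if n_plates == 0:
        raise ValueError("no records to fit")

    # starting values: beta from background-well means, delta = 1, alpha from
    # background-corrected means, homoscedastic weights
    bg = ~is_cell
    beta = np.zeros(n_plates)
    for p in range(n_plates):
        sel = bg & (plate == p)
        beta[p] = y[sel].mean() if sel.any() else 0.0
    delta = np.ones(n_plates)
    alpha = np.zeros(max(n_alpha, 1))
    if n_alpha:
        resid0 = y - beta[plate]
        num = np.bincount(acode[is_cell], resid0[is_cell], minlength=n_alpha)
        cnt = np.bincount(acode[is_cell], minlength=n_alpha)
        alpha = num / np.maximum(cnt, 1)
    xi, sigma = 0.0, 1.0
    w = np.ones(n)
    if start is not None:
        beta = np.array([start["beta"].get(key, b) for key, b in zip(plate_index, beta)])
        delta = np.array([start["delta"].get(key, d) for key, d in zip(plate_index, delta)])
        alpha = np.array(
            [start["alpha"].get(key, a) for key, a in zip(alpha_index, alpha)]
        ) if n_alpha else alpha
        xi, sigma = start.get("xi", 0.0), start.get("sigma", 1.0)

    cell_idx = np.flatnonzero(is_cell)
    ac = acode[cell_idx]
    pc = plate[cell_idx]
    yc = y[cell_idx]

    time_groups = [
        (np.flatnonzero(np.isclose(plate_time, t)), np.flatnonzero(np.isclose(alpha_time, t)))
        for t in np.unique(plate_time)
    ]

    def fitted_with(beta_, delta_, alpha_):
        m = beta_[plate].copy()
        if n_alpha:
            m[cell_idx] += delta_[pc] * alpha_[ac]
        return m

    if start is not None:
        w = np.maximum(np.abs(fitted_with(beta, delta, alpha)), _MEAN_CLIP) ** (-2.0 * xi)

    def fitted_means():
        return fitted_with(beta, delta, alpha)

    def normalise_scale():
        # resolve the delta*alpha scale indeterminacy per exposure time
        for pt, at in time_groups:
            if at.size == 0:
                continue
            if delta_constraint == "geomean":
                g = math.exp(np.mean(np.log(np.abs(delta[pt]))))
            elif delta_constraint == "first":
                g = abs(delta[pt][0])
            else:
                raise ValueError(f"unknown delta constraint {delta_constraint!r}")
            if g <= 0 or not np.isfinite(g):
                raise ValueError("singular design: plate effect collapsed to zero")
            delta[pt] /= g
            alpha[at] *= g

    converged = False
    prev = None
    p_dim = 2 * n_plates + n_alpha  # [beta, delta, alpha]

    def mean_step():
        # Gauss-Newton on the bilinear mean (three nonzeros per Jacobian row);
        # the per-time delta*alpha gauge freedom makes the normal matrix
        # singular, so the minimum-norm step is taken and the gauge re-fixed.
        nonlocal beta, delta, alpha
        if n_alpha == 0:
            num = np.bincount(plate, w * y, minlength=n_plates)
            den = np.bincount(plate, w, minlength=n_plates)
            beta[:] = num / np.maximum(den, 1e-300)
            return
        wc = w[cell_idx]
        for _gn in range(60):
            m = fitted_means()
            r = y - m
            # normal equations J'WJ assembled blockwise (3 nonzeros per row);
            # a tiny ridge regularises the gauge direction
            aa, dd = alpha[ac], delta[pc]
            A = np.zeros((p_dim, p_dim))
            i_b, i_d, i_a = (
                np.arange(n_plates),
                n_plates + np.arange(n_plates),
                2 * n_plates + np.arange(n_alpha),
            )
            A[i_b, i_b] = np.bincount(plate, w, minlength=n_plates)
            A[i_d, i_d] = np.bincount(pc, wc * aa**2, minlength=n_plates)
            A[i_a, i_a] = np.bincount(ac, wc * dd**2, minlength=n_alpha)
            bd = np.bincount(pc, wc * aa, minlength=n_plates)
            A[i_b, i_d] = bd
            A[i_d, i_b] = bd
            ba = np.zeros((n_plates, n_alpha))
            np.add.at(ba, (pc, ac), wc * dd)
            A[:n_plates, 2 * n_plates :] = ba
            A[2 * n_plates :, :n_plates] = ba.T
            da = np.zeros((n_plates, n_alpha))
            np.add.at(da, (pc, ac), wc * aa * dd)
            A[n_plates : 2 * n_plates, 2 * n_plates :] = da
            A[2 * n_plates :, n_plates : 2 * n_plates] = da.T
            rhs = np.concatenate(
                [
                    np.bincount(plate, w * r, minlength=n_plates),
                    np.bincount(pc, wc * aa * r[cell_idx], minlength=n_plates),
                    np.bincount(ac, wc * dd * r[cell_idx], minlength=n_alpha),
                ]
            )
            ridge = 1e-9 * max(float(np.max(np.diagonal(A))), 1e-12)
            A[np.arange(p_dim), np.arange(p_dim)] += ridge
            try:
                step = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError as err:
                raise ValueError("singular design: plate model not identifiable") from err
            sse = float(np.sum(w * r**2))
            damp = 1.0
            for _half in range(30):
                beta_n = beta + damp * step[:n_plates]
                delta_n = delta + damp * step[n_plates : 2 * n_plates]
                alpha_n = alpha + damp * step[2 * n_plates :]
                sse_n = float(np.sum(w * (y - fitted_with(beta_n, delta_n, alpha_n)) ** 2))
                if sse_n <= sse * (1 + 1e-14):
                    break
                damp *= 0.5
            beta, delta, alpha = beta_n, delta_n, alpha_n
            normalise_scale()
            if sse - sse_n < 1e-13 * max(sse, 1e-30) or damp * float(
                np.max(np.abs(step))
            ) < 1e-12 * max(float(np.max(np.abs(y))), 1.0):
                break

    for _ in range(max_iter):
        mean_step()

        # --- profile-ML update of (xi, sigma) on the residuals
        m = fitted_means()
        r = y - m
        mabs = np.maximum(np.abs(m), _MEAN_CLIP)
        msq = r**2
        if msq.mean() < 1e-22:  # (near-)noiseless data: variance law unidentified
            sigma = math.sqrt(max(msq.mean(), 0.0))
            xi = 0.0
            converged = True
            break
        logm = np.log(mabs)

        def nll(x):
            return 2.0 * x * logm.mean() + math.log(np.mean(msq * mabs ** (-2.0 * x)))

        res = minimize_scalar(nll, bounds=(0.0, _XI_MAX), method="bounded",
                              options={"xatol": 1e-10})
        xi = float(res.x)
        sigma = math.sqrt(float(np.mean(msq * mabs ** (-2.0 * xi))))
        w = mabs ** (-2.0 * xi)

        state = np.concatenate([beta, delta, alpha[:n_alpha], [xi, sigma]])
        if prev is not None:
            if np.max(np.abs(state - prev) / np.maximum(np.abs(prev), 1e-8)) < tol:
                converged = True
                break
        prev = state

    return beta, delta, alpha[:n_alpha], xi, sigma, plate_index, alpha_index, fitted_means(), converged


def _assemble(
    raw_records: pd.DataFrame,
    concentrations: np.ndarray,
    keep: np.ndarray,
    fit,
    floor: float,
) -> PreprocessedAbsorbance:
    beta, delta, alpha, xi, sigma, plate_index, alpha_index, fitted_keep, converged = fit
    fitted = np.full(len(raw_records), np.nan)
    fitted[keep] = fitted_keep

    cells_full = raw_records[~raw_records["is_background"]]
    times = sorted({t for (t, _) in alpha_index} | set(cells_full["time_h"]))
    indices = sorted(
        {int(i) for (_, i) in alpha_index} | {int(i) for i in cells_full["conc_index"]}
    )
    table = pd.DataFrame(np.nan, index=pd.Index(times, name="time_h"),
                         columns=pd.Index(indices, name="conc_index"))
    for (t, i), a in zip(alpha_index, alpha):
        table.loc[t, int(i)] = a
    floored = table <= floor * (1 + 1e-9)
    table = table.clip(lower=floor)
    # concentrations whose wells were all rejected stay NaN in the table
    present = raw_records.loc[keep]
    cells_all = raw_records[~raw_records["is_background"]]
    for (t, i) in {(t, int(i)) for t, i in
                   zip(cells_all["time_h"], cells_all["conc_index"])}:
        here = (present["time_h"] == t) & (present["conc_index"] == i) & (~present["is_background"])
        if not here.any():
            warnings.warn(
                f"all wells at time {t}, concentration index {i} were flagged as outliers; "
                "alpha reported as missing",
                ConvergenceWarning,
                stacklevel=3,
            )
            if t in table.index and i in table.columns:
                table.loc[t, i] = np.nan

    midx = pd.MultiIndex.from_tuples(list(plate_index), names=["replicate", "time_h"])
    return PreprocessedAbsorbance(
        alpha=table,
        delta=pd.Series(delta, index=midx, name="delta"),
        beta=pd.Series(beta, index=midx, name="beta"),
        xi=xi,
        sigma=sigma,
        outlier_mask=~keep,
        floor=floor,
        records=raw_records,
        fitted=fitted,
        concentrations=np.asarray(concentrations, dtype=float),
        converged=converged,
        floored=floored,
    )


def fit_plate_model(
    raw: RawPlateSet | pd.DataFrame,
    *,
    floor: float = DEFAULT_FLOOR,
    delta_constraint: str = "geomean",
    tol: float = 1e-8,
    max_iter: int = 50,
    start: dict | None = None,
) -> PreprocessedAbsorbance:
    """Fit the heteroscedastic plate model without outlier rejection."""
    if isinstance(raw, RawPlateSet):
        records, conc = raw.records, raw.concentrations
    else:
        records, conc = raw.reset_index(drop=True), np.array([])
    keep = np.ones(len(records), dtype=bool)
    fit = _fit_core(records, delta_constraint, tol, max_iter, start=start)
    if not fit[-1]:
        warnings.warn("plate-model IRLS did not converge; returning last iterate",
                      ConvergenceWarning, stacklevel=2)
    return _assemble(records, conc, keep, fit, floor)


def preprocess(
    raw: RawPlateSet,
    sd_threshold: float = 3.0,
    max_outlier_iter: int = 2,
    *,
    floor: float = DEFAULT_FLOOR,
    delta_constraint: str = "geomean",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> PreprocessedAbsorbance:
    """Full pre-processing: IRLS fit with iterated outlier rejection.

    Fit, flag records whose standardised residual exceeds ``sd_threshold``,
    refit on the survivors, and repeat up to ``max_outlier_iter`` detection
    passes (or until no new outlier appears).
    """
    records = raw.records
    keep = np.ones(len(records), dtype=bool)
    fit = _fit_core(records, delta_constraint, tol, max_iter)
    data_scale = np.max(np.abs(records["absorbance"].to_numpy(dtype=float)))
    for _ in range(max_outlier_iter):
        beta, delta, alpha, xi, sigma, plate_index, alpha_index, fitted, _ = fit
        if sigma <= 1e-10 * max(data_scale, 1.0):
            break  # residual scale at numerical noise: nothing to flag
        y = records.loc[keep, "absorbance"].to_numpy(dtype=float)
        sd = np.maximum(np.abs(fitted), _MEAN_CLIP) ** xi * sigma
        z = (y - fitted) / sd
        new_out = np.abs(z) > sd_threshold
        if not new_out.any():
            break
        idx = np.flatnonzero(keep)[new_out]
        keep[idx] = False
        if not keep.any():
            raise ValueError("all records rejected as outliers")
        warm = {
            "beta": dict(zip(plate_index, beta)),
            "delta": dict(zip(plate_index, delta)),
            "alpha": dict(zip(alpha_index, alpha)),
            "xi": xi,
            "sigma": sigma,
        }
        fit = _fit_core(records.loc[keep], delta_constraint, tol, max_iter, start=warm)
    if not fit[-1]:
        warnings.warn("plate-model IRLS did not converge; returning last iterate",
                      ConvergenceWarning, stacklevel=2)
    return _assemble(records, raw.concentrations, keep, fit, floor)


def colour_correction_from_background_plates(
    cell_free: RawPlateSet | pd.DataFrame, **fit_kwargs
):
    """Estimate drug-colour excess absorbance from cell-free plates.

    The cell-free plates follow the same layout as assay plates (drug dilution
    wells plus drug-free background wells) but contain no cells, so the fitted
    ``alpha`` values measure the absorbance caused by the drug itself at each
    concentration.  Values are averaged over times and floored at zero.
    """
    from .plates import ColourCorrection

    fit_kwargs.setdefault("floor", 0.0)
    pre = fit_plate_model(cell_free, **fit_kwargs)
    mean_alpha = pre.alpha.mean(axis=0, skipna=True)
    values = {int(i): float(v) for i, v in mean_alpha.items() if int(i) != 0}
    return ColourCorrection(values=values)
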