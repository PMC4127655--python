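"""Synthetic dose-response experiments and the bias/SD/MSE simulation study.

Nine reference cell-line models span doubling times of 15, 30 and 60 hours
and GI50 values on an even log10 grid from -8.40 to -6.60 (spacing 0.225).
The kill rate is the five-parameter logistic of :mod:`drgrowth.models` with
a = 2, b = 1/5 per hour, d = 0, f = 1 and the midpoint calibrated per cell
line to its GI50.  Cell counts follow the closed-form growth/decay solution
with N0 = 10,000 cells per well; absorbance is cell count times
gamma = 0.4/10,000 OD per cell, perturbed per plate by a multiplicative
lognormal effect delta and an additive lognormal background beta and per well
by heteroscedastic Gaussian technical noise -- the magnitudes estimated from
a B-cell lymphoma/myeloma doxorubicin screen.

Each simulated experiment comprises ``K`` replicate plate sets; each plate
carries 18 drug concentrations in triplicate plus three untreated controls
and three medium-only background wells, and the assay is read at effective
times 1, 25, 49 and 73 h (reagent added at 24 h intervals, incubated 2 h, the
count referred to the interval midpoint).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .curves import g_curve
from .growthfit import fit_growth
from .plates import RawPlateSet
from .preprocess import ConvergenceWarning, preprocess
from .summaries import g_summaries

__all__ = [
    "CellLineModel",
    "NoiseParameters",
    "StudyDesign",
    "reference_models",
    "simulate_plate_set",
    "run_simulation_study",
    "DEFAULT_LADDER",
]

# 18 equally spaced log10 concentrations bracketing every reference statistic
# (-8.40 .. -5.90) with ~0.2-0.3 decades of margin; fine enough that linear
# interpolation of the curve resolves each crossing beyond two decimals.
DEFAULT_LADDER = np.linspace(-8.6, -5.6, 18)


@dataclass(frozen=True)
class CellLineModel:
    """Ground-truth generator parameters for one simulated cell line."""

    name: str
    T0: float
    kill: models.LogisticKillRate
    N0: float = 10_000.0

    def summaries(self) -> models.AnalyticSummaries:
        return models.analytic_summaries(self.T0, self.kill)

    def net_rate(self, c) -> np.ndarray:
        """True net growth rate 1/Tc at log10 concentration(s) c."""
        return 1.0 / self.T0 - models.kill_rate(c, self.kill)


@dataclass(frozen=True)
class NoiseParameters:
    """Noise magnitudes of the absorbance model (log-scale lognormal for plate effects)."""

    mu_beta: float = -0.8
    sigma_beta: float = 0.13
    mu_delta: float = 0.0
    sigma_delta: float = 0.38
    xi: float = 1.42
    sigma_eps: float = 0.074

    def __post_init__(self) -> None:
        if self.sigma_beta < 0 or self.sigma_delta < 0 or self.sigma_eps < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseParameters":
        return cls(sigma_beta=0.0, sigma_delta=0.0, sigma_eps=0.0)


@dataclass(frozen=True)
class StudyDesign:
    """Plate layout and timing of the simulated experiments."""

    concentrations: np.ndarray = field(default_factory=lambda: DEFAULT_LADDER.copy())
    wells_per_conc: int = 3
    control_wells: int = 3
    background_wells: int = 3
    times: tuple = (1.0, 25.0, 49.0, 73.0)  # effective: addition + t_inc/2
    gamma: float = 0.4 / 10_000.0
    K: int = 3

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if not np.all(np.diff(conc) > 0):
            raise ValueError("concentration ladder must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)


def reference_models(a: float = 2.0, b: float = 0.2, d: float = 0.0, f: float = 1.0):
    """The nine reference cell-line models (doubling time, calibrated kill curve)."""
    T0s = [60, 30, 15, 15, 30, 60, 15, 60, 30]
    gi50s = [-8.40 + 0.225 * j for j in range(9)]
    return [
        CellLineModel(
            name=f"Cell {j + 1}",
            T0=float(T0),
            kill=models.calibrate_midpoint("GI50", gi50, T0, a=a, b=b, d=d, f=f),
        )
        for j, (T0, gi50) in enumerate(zip(T0s, gi50s))
    ]


def simulate_plate_set(
    model: CellLineModel,
    design: StudyDesign = StudyDesign(),
    noise: NoiseParameters = NoiseParameters(),
    seed: int | np.random.Generator | None = None,
    times=None,
) -> RawPlateSet:
    """Generate the absorbance records of one simulated experiment.

    One plate per (replicate k, exposure time); optionally restricted to a
    subset of exposure times.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = design.times if times is None else tuple(times)
    conc = design.concentrations
    I = len(conc)
    kill = models.kill_rate(conc, model.kill)
    rows = []
    for k in range(1, design.K + 1):
        for t in times:
            if noise.sigma_delta > 0 or noise.mu_delta != 0:
                delta = math.exp(rng.normal(noise.mu_delta, noise.sigma_delta))
            else:
                delta = 1.0
            beta = math.exp(rng.normal(noise.mu_beta, noise.sigma_beta))
            # cell signal per concentration index (0 = untreated control)
            signal = np.empty(I + 1)
            signal[0] = design.gamma * model.N0 * 2.0 ** (t / model.T0)
            signal[1:] = design.gamma * model.N0 * 2.0 ** (t * (1.0 / model.T0 - kill))
            well = 0
            for i in range(0, I + 1):
                n_wells = design.control_wells if i == 0 else design.wells_per_conc
                for _ in range(n_wells):
                    well += 1
                    rows.append(
                        (model.name, k, t, np.nan if i == 0 else conc[i - 1], i, well,
                         delta * signal[i] + beta, False, i == 0)
                    )
            for _ in range(design.background_wells):
                well += 1
                rows.append((model.name, k, t, np.nan, 0, well, beta, True, False))
    rec = pd.DataFrame(
        rows,
        columns=["cell_line", "replicate", "time_h", "conc", "conc_index", "well",
                 "absorbance", "is_background", "is_control"],
    )
    mean = rec["absorbance"].to_numpy()
    sd = np.abs(mean) ** noise.xi * noise.sigma_eps
    rec["absorbance"] = mean + rng.normal(0.0, 1.0, size=len(rec)) * sd
    return RawPlateSet(rec, conc)


def _analyse(raw: RawPlateSet, **pre_kwargs):
    pre = preprocess(raw, **pre_kwargs)
    fit = fit_growth(pre)
    return g_summaries(g_curve(fit))


def run_simulation_study(
    cell_models=None,
    design: StudyDesign = StudyDesign(),
    noise: NoiseParameters = NoiseParameters(),
    n_reps: int = 300,
    times=(25.0, 49.0, 73.0),
    seed: int | None = None,
    initial_time: float = 1.0,
    **pre_kwargs,
) -> pd.DataFrame:
    """Bias/SD/MSE of the G-model statistics over repeated simulated experiments.

    Each exposure time is analysed as a two-time-point experiment pairing the
    initial read (1 h) with that time.  Estimates are compared against the
    analytic truths of each cell-line model; censored estimates enter the
    aggregates at their endpoint values and are counted separately.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    cell_models = reference_models() if cell_models is None else cell_models
    rng = np.random.default_rng(seed)
    stat_names = ["GI50", "TGI", "LC48"]
    out_rows = []
    for model in cell_models:
        truth = model.summaries()
        truths = dict(zip(stat_names, truth))
        est = {(t, s): [] for t in times for s in stat_names}
        ncens = {(t, s): 0 for t in times for s in stat_names}
        failures = {t: 0 for t in times}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(n_reps):
                raw = simulate_plate_set(
                    model, design, noise, rng, times=(initial_time, *times)
                )
                for t in times:
                    try:
                        summ = _analyse(raw.subset_times([initial_time, t]), **pre_kwargs)
                    except Exception:
                        failures[t] += 1
                        continue
                    for s in stat_names:
                        est[(t, s)].append(summ.stats[s].value)
                        if summ.stats[s].censored:
                            ncens[(t, s)] += 1
        for t in times:
            row = {"cell_line": model.name, "T0": model.T0, "time": t,
                   "n": n_reps - failures[t], "failures": failures[t]}
            for s in stat_names:
                e = np.asarray(est[(t, s)])
                row[f"bias_{s}"] = float(np.mean(e - truths[s]))
                row[f"sd_{s}"] = float(np.std(e, ddof=1))
                row[f"mse_{s}"] = float(np.mean((e - truths[s]) ** 2))
                row[f"censored_{s}"] = ncens[(t, s)]
            out_rows.append(row)
    return pd.DataFrame(out_rows)
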