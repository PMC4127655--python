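"""Closed-form cell growth/decay mathematics and the three dose-response models.

An untreated cell line grows exponentially with doubling time ``T0``.  A drug at
concentration ``c`` kills (or arrests) cells at an exponential rate with
concentration-dependent halving time ``Tc_dagger``, so the metabolising cell
count follows

    N(t, c) = N0 * 2**(t/T0 - t/Tc_dagger) = N0 * 2**(t/Tc),

with the *net* doubling-or-halving time ``Tc`` given by
``1/Tc = 1/T0 - 1/Tc_dagger``.  Three dose-response models summarise such an
experiment at exposure time ``t``:

* ``G`` -- growth-rate based, ``T0/Tc`` while the count still grows and
  ``1/Tc`` on the decay branch.  ``G`` does not depend on ``t``.
* ``D`` -- net-difference based (the NCI60 convention), relative change in
  ``N - N0`` against the untreated change.
* ``R`` -- relative count, ``N(t,c)/N(t,0) = 2**(-t/Tc_dagger)``.

``d_to_g`` and ``r_to_g`` are the exact transformations recovering the
time-free ``G`` value from a ``D`` or ``R`` value observed at a known exposure
time, given the doubling time.  The five-parameter logistic ``kill_rate`` is
the concentration -> ``1/Tc_dagger`` mapping used by the simulator.

Concentrations are log10 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GrowthParameters",
    "LogisticKillRate",
    "AnalyticSummaries",
    "net_rate",
    "cell_count",
    "g_model",
    "d_model",
    "r_model",
    "d_to_g",
    "r_to_g",
    "kill_rate",
    "invert_kill_rate",
    "required_rate",
    "calibrate_midpoint",
    "analytic_summaries",
]

LC_REFERENCE_HOURS = 48.0


@dataclass(frozen=True)
class GrowthParameters:
    """Ground-truth growth/kill parameters for one concentration.

    Parameters
    ----------
    N0 : float
        Seeded cell count, > 0.
    T0 : float
        Untreated doubling time in hours, > 0.
    Tdagger : float
        Drug-induced kill halving time in hours, > 0.  ``math.inf`` denotes
        "no drug effect" and is the canonical untreated representation.
    """

    N0: float
    T0: float
    Tdagger: float = math.inf

    def __post_init__(self) -> None:
        if not self.N0 > 0:
            raise ValueError(f"N0 must be positive, got {self.N0}")
        if not self.T0 > 0:
            raise ValueError(f"T0 must be positive, got {self.T0}")
        if not self.Tdagger > 0:
            raise ValueError(f"Tdagger must be positive, got {self.Tdagger}")


def net_rate(p: GrowthParameters) -> float:
    """Net growth rate ``1/Tc = 1/T0 - 1/Tdagger`` (per hour; 0 at TGI)."""
    return 1.0 / p.T0 - (0.0 if math.isinf(p.Tdagger) else 1.0 / p.Tdagger)


def cell_count(t: float, p: GrowthParameters) -> float:
    """Metabolising cell count ``N0 * 2**(t * (1/T0 - 1/Tdagger))`` at ``t >= 0`` hours."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    return p.N0 * 2.0 ** (t * net_rate(p))


def g_model(T0, inv_Tc):
    """Time-free growth-based dose-response value.

    ``T0 * inv_Tc`` (unitless, in [0, 1] for growth between none and untreated)
    while the net rate is non-negative, and the raw negative rate ``inv_Tc``
    (per hour) on the decay branch.  Continuous (= 0) at total growth
    inhibition.
    """
    T0 = np.asarray(T0, dtype=float)
    if np.any(T0 <= 0):
        raise ValueError("T0 must be positive")
    inv_Tc = np.asarray(inv_Tc, dtype=float)
    out = np.where(inv_Tc >= 0, T0 * inv_Tc, inv_Tc)
    return out[()] if out.ndim == 0 else out


def d_model(t: float, T0: float, inv_Tc) -> np.ndarray | float:
    """Difference-based dose-response value at exposure time ``t`` hours.

    ``(2**(t*inv_Tc) - 1) / (2**(t/T0) - 1)`` on the growth branch
    (``inv_Tc >= 0``), ``2**(t*inv_Tc) - 1`` on the decay branch.
    """
    if t <= 0:
        raise ValueError(f"d_model requires t > 0, got {t}")
    if T0 <= 0:
        raise ValueError("T0 must be positive")
    inv_Tc = np.asarray(inv_Tc, dtype=float)
    change = np.expm1(t * inv_Tc * math.log(2.0))
    out = np.where(inv_Tc >= 0, change / math.expm1(t / T0 * math.log(2.0)), change)
    return out[()] if out.ndim == 0 else out


def r_model(t: float, Tdagger) -> np.ndarray | float:
    """Relative-count dose-response value ``2**(-t/Tdagger)``; 1 when untreated."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    Tdagger = np.asarray(Tdagger, dtype=float)
    if np.any(Tdagger <= 0):
        raise ValueError("Tdagger must be positive")
    with np.errstate(divide="ignore"):
        out = 2.0 ** (-t / Tdagger)
    return out[()] if out.ndim == 0 else out


def d_to_g(D, t: float, T0: float) -> np.ndarray | float:
    """Exact inverse of :func:`d_model`: recover the time-free ``G`` value.

    ``(T0/t) * log2((2**(t/T0) - 1) * D + 1)`` for ``D >= 0`` and
    ``(1/t) * log2(D + 1)`` otherwise.  Requires ``D > -1``.
    """
    if t <= 0 or T0 <= 0:
        raise ValueError("t and T0 must be positive")
    D = np.asarray(D, dtype=float)
    if np.any(D <= -1):
        raise ValueError("d_to_g requires D > -1")
    with np.errstate(invalid="ignore", divide="ignore"):
        growth = (T0 / t) * np.log2(np.expm1(t / T0 * math.log(2.0)) * D + 1.0)
        decay = np.log2(D + 1.0) / t
        out = np.where(D >= 0, growth, decay)
    return out[()] if out.ndim == 0 else out


def r_to_g(R, t: float, T0: float) -> np.ndarray | float:
    """Exact inverse of :func:`r_model` (with the net-rate identity): ``G`` from ``R``.

    Growth branch (``N >= N0``, i.e. ``t/T0 >= -log2 R``):
    ``1 + (T0/t) * log2 R``; decay branch: ``1/T0 + (1/t) * log2 R``.
    Requires ``0 < R <= 1`` up to noise (any ``R > 0`` is accepted).
    """
    if t <= 0 or T0 <= 0:
        raise ValueError("t and T0 must be positive")
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("r_to_g requires R > 0")
    log2R = np.log2(R)
    growth = 1.0 + (T0 / t) * log2R
    decay = 1.0 / T0 + log2R / t
    out = np.where(t / T0 + log2R >= 0, growth, decay)
    return out[()] if out.ndim == 0 else out


@dataclass(frozen=True)
class LogisticKillRate:
    """Five-parameter logistic kill-rate curve ``1/Tc_dagger`` as a function of log10 c.

    ``kill(c) = b - (b - d) / (1 + exp(a*(c - e)))**f`` -- rises from the
    baseline ``d`` (per hour, usually 0) at low concentration to the maximal
    kill rate ``b`` (per hour) at high concentration, with steepness ``a``
    (per log10 unit), midpoint ``e`` (log10 concentration) and asymmetry ``f``.
    """

    a: float
    b: float
    d: float
    e: float
    f: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("steepness a must be positive")
        if not self.f > 0:
            raise ValueError("asymmetry f must be positive")
        if not (self.b > self.d >= 0):
            raise ValueError("kill-rate bounds must satisfy b > d >= 0")


def kill_rate(c, k: LogisticKillRate) -> np.ndarray | float:
    """Evaluate the logistic kill rate ``1/Tc_dagger(c)`` (per hour)."""
    c = np.asarray(c, dtype=float)
    out = k.b - (k.b - k.d) / (1.0 + np.exp(k.a * (c - k.e))) ** k.f
    return out[()] if out.ndim == 0 else out


def invert_kill_rate(rate: float, k: LogisticKillRate) -> float:
    """log10 concentration at which the kill rate equals ``rate``.

    Closed form for every asymmetry ``f > 0``.  Returns ``nan`` when the
    rate is not attained (outside ``(d, b)``), i.e. the statistic is censored.
    """
    if not (k.d < rate < k.b):
        return math.nan
    return k.e + math.log(((k.b - k.d) / (k.b - rate)) ** (1.0 / k.f) - 1.0) / k.a


def required_rate(stat: str, T0: float, lc_t: float = LC_REFERENCE_HOURS) -> float:
    """Kill rate ``1/Tc_dagger`` at which a named summary statistic is attained.

    ``GI50`` (or any ``GIx``): the growth branch value ``G = (100-x)/100``
    needs ``kill = x/(100*T0)``; ``TGI``: ``kill = 1/T0``; ``LC48`` (or
    ``LC<t>``): the decay branch ``G = -1/t`` needs ``kill = 1/T0 + 1/t``.
    """
    if T0 <= 0:
        raise ValueError("T0 must be positive")
    stat = stat.upper()
    if stat == "TGI":
        return 1.0 / T0
    if stat.startswith("GI"):
        x = float(stat[2:]) if len(stat) > 2 else 50.0
        if not 0 < x < 100:
            raise ValueError(f"GI percentage must be in (0, 100), got {x}")
        return x / (100.0 * T0)
    if stat.startswith("LC"):
        t = float(stat[2:]) if len(stat) > 2 else lc_t
        if t <= 0:
            raise ValueError("LC reference time must be positive")
        return 1.0 / T0 + 1.0 / t
    raise ValueError(f"unknown summary statistic {stat!r}")


def calibrate_midpoint(
    stat: str,
    target_c: float,
    T0: float,
    a: float = 2.0,
    b: float = 0.2,
    d: float = 0.0,
    f: float = 1.0,
) -> LogisticKillRate:
    """Solve the logistic midpoint ``e`` so that ``stat`` is attained at ``target_c``.

    The required kill rate must lie strictly inside ``(d, b)``; otherwise the
    target is infeasible for these shape parameters.
    """
    rate = required_rate(stat, T0)
    if not (d < rate < b):
        raise ValueError(
            f"{stat} at T0={T0} needs kill rate {rate:.4g}, outside the attainable ({d}, {b})"
        )
    # invert_kill_rate with e=0 gives the offset of the target from the midpoint
    offset = math.log(((b - d) / (b - rate)) ** (1.0 / f) - 1.0) / a
    return LogisticKillRate(a=a, b=b, d=d, e=target_c - offset, f=f)


class AnalyticSummaries(NamedTuple):
    gi50: float
    tgi: float
    lc48: float


def analytic_summaries(T0: float, k: LogisticKillRate, lc_t: float = LC_REFERENCE_HOURS) -> AnalyticSummaries:
    """Closed-form GI50, TGI and LC48 (log10 concentration) for a kill-rate curve.

    Statistics whose required kill rate is not attainable come back as ``nan``
    (censored).  When all three are finite they are strictly ordered
    GI50 < TGI < LC48 because the kill rate increases with concentration.
    """
    return AnalyticSummaries(
        gi50=invert_kill_rate(required_rate("GI50", T0), k),
        tgi=invert_kill_rate(required_rate("TGI", T0), k),
        lc48=invert_kill_rate(required_rate(f"LC{lc_t:g}", T0), k),
    )
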