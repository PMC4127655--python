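"""Shared fixtures: reference cell-line models and exact (noise-free) inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import drgrowth as dg
from drgrowth.preprocess import PreprocessedAbsorbance

# Reference characteristics of the nine simulated cell lines: doubling time
# and the printed two-decimal GI50 / TGI / LC48 values.
REFERENCE_LINES = [
    (60, -8.40, -8.03, -7.57),
    (30, -8.18, -7.78, -7.47),
    (15, -7.95, -7.49, -7.27),
    (15, -7.72, -7.27, -7.05),
    (30, -7.50, -7.11, -6.80),
    (60, -7.28, -6.91, -6.44),
    (15, -7.05, -6.59, -6.37),
    (60, -6.82, -6.46, -5.99),
    (30, -6.60, -6.21, -5.90),
]


@pytest.fixture(scope="session")
def cell_models():
    return dg.reference_models()


def exact_preprocessed(
    model: dg.CellLineModel,
    times,
    concentrations=None,
    gamma: float = 0.4 / 10_000.0,
    floor: float = 0.025,
) -> PreprocessedAbsorbance:
    """Noise-free summarised absorbance straight from the growth law.

    Builds the alpha table the pre-processing stage would return on exact
    data, bypassing the plate fit; used to oracle-test curve estimation.
    """
    conc = np.asarray(
        dg.simulate.DEFAULT_LADDER if concentrations is None else concentrations,
        dtype=float,
    )
    rates = model.net_rate(conc)
    cols = pd.Index(range(len(conc) + 1), name="conc_index")
    alpha = pd.DataFrame(index=pd.Index(list(times), name="time_h"), columns=cols,
                         dtype=float)
    for t in times:
        alpha.loc[t, 0] = gamma * model.N0 * 2.0 ** (t / model.T0)
        alpha.loc[t, 1:] = gamma * model.N0 * 2.0 ** (t * rates)
    floored = alpha < floor
    alpha = alpha.clip(lower=floor)
    plates = pd.MultiIndex.from_tuples([(1, t) for t in times],
                                       names=["replicate", "time_h"])
    return PreprocessedAbsorbance(
        alpha=alpha,
        delta=pd.Series(1.0, index=plates, name="delta"),
        beta=pd.Series(0.45, index=plates, name="beta"),
        xi=0.0,
        sigma=0.0,
        outlier_mask=np.zeros(0, dtype=bool),
        floor=floor,
        records=pd.DataFrame(),
        fitted=np.zeros(0),
        concentrations=conc,
        floored=floored,
    )


@pytest.fixture(scope="session")
def noiseless_raw_cell5():
    """One exact simulated experiment (cell line 5, times 1 h and 49 h)."""
    model = dg.reference_models()[4]
    return dg.simulate_plate_set(
        model, dg.StudyDesign(), dg.NoiseParameters.noiseless(), seed=0,
        times=(1.0, 49.0),
    )
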