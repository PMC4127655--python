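"""Model-based pre-processing: recovery, outlier rejection, variance law."""

import numpy as np
import pandas as pd
import pytest

import drgrowth as dg
from drgrowth.plates import ColourCorrection, RawPlateSet
from drgrowth.preprocess import fit_plate_model, preprocess


def build_plates(
    alpha, deltas, betas, time=49.0, wells=3, n_bg=3, rng=None, xi=1.42, sigma=0.0
):
    """Hand-rolled plate records Y = delta*alpha + beta (+ heteroscedastic noise)."""
    rows = []
    I = len(alpha) - 1  # alpha[0] is the untreated control
    conc = np.linspace(-8.0, -6.0, I)
    for k, (d, b) in enumerate(zip(deltas, betas), start=1):
        w = 0
        for i in range(I + 1):
            for _ in range(wells):
                w += 1
                rows.append((
                    "line", k, time, np.nan if i == 0 else conc[i - 1], i, w,
                    d * alpha[i] + b, False, i == 0,
                ))
        for _ in range(n_bg):
            w += 1
            rows.append(("line", k, time, np.nan, 0, w, b, True, False))
    rec = pd.DataFrame(rows, columns=[
        "cell_line", "replicate", "time_h", "conc", "conc_index", "well",
        "absorbance", "is_background", "is_control"])
    if rng is not None and sigma > 0:
        m = rec["absorbance"].to_numpy()
        rec["absorbance"] = m + rng.normal(0, 1, len(rec)) * np.abs(m) ** xi * sigma
    return RawPlateSet(rec, conc)


ALPHA = np.array([0.62, 0.55, 0.40, 0.21, 0.12, 0.05])


class TestFitRecovery:
    def test_noiseless_parameters_recovered(self):
        """Exact data from the plate model reproduce delta, beta, alpha."""
        deltas, betas = [0.8, 1.25], [0.3, 0.4]  # geometric mean of delta = 1
        raw = build_plates(ALPHA, deltas, betas)
        pre = fit_plate_model(raw, floor=0.0)
        assert pre.beta.to_numpy() == pytest.approx(betas, abs=1e-8)
        assert pre.delta.to_numpy() == pytest.approx(deltas, abs=1e-8)
        assert pre.alpha.iloc[0].to_numpy() == pytest.approx(ALPHA, abs=1e-8)
        assert pre.sigma < 1e-8

    def test_first_plate_constraint(self):
        """With the first-plate gauge the raw generating scale is recovered."""
        deltas, betas = [1.0, 1.3], [0.3, 0.4]
        raw = build_plates(ALPHA, deltas, betas)
        pre = fit_plate_model(raw, floor=0.0, delta_constraint="first")
        assert pre.delta.to_numpy() == pytest.approx(deltas, abs=1e-8)
        assert pre.alpha.iloc[0].to_numpy() == pytest.approx(ALPHA, abs=1e-8)

    def test_single_plate_matches_group_means(self):
        """One plate is a saturated design: estimates are the plain group means."""
        rng = np.random.default_rng(5)
        raw = build_plates(ALPHA, [1.0], [0.35], rng=rng, sigma=0.05)
        pre = fit_plate_model(raw, floor=0.0)
        rec = raw.records
        bg_mean = rec.loc[rec.is_background, "absorbance"].mean()
        assert pre.beta.iloc[0] == pytest.approx(bg_mean, abs=1e-7)
        for i in range(len(ALPHA)):
            cells = rec[(rec.conc_index == i) & ~rec.is_background]
            assert pre.delta.iloc[0] * pre.alpha.iloc[0, i] + pre.beta.iloc[0] == (
                pytest.approx(cells["absorbance"].mean(), abs=1e-7)
            )

    def test_background_only_records(self):
        """Cell-free, drug-free records: alpha empty, beta = background mean."""
        rec = pd.DataFrame({
            "cell_line": "x", "replicate": 1, "time_h": 49.0, "conc": np.nan,
            "conc_index": 0, "well": range(6),
            "absorbance": [0.41, 0.43, 0.44, 0.40, 0.42, 0.46],
            "is_background": True, "is_control": False,
        })
        pre = fit_plate_model(rec)
        assert pre.alpha.empty
        assert pre.beta.iloc[0] == pytest.approx(np.mean(rec["absorbance"]))

    def test_variance_parameters_recovered(self):
        """xi and sigma estimates concentrate around the generating values."""
        rng = np.random.default_rng(11)
        xis, sigmas = [], []
        for _ in range(30):
            raw = build_plates(ALPHA * 4, [0.9, 1.1, 1.0], [0.3, 0.4, 0.5],
                               wells=6, rng=rng, xi=1.42, sigma=0.074)
            pre = fit_plate_model(raw, floor=0.0)
            xis.append(pre.xi)
            sigmas.append(pre.sigma)
        assert np.mean(xis) == pytest.approx(1.42, abs=0.25)
        assert np.mean(sigmas) == pytest.approx(0.074, rel=0.25)

    def test_xi_accuracy_improves_with_well_count(self):
        """More wells pin the variance exponent more tightly."""
        errs = {}
        for wells in (2, 8):
            rng = np.random.default_rng(13)
            e = []
            for _ in range(25):
                raw = build_plates(ALPHA * 4, [0.9, 1.1, 1.0], [0.3, 0.4, 0.5],
                                   wells=wells, rng=rng, xi=1.42, sigma=0.074)
                e.append(abs(fit_plate_model(raw, floor=0.0).xi - 1.42))
            errs[wells] = np.mean(e)
        assert errs[8] < errs[2]

    def test_alpha_unbiased_under_noise(self):
        """Monte-Carlo mean of alpha-hat matches the generating alpha."""
        rng = np.random.default_rng(21)
        acc = []
        for _ in range(80):
            raw = build_plates(ALPHA, [0.9, 1.1], [0.3, 0.4], rng=rng, sigma=0.05)
            pre = fit_plate_model(raw, floor=0.0)
            acc.append(pre.alpha.iloc[0].to_numpy(dtype=float))
        mean_alpha = np.mean(acc, axis=0)
        se = np.std(acc, axis=0) / np.sqrt(len(acc))
        assert np.all(np.abs(mean_alpha - ALPHA) < 4 * se + 1e-3)


class TestOutlierRejection:
    def test_clean_data_has_empty_mask(self):
        raw = build_plates(ALPHA, [0.8, 1.25], [0.3, 0.4])
        pre = preprocess(raw)
        assert pre.outlier_mask.sum() == 0

    def test_single_spike_flagged_and_alpha_recovered(self):
        raw = build_plates(ALPHA, [0.8, 1.25], [0.3, 0.4])
        clean = preprocess(raw, floor=0.0).alpha.iloc[0].to_numpy(dtype=float)
        rec = raw.records.copy()
        spike_row = rec.index[(rec.conc_index == 2) & ~rec.is_background][0]
        rec.loc[spike_row, "absorbance"] += 10.0
        pre = preprocess(RawPlateSet(rec, raw.concentrations), floor=0.0)
        assert pre.outlier_mask.sum() == 1
        assert pre.outlier_mask[spike_row]
        assert pre.alpha.iloc[0].to_numpy(dtype=float) == pytest.approx(clean, abs=1e-3)

    def test_two_control_spikes_flagged(self):
        """Analogue of two aberrant untreated-control wells on one plate."""
        raw = build_plates(ALPHA, [0.8, 1.25], [0.3, 0.4])
        rec = raw.records.copy()
        controls = rec.index[(rec.replicate == 2) & rec.is_control][:2]
        rec.loc[controls, "absorbance"] += 5.0
        pre = preprocess(RawPlateSet(rec, raw.concentrations))
        assert set(np.flatnonzero(pre.outlier_mask)) == set(controls)

    def test_all_wells_of_concentration_flagged_reports_missing(self):
        """Irreconcilable wells for one concentration leave its alpha missing."""
        alpha = np.linspace(0.7, 0.05, 11)
        raw = build_plates(alpha, [1.0], [0.35], wells=2)
        rec = raw.records.copy()
        rows = rec.index[(rec.conc_index == 3) & ~rec.is_background]
        rec.loc[rows, "absorbance"] += [4.0, -4.0]
        with pytest.warns(UserWarning, match="outlier"):
            pre = preprocess(RawPlateSet(rec, raw.concentrations))
        assert pre.outlier_mask[rows].all()
        assert np.isnan(pre.alpha.iloc[0, 3])


class TestModelAdequacy:
    @pytest.fixture(scope="class")
    def noisy_fit(self):
        model = dg.reference_models()[4]
        raw = dg.simulate_plate_set(model, dg.StudyDesign(), seed=99, times=(1.0, 49.0))
        return preprocess(raw)

    def test_standardized_residuals_unit_variance(self, noisy_fit):
        z = noisy_fit.standardized_residuals()
        assert np.var(z) == pytest.approx(1.0, abs=0.25)

    def test_no_trend_against_fitted(self, noisy_fit):
        """Slope of standardized residuals on fitted means is insignificant."""
        z = noisy_fit.standardized_residuals()
        m = noisy_fit.fitted[~noisy_fit.outlier_mask]
        X = np.column_stack([np.ones_like(m), m])
        coef, res, *_ = np.linalg.lstsq(X, z, rcond=None)
        dof = len(z) - 2
        s2 = res[0] / dof
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(coef[1]) < 2 * se

    def test_scale_equivariance(self, noisy_fit):
        """Rescaling all absorbances rescales the fit and leaves G-stats alone."""
        kappa = 3.7
        rec = noisy_fit.records.copy()
        rec["absorbance"] *= kappa
        raw = RawPlateSet(rec, noisy_fit.concentrations)
        pre2 = preprocess(raw, floor=0.025 * kappa)
        assert pre2.beta.to_numpy() == pytest.approx(
            kappa * noisy_fit.beta.to_numpy(), rel=1e-5
        )
        assert pre2.alpha.to_numpy() == pytest.approx(
            kappa * noisy_fit.alpha.to_numpy(), rel=1e-5
        )
        assert pre2.xi == pytest.approx(noisy_fit.xi, abs=1e-4)
        assert pre2.sigma == pytest.approx(
            noisy_fit.sigma * kappa ** (1 - noisy_fit.xi), rel=1e-3
        )
        s1 = dg.g_summaries(dg.g_curve(dg.fit_growth(noisy_fit)))
        s2 = dg.g_summaries(dg.g_curve(dg.fit_growth(pre2)))
        for name in s1.stats:
            assert s2.stats[name].value == pytest.approx(s1.stats[name].value, abs=1e-5)


class TestColourCorrection:
    def test_zero_correction_is_identity(self, noiseless_raw_cell5):
        cc = ColourCorrection({i: 0.0 for i in range(1, 19)})
        out = dg.apply_colour_correction(noiseless_raw_cell5, cc)
        assert np.allclose(out.records["absorbance"], noiseless_raw_cell5.records["absorbance"])

    def test_subtraction_applies_to_drugged_wells_only(self):
        raw = build_plates(ALPHA, [1.0], [0.35])
        cc = ColourCorrection({i: 0.15 for i in range(1, len(ALPHA))})
        out = dg.apply_colour_correction(raw, cc)
        drugged = ~raw.records.is_background & ~raw.records.is_control
        assert np.allclose(
            out.records.loc[drugged, "absorbance"],
            raw.records.loc[drugged, "absorbance"] - 0.15,
        )
        assert np.allclose(
            out.records.loc[~drugged, "absorbance"],
            raw.records.loc[~drugged, "absorbance"],
        )

    def test_missing_index_raises(self):
        raw = build_plates(ALPHA, [1.0], [0.35])
        with pytest.raises(ValueError, match="missing"):
            dg.apply_colour_correction(raw, ColourCorrection({1: 0.1}))

    def test_corrections_recovered_from_cell_free_plates(self):
        """Fitting cell-free plates returns the drug-colour absorbance curve."""
        colour = np.array([0.0, 0.01, 0.03, 0.08, 0.16, 0.30])  # index 0 unused
        rng = np.random.default_rng(3)
        raw = build_plates(colour, [1.0, 1.0], [0.40, 0.44], rng=rng,
                           xi=0.0, sigma=0.005)
        cc = dg.colour_correction_from_background_plates(raw)
        got = np.array([cc.values[i] for i in range(1, 6)])
        assert got == pytest.approx(colour[1:], abs=0.01)


def test_plate_set_invariants():
    raw = build_plates(ALPHA, [1.0], [0.35])
    rec = raw.records
    with pytest.raises(ValueError, match="background"):
        RawPlateSet(rec[~rec.is_background], raw.concentrations)
    with pytest.raises(ValueError, match="increasing"):
        RawPlateSet(rec, raw.concentrations[::-1])
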