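import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from propellerevo.foldbiophys import (CalibrationCurve, DataError,
                                      DenaturationDataset, FitError,
                                      classify_concentration_dependence,
                                      fit_calibration, fit_thermal_melt,
                                      fit_three_state, fit_two_state,
                                      invert_calibration, select_model,
                                      three_state_signal, trait_pca,
                                      two_state_signal, two_state_transform)
from propellerevo.synthetic import (CurveSpec, simulate_curve,
                                    three_state_spec, two_state_spec)


class TestCalibration:
    def test_printed_curve_recovered_from_noiseless_points(self):
        true = CalibrationCurve(A=0.843, K=5.00, h=0.483)
        x = np.geomspace(0.05, 100, 25)
        fit = fit_calibration(x, true.predict(x))
        assert abs(fit.A - 0.843) < 0.005
        assert abs(fit.K - 5.00) < 0.005
        assert abs(fit.h - 0.483) < 0.005

    def test_half_saturation_at_K(self):
        c = CalibrationCurve(A=0.8, K=4.0, h=0.5)
        assert c.predict(4.0) == pytest.approx(0.4)

    def test_monotone_increasing(self):
        c = CalibrationCurve(A=0.843, K=5.0, h=0.483)
        y = c.predict(np.geomspace(0.01, 500, 200))
        assert np.all(np.diff(y) > 0)

    def test_inversion_roundtrip(self):
        c = CalibrationCurve(A=0.843, K=5.0, h=0.483)
        for x in np.geomspace(0.05, 100, 20):
            back = invert_calibration(float(c.predict(x)), c)
            assert abs(back - x) / x < 1e-9

    @pytest.mark.parametrize("y", [0.0, -0.1, 0.843, 1.0])
    def test_out_of_range_absorbance(self, y):
        c = CalibrationCurve(A=0.843, K=5.0, h=0.483)
        with pytest.raises(ValueError):
            invert_calibration(y, c)

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([-1, 1, 2, 3, 4], [0.1] * 5)


class TestTwoState:
    def test_recovers_generating_midpoint(self):
        data = simulate_curve(two_state_spec(cm=2.0, m=2.0, seed=5,
                                             noise_sd=0.01))
        fit = fit_two_state(data)
        assert abs(fit.Cm[0] - 2.0) < 0.05
        assert fit.apparent

    def test_native_fraction_half_at_midpoint(self):
        data = simulate_curve(two_state_spec(seed=3))
        fit = fit_two_state(data)
        f = fit.fractions(np.array([fit.Cm[0]]))
        assert f[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_fitted_m_monotone_in_generating_m(self):
        fitted = []
        for m in (1.0, 2.0, 4.0):
            data = simulate_curve(two_state_spec(m=m, seed=9))
            fitted.append(fit_two_state(data).m[0])
        assert fitted[0] < fitted[1] < fitted[2]

    def test_flat_data_raises(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 6, 61)
        y = 0.5 + rng.normal(0, 0.01, 61)
        with pytest.raises(FitError):
            fit_two_state(DenaturationDataset(x, y))

    def test_rescaling_invariance(self):
        data = simulate_curve(two_state_spec(seed=13))
        fit1 = fit_two_state(data)
        fit2 = fit_two_state(DenaturationDataset(data.x, data.y * 1000.0))
        assert fit1.Cm[0] == pytest.approx(fit2.Cm[0], abs=1e-6)
        assert fit1.m[0] == pytest.approx(fit2.m[0], abs=1e-6)


class TestThreeState:
    def test_recovers_inter_inflection_interval(self):
        data = simulate_curve(three_state_spec(1.2, seed=43))
        fit = fit_three_state(data)
        assert abs(fit.delta_Cm - 1.2) < 0.1
        assert fit.Cm[1] > fit.Cm[0]

    def test_fractions_sum_to_one(self):
        data = simulate_curve(three_state_spec(0.8, seed=2))
        fit = fit_three_state(data)
        fr = fit.fractions(np.linspace(0, 6, 101))
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fr >= 0)

    def test_intermediate_peak_between_midpoints(self):
        data = simulate_curve(three_state_spec(1.0, seed=4))
        fit = fit_three_state(data)
        x = np.linspace(0, 6, 2001)
        fr = fit.fractions(x)
        peak = x[np.argmax(fr[:, 1])]
        assert fit.Cm[0] < peak < fit.Cm[1]

    def test_delta_cm_median_error_small(self):
        """Median |dCm error| < 0.1 M over seeded 1%-noise replicates at
        the canonical 61-point gradient."""
        errs = []
        for seed in range(15):
            data = simulate_curve(three_state_spec(1.2, seed=seed,
                                                   n_points=61))
            errs.append(abs(fit_three_state(data).delta_Cm - 1.2))
        assert np.median(errs) < 0.1

    def test_rescaling_invariance(self):
        data = simulate_curve(three_state_spec(1.2, seed=6))
        fit1 = fit_three_state(data)
        fit2 = fit_three_state(DenaturationDataset(data.x, data.y * 50.0))
        assert fit1.delta_Cm == pytest.approx(fit2.delta_Cm, abs=1e-5)

    def test_collapse_as_intermediate_depopulates(self):
        """Pushing the intermediate's transition out of range collapses the
        three-state signal onto a pure two-state curve; the residual
        shrinks monotonically as the intermediate population vanishes."""
        x = np.linspace(0, 6, 301)
        devs = []
        for cm2 in (2.5, 6.0, 9.0, 12.0):
            # with the I=D step pushed to +infinity the intermediate plays
            # the role of the apparent denatured state
            y3 = three_state_signal(x, 2.0, cm2, 2.0, 2.0,
                                    1.0, 0.0, 0.5, 0.2, 0.0)
            y2 = two_state_signal(x, 2.0, 2.0, 1.0, 0.0, 0.5, 0.0)
            devs.append(np.abs(y3 - y2).max())
        assert devs[0] > devs[1] > devs[2] > devs[3]
        assert devs[-1] < 1e-6

    def test_baseline_limits(self):
        data = simulate_curve(three_state_spec(1.2, seed=8))
        fit = fit_three_state(data)
        b = fit.baselines
        assert fit.predict(np.array([-50.0]))[0] == pytest.approx(
            b["a_n"] + b["b_n"] * -50.0, abs=1e-6)
        assert fit.predict(np.array([60.0]))[0] == pytest.approx(
            b["a_d"] + b["b_d"] * 60.0, abs=1e-6)


class TestSelectModel:
    def test_two_state_data_selects_two(self):
        picks = [select_model(simulate_curve(
            two_state_spec(seed=s, n_points=61))) for s in range(40)]
        assert np.mean(np.array(picks) == 2) >= 0.95

    def test_three_state_data_selects_three(self):
        picks = [select_model(simulate_curve(
            three_state_spec(1.2, seed=s, n_points=61)))
            for s in range(40)]
        assert np.mean(np.array(picks) == 3) >= 0.95

    def test_flat_line_propagates_fit_error(self):
        x = np.linspace(0, 6, 61)
        y = np.full(61, 0.5)
        with pytest.raises(FitError):
            select_model(DenaturationDataset(x, y))


class TestTwoStateTransform:
    def test_identical_series_unity(self):
        s = np.linspace(1, 2, 20)
        assert np.allclose(two_state_transform(s, s), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            two_state_transform([1, 2], [1, 2, 3])

    def test_zero_denominator(self):
        with pytest.raises(DataError):
            two_state_transform([1.0, 2.0], [1.0, 0.0])

    def test_ratio_fit_gives_shallower_pseudo_m(self):
        """Collapsing three-state wavelength series to a single ratio and
        refitting two-state yields a pseudo-m below the m of matched
        genuinely two-state data."""
        x = np.linspace(0, 6, 121)
        # native-wavelength channel falls, denatured channel rises
        native = three_state_signal(x, 2.0, 3.2, 3.0, 3.0,
                                    1.0, 0.0, 0.55, 0.2, 0.0)
        denat = three_state_signal(x, 2.0, 3.2, 3.0, 3.0,
                                   0.3, 0.0, 0.7, 1.0, 0.0)
        ratio = two_state_transform(native, denat)
        pseudo = fit_two_state(DenaturationDataset(x, ratio))
        true_two = simulate_curve(two_state_spec(cm=pseudo.Cm[0], m=3.0,
                                                 seed=1, noise_sd=0.0))
        direct = fit_two_state(true_two)
        assert pseudo.m[0] < direct.m[0]


class TestThermalMelt:
    def test_recovers_midpoint(self):
        spec = CurveSpec("melt", dict(tm=60.0, width=2.0, a_n=1.0,
                                      b_n=-0.002, a_d=0.1, b_d=0.001),
                         noise_sd=0.01, n_points=71, x_range=(20, 90),
                         seed=7)
        fit = fit_thermal_melt(simulate_curve(spec))
        assert not fit.censored
        assert abs(fit.tm - 60.0) < 1.0

    def test_incomplete_transition_censored(self):
        spec = CurveSpec("melt", dict(tm=96.0, width=2.0, a_n=1.0,
                                      b_n=-0.002, a_d=0.1, b_d=0.001),
                         noise_sd=0.01, n_points=71, x_range=(20, 90),
                         seed=7)
        fit = fit_thermal_melt(simulate_curve(spec))
        assert fit.censored
        assert fit.tm is None
        assert fit.censored_bound >= 90.0

    def test_flat_data_censored_not_spurious(self):
        rng = np.random.default_rng(1)
        t = np.linspace(20, 90, 71)
        y = 1.0 + rng.normal(0, 0.01, 71)
        fit = fit_thermal_melt(DenaturationDataset(t, y))
        assert fit.censored

    def test_shift_equivariance(self):
        """Raising the generating Tm by 21 C shifts the fitted Tm by
        21 +/- 1 C."""
        fits = []
        for tm in (55.0, 76.0):
            spec = CurveSpec("melt", dict(tm=tm, width=2.0, a_n=1.0,
                                          b_n=-0.002, a_d=0.1, b_d=0.001),
                             noise_sd=0.01, n_points=91, x_range=(15, 95),
                             seed=17)
            fits.append(fit_thermal_melt(simulate_curve(spec),
                                         upper_limit=95.0).tm)
        assert fits[1] - fits[0] == pytest.approx(21.0, abs=1.0)


class TestConcentrationDependence:
    def test_bell_by_definition(self):
        assert classify_concentration_dependence(
            [1, 5, 25], [0.4, 1.0, 0.5]) == "bell"

    def test_monotone_decreasing(self):
        assert classify_concentration_dependence(
            [1, 5, 25, 100], [1.0, 0.7, 0.4, 0.2]) == "monotone_decreasing"

    def test_flat(self):
        assert classify_concentration_dependence(
            [1, 5, 25, 100], [0.95, 1.0, 0.97, 0.99]) == "flat"

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            classify_concentration_dependence([1, 5], [1.0, 0.5])

    def test_mechanistic_toy_models(self):
        """Oligomer folding (assembly ~ c, misfolding ~ c^2) is bell
        shaped; monomer folding (misfolding ~ c) decreases monotonically."""
        c = np.array([0.5, 2.0, 8.0, 32.0, 128.0])
        oligo = (c / (1 + 0.05 * c)) / (1 + 0.002 * c ** 2)
        mono = 1.0 / (1 + 0.05 * c)
        assert classify_concentration_dependence(c, oligo / oligo.max()) \
            == "bell"
        assert classify_concentration_dependence(c, mono / mono.max()) \
            == "monotone_decreasing"


class TestTraitPCA:
    @staticmethod
    def table(n=8, seed=0):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        df = pd.DataFrame({
            "binding_capacity": latent + 0.1 * rng.normal(size=n),
            "soluble": latent + 0.1 * rng.normal(size=n),
            "insoluble": rng.normal(size=n),
            "affinity": rng.normal(size=n),
            "thermal_stability": rng.normal(size=n),
            "folding_efficiency": rng.normal(size=n),
        })
        return df

    def test_variance_fraction_matches_dense_eigensolver(self):
        df = self.table()
        res = trait_pca(df)
        ref = np.linalg.eigvalsh(df.corr().to_numpy())[::-1]
        assert np.allclose(res.eigenvalues, ref, atol=1e-10)
        assert res.variance_fractions[0] == pytest.approx(
            ref[0] / ref.sum())
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_identity_correlation_uniform_fractions(self):
        rng = np.random.default_rng(3)
        n = 4000
        df = pd.DataFrame(rng.normal(size=(n, 6)),
                          columns=list("abcdef"))
        res = trait_pca(df)
        assert np.allclose(res.variance_fractions, 1 / 6, atol=0.05)

    def test_correlated_pair_loads_together(self):
        res = trait_pca(self.table())
        pc1 = res.loadings["PC1"]
        assert np.sign(pc1["binding_capacity"]) == np.sign(pc1["soluble"])
        assert abs(pc1["binding_capacity"]) > 0.4

    def test_constant_column_error_names_trait(self):
        df = self.table()
        df["affinity"] = 1.0
        with pytest.raises(ValueError, match="affinity"):
            trait_pca(df)

    def test_requires_three_complete_cases(self):
        df = self.table(n=5)
        df.iloc[:3, 0] = np.nan
        with pytest.raises(ValueError):
            trait_pca(df)


def test_simulated_curve_noise_free_is_exact():
    spec = three_state_spec(1.2, seed=0, noise_sd=0.0)
    data = simulate_curve(spec)
    y = three_state_signal(data.x, 2.0, 3.2, 6.0, 6.0, 1.0, -0.02, 0.45,
                           0.15, 0.01)
    assert np.abs(data.y - y).max() < 1e-12
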