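"""Glass-transition estimators and WLF shifting."""

import warnings

import numpy as np
import pytest

from lignotherm.exceptions import (
    DegenerateFitError,
    DomainError,
    NoCrossoverError,
    NoOnsetError,
)
from lignotherm.synthetic import DilatometryParams, gen_dilatometry
from lignotherm.thermal import (
    DilatometryCurve,
    GlassTransitionModel,
    WlfParams,
    bilinear_tg,
    fit_hyperbolic,
    h0,
    hyperbolic_density,
    hyperbolic_tg,
    invert_wlf,
    onset_tg,
    wlf_log_shift,
)


def _two_line_curve():
    """Noise-free curve from rho_low = 1.40 - 2e-4 T (below 400 K) and
    rho_high = 1.60 - 6e-4 T (above); analytic crossover at 500 K."""
    T = np.arange(150.0, 551.0, 25.0)
    rho = np.where(T <= 400.0, 1.40 - 2e-4 * T, 1.60 - 6e-4 * T)
    return DilatometryCurve(T=T, rho=rho)


class TestBilinear:
    def test_analytic_intersection(self):
        est = bilinear_tg(_two_line_curve())
        assert est.Tg == pytest.approx(500.0, abs=1e-9)
        assert est.method == "bilinear"

    def test_parallel_lines_rejected(self):
        T = np.arange(150.0, 551.0, 25.0)
        curve = DilatometryCurve(T=T, rho=1.40 - 2e-4 * T)
        with pytest.raises(NoCrossoverError):
            bilinear_tg(curve)

    def test_range_outside_data(self):
        T = np.arange(300.0, 551.0, 25.0)
        curve = DilatometryCurve(T=T, rho=1.40 - 2e-4 * T)
        with pytest.raises(DomainError):
            bilinear_tg(curve, low_range=(150.0, 225.0))

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(DomainError):
            bilinear_tg(_two_line_curve(), low_range=(150.0, 400.0),
                        high_range=(300.0, 550.0))

    def test_warns_when_tg_near_range_edge(self):
        curve = gen_dilatometry(DilatometryParams(Tg_true=420.0,
                                                  noise_sd=0.0, n_replicas=1))
        with pytest.warns(UserWarning, match="100 K"):
            bilinear_tg(curve)

    def test_synthetic_recovery(self):
        """Median bilinear error over seeded synthetic curves stays within
        the +/- 15 K band at the stated noise."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            errs = []
            for seed in range(30):
                curve = gen_dilatometry(DilatometryParams(
                    Tg_true=420.0, breadth=40.0, noise_sd=0.002,
                    n_replicas=5, seed=seed))
                errs.append(bilinear_tg(curve).Tg - 420.0)
        assert abs(np.median(errs)) <= 15.0

    def test_bootstrap_uncertainty_positive(self):
        curve = gen_dilatometry(DilatometryParams(Tg_true=420.0, seed=4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            est = bilinear_tg(curve, uncertainty="bootstrap", seed=1)
        assert est.uncertainty > 0


class TestHyperbolicFit:
    TRUE = dict(rho0=1.30, a=3e-4, b=-2e-4, T0=430.0, c=4.0)

    def _exact_curve(self):
        T = np.arange(150.0, 551.0, 10.0)
        rho = hyperbolic_density(T, **self.TRUE)
        return DilatometryCurve(T=T, rho=rho)

    def test_self_consistent_recovery(self):
        """Parameters of exactly model-generated data recovered to 1e-3."""
        fit = fit_hyperbolic(self._exact_curve())
        for name, true in self.TRUE.items():
            assert getattr(fit, name) == pytest.approx(true, rel=1e-3)

    def test_value_at_t0_identity(self):
        """rho(T0) = rho0 + b e^(c/2) since H0(T0) = -e^(c/2)."""
        fit = fit_hyperbolic(self._exact_curve())
        expected = fit.rho0 + fit.b * np.exp(fit.c / 2.0)
        assert fit.predict(fit.T0) == pytest.approx(expected, rel=1e-12)
        assert h0(fit.T0, fit.T0, fit.c) == pytest.approx(
            -np.exp(fit.c / 2.0))

    def test_pure_line_flags_degenerate(self):
        T = np.arange(150.0, 551.0, 25.0)
        fit = fit_hyperbolic(DilatometryCurve(T=T, rho=1.40 - 2e-4 * T))
        assert fit.degenerate
        with pytest.raises(DegenerateFitError):
            hyperbolic_tg(fit, (150.0, 550.0))

    def test_too_few_points(self):
        T = np.array([150.0, 250.0, 350.0, 450.0, 550.0])
        with pytest.raises(DomainError):
            fit_hyperbolic(DilatometryCurve(T=T, rho=np.full(5, 1.2)))


class TestHyperbolicTg:
    def test_numeric_scan_equals_t0(self):
        """|rho''| is extremal at T0 for this family (0.1 K scan)."""
        T = np.arange(150.0, 551.0, 10.0)
        rho = hyperbolic_density(T, 1.30, 3e-4, -2e-4, 430.0, 4.0)
        fit = fit_hyperbolic(DilatometryCurve(T=T, rho=rho))
        est = hyperbolic_tg(fit, (150.0, 550.0))
        assert est.Tg == pytest.approx(430.0, abs=0.1)

    def test_translation_equivariance(self):
        p = DilatometryParams(Tg_true=420.0, seed=8)
        curve = gen_dilatometry(p)
        shifted = DilatometryCurve(T=curve.T + 50.0, rho=curve.rho,
                                   rho_sd=curve.rho_sd)
        fit = fit_hyperbolic(curve)
        fit_s = fit_hyperbolic(shifted)
        tg = hyperbolic_tg(fit, curve.span).Tg
        tg_s = hyperbolic_tg(fit_s, shifted.span).Tg
        assert tg_s - tg == pytest.approx(50.0, abs=0.2)

    def test_density_scaling_invariance(self):
        curve = gen_dilatometry(DilatometryParams(Tg_true=420.0, seed=8))
        scaled = DilatometryCurve(T=curve.T, rho=curve.rho * 1.7)
        tg = hyperbolic_tg(fit_hyperbolic(curve), curve.span).Tg
        tg_s = hyperbolic_tg(fit_hyperbolic(scaled), scaled.span).Tg
        assert tg_s == pytest.approx(tg, abs=0.2)


class TestOnset:
    def _fit_and_line(self, **kwargs):
        p = DilatometryParams(Tg_true=420.0, noise_sd=0.0, n_replicas=1,
                              **kwargs)
        curve = gen_dilatometry(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            bilinear = bilinear_tg(curve)
        return fit_hyperbolic(curve), bilinear, curve

    def test_identical_line_has_no_onset(self):
        T = np.arange(150.0, 551.0, 25.0)
        rho = 1.40 - 2e-4 * T
        fit = fit_hyperbolic(DilatometryCurve(T=T, rho=rho))
        with pytest.raises(NoOnsetError):
            onset_tg(fit, (-2e-4, 1.40), (150.0, 550.0))

    def test_matches_brute_force_grid_scan(self):
        """Onset equals an independent 0.1 K grid scan of the deviation."""
        fit, bilinear, curve = self._fit_and_line(slope_melt=-1.5e-3,
                                                  breadth=60.0)
        line = bilinear.diagnostics["low_line"]
        est = onset_tg(fit, line, curve.span, threshold_pct=2.0)
        grid = np.arange(curve.span[0], curve.span[1] + 0.05, 0.1)
        dev = np.abs(fit.predict(grid)
                     - (line["slope"] * grid + line["intercept"]))
        rel = dev / np.abs(line["slope"] * grid + line["intercept"])
        oracle = grid[np.argmax(rel > 0.02)]
        assert est.Tg == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_threshold(self):
        fit, bilinear, curve = self._fit_and_line(slope_melt=-1.5e-3,
                                                  breadth=60.0)
        line = bilinear.diagnostics["low_line"]
        previous = -np.inf
        for pct in (0.5, 1.0, 2.0, 3.0, 5.0):
            tg = onset_tg(fit, line, curve.span, threshold_pct=pct).Tg
            assert tg >= previous
            previous = tg

    def test_broad_transition_onset_below_bilinear(self):
        """For a broad transition the onset estimate reads below the bilinear
        crossover; for a narrow one it reads above."""
        fit, bilinear, curve = self._fit_and_line(slope_melt=-1.5e-3,
                                                  breadth=120.0)
        broad = onset_tg(fit, bilinear.diagnostics["low_line"], curve.span)
        assert broad.Tg < bilinear.Tg
        fit_n, bil_n, curve_n = self._fit_and_line(slope_melt=-1.5e-3,
                                                   breadth=15.0)
        narrow = onset_tg(fit_n, bil_n.diagnostics["low_line"], curve_n.span)
        assert narrow.Tg > bil_n.Tg


class TestWlf:
    def test_zero_offset_gives_zero_shift(self):
        assert wlf_log_shift(WlfParams(17.44, 51.6), 400.0, 400.0) == 0.0

    def test_direct_substitution(self):
        assert wlf_log_shift(WlfParams(10.0, 50.0), 450.0, 400.0) \
            == pytest.approx(5.0)

    def test_pole_rejected(self):
        with pytest.raises(DomainError):
            wlf_log_shift(WlfParams(10.0, 50.0), 350.0, 400.0)

    def test_invert_examples(self):
        assert invert_wlf(WlfParams(10.0, 50.0), 0.0) == 0.0
        assert invert_wlf(WlfParams(10.0, 50.0), 5.0) == pytest.approx(50.0)

    def test_invert_at_c1_rejected(self):
        with pytest.raises(DomainError):
            invert_wlf(WlfParams(10.0, 50.0), 10.0)

    def test_round_trip(self):
        p = WlfParams(17.44, 51.6)
        for dT in (-30.0, 5.0, 80.0):
            L = wlf_log_shift(p, 400.0 + dT, 400.0)
            assert invert_wlf(p, L) == pytest.approx(dT, abs=1e-9)

    def test_slower_cooling_shifts_tg_down(self):
        """Cooling slower than the reference rate gives a negative offset:
        the laboratory-rate Tg sits below the fast-quench estimate."""
        rate_ref = 2.5 / 1e-9  # K/s, stepwise-quench effective rate
        rate_lab = 10.0 / 60.0  # K/s (10 K/min)
        L = np.log10(rate_lab / rate_ref)
        dT = invert_wlf(WlfParams(17.44, 51.6), L)
        assert dT < 0


class TestGlassTransitionModel:
    def test_three_methods_and_summary(self):
        curve = gen_dilatometry(DilatometryParams(Tg_true=420.0, seed=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            results = GlassTransitionModel(curve).fit()
        assert set(results.estimates) == {"bilinear", "hyperbolic", "onset"}
        text = results.summary()
        assert "bilinear" in text and "hyperbolic" in text

    def test_plot_smoke(self):
        curve = gen_dilatometry(DilatometryParams(Tg_true=420.0, seed=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            results = GlassTransitionModel(curve).fit()
        ax = results.plot()
        assert ax.get_xlabel() == "T (K)"
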