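"""Forward models and capacity fitting for C3 and C4 CO2-response curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leafphys as lp
from conftest import make_curve


class TestForwardModels:
    def test_rubisco_limited_compensation_point(self, constants):
        # at ci = gammastar assimilation equals -Rd exactly
        assert lp.fvcb_ac(constants.gammastar, 100.0, 1.5) == pytest.approx(-1.5)
        assert lp.fvcb_aj(constants.gammastar, 150.0, 1.5) == pytest.approx(-1.5)

    def test_rubisco_limited_value(self):
        # 100*(300-42.75)/(300+710.4) - 1.5, with Km from the default constants
        assert lp.fvcb_ac(300.0, 100.0, 1.5) == pytest.approx(23.96, abs=0.02)

    def test_electron_transport_value(self):
        # 150*(1800-42.75)/(4*1800+8*42.75) - 1.5
        assert lp.fvcb_aj(1800.0, 150.0, 1.5) == pytest.approx(33.45, abs=0.01)

    def test_electron_transport_asymptote(self):
        # ci -> infinity gives J/4 - Rd
        assert lp.fvcb_aj(1e9, 150.0, 1.5) == pytest.approx(150 / 4 - 1.5, rel=1e-5)

    @given(st.floats(1.0, 2000.0), st.floats(1.0, 2000.0))
    @settings(max_examples=50, deadline=None)
    def test_rubisco_limited_monotone_in_ci(self, ci1, ci2):
        lo, hi = sorted((ci1, ci2))
        assert lp.fvcb_ac(lo, 100.0, 1.5) <= lp.fvcb_ac(hi, 100.0, 1.5) + 1e-12

    @given(st.floats(0.0, 3000.0))
    @settings(max_examples=50, deadline=None)
    def test_min_rate_below_both_limitations(self, ci):
        an = lp.fvcb_an(ci, 100.0, 180.0, 1.5)
        assert an <= lp.fvcb_ac(ci, 100.0, 1.5) + 1e-12
        assert an <= lp.fvcb_aj(ci, 180.0, 1.5) + 1e-12

    def test_pepc_half_saturation_and_value(self):
        assert lp.c4_pepc_limited(80.0, 110.0, 80.0, 2.0) == pytest.approx(110 / 2 - 2)
        # 110*40/120 - 2
        assert lp.c4_pepc_limited(40.0, 110.0, 80.0, 2.0) == pytest.approx(34.667, abs=1e-3)
        assert lp.c4_pepc_limited(1e9, 110.0, 80.0, 2.0) == pytest.approx(108.0, rel=1e-6)

    def test_nrh_intercept_and_theta_limit(self):
        assert lp.nrh(0.0, 0.5, 40.0, 0.7, offset=-2.0) == pytest.approx(-2.0)
        # theta -> 0 reproduces the rectangular hyperbola
        ci = np.linspace(1, 800, 40)
        phi, Asat = 0.5, 40.0
        rect = phi * ci * Asat / (phi * ci + Asat) - 2.0
        assert np.allclose(lp.nrh(ci, phi, Asat, 0.01, -2.0), rect, atol=0.25)

    def test_iwue(self):
        assert lp.compute_iwue(30.0, 0.3) == pytest.approx(100.0)
        assert lp.compute_iwue(0.0, 0.3) == 0.0
        with pytest.raises(ValueError):
            lp.compute_iwue(30.0, 0.0)


class TestBilinearFit:
    def test_noiseless_recovery(self, noiseless_c3_curve):
        fit = lp.fit_fvcb_bilinear(noiseless_c3_curve)
        assert fit.success
        assert fit.Vcmax == pytest.approx(100.0, rel=0.01)
        assert fit.Jmax == pytest.approx(180.0, rel=0.01)
        assert fit.Rd == pytest.approx(1.5, rel=0.01)
        ci = noiseless_c3_curve.ci
        assert ci.min() <= fit.transition_ci <= ci.max()

    def test_against_grid_search_oracle(self, c3_params):
        # exhaustive lattice search can never beat the bilinear SSE by more
        # than numerical slack, on small noisy instances
        rng = np.random.default_rng(0)
        for seed in range(5):
            curve = lp.generate_aci_c3(c3_params, noise_sd=0.4, seed=seed)
            fit = lp.fit_fvcb_bilinear(curve)
            oracle = _grid_search_sse(curve, n=30)
            assert fit.sse <= oracle + 1e-6

    def test_monte_carlo_recovery_and_vanishing_bias(self, c3_params):
        med_err = {}
        for sd in (0.0, 0.3, 0.6):
            errs = [abs(lp.fit_fvcb_bilinear(
                lp.generate_aci_c3(c3_params, noise_sd=sd, seed=s)).Vcmax - 100) / 100
                for s in range(60)]
            med_err[sd] = float(np.median(errs))
        assert med_err[0.3] <= 0.10
        # bias shrinks toward zero with the noise level
        assert med_err[0.0] <= med_err[0.3] <= med_err[0.6] + 0.02
        assert med_err[0.0] < 1e-8

    def test_too_few_points_rejected(self):
        curve = make_curve([100, 200, 300, 400, 500], [5, 10, 15, 18, 20],
                           species="tomato")
        with pytest.raises(lp.FitError):
            lp.fit_fvcb_bilinear(curve)

    def test_degenerate_flat_curve_flagged(self):
        ci = np.linspace(100, 1500, 8)
        curve = make_curve(ci, np.full(8, -3.0), species="tomato")
        fit = lp.fit_fvcb_bilinear(curve)
        assert not fit.success

    def test_prediction_continuous_across_transition(self, noiseless_c3_curve):
        fit = lp.fit_fvcb_bilinear(noiseless_c3_curve)
        ci = np.linspace(fit.transition_ci - 1, fit.transition_ci + 1, 101)
        pred = lp.fvcb_an(ci, fit.Vcmax, fit.Jmax, fit.Rd)
        assert np.max(np.abs(np.diff(pred))) < 0.01  # no jump at the kink


def _grid_search_sse(curve, n=30):
    vgrid = np.linspace(80, 120, n)
    jgrid = np.linspace(150, 210, n)
    rgrid = np.linspace(0.0, 3.0, n)
    ci = curve.ci
    K = lp.DEFAULT_CONSTANTS
    x1 = (ci - K.gammastar) / (ci + K.Km)
    x2 = (ci - K.gammastar) / (4 * ci + 8 * K.gammastar)
    best = np.inf
    for V in vgrid:
        ac = V * x1
        for J in jgrid:
            m = np.minimum(ac, J * x2)
            for R in rgrid:
                sse = float(np.sum((curve.A - (m - R)) ** 2))
                best = min(best, sse)
    return best


class TestVpmaxFit:
    def test_noiseless_exact_recovery(self):
        ci = np.array([10.0, 25.0, 50.0, 80.0])
        A = lp.c4_pepc_limited(ci, 110.0, 80.0, 2.0)
        fit = lp.fit_vpmax(make_curve(ci, A))
        assert fit.success
        assert fit.Vpmax == pytest.approx(110.0, rel=1e-3)
        assert fit.Rd_slope == pytest.approx(2.0, rel=1e-3)

    def test_degenerate_constant_assimilation(self):
        ci = np.array([10.0, 25.0, 50.0, 80.0])
        fit = lp.fit_vpmax(make_curve(ci, np.full(4, 12.0)))
        assert not fit.success

    def test_too_few_low_ci_points(self):
        ci = np.array([150.0, 300.0, 500.0, 40.0, 70.0])
        with pytest.raises(lp.FitError):
            lp.fit_vpmax(make_curve(ci, np.zeros(5)), ci_cutoff=100.0)

    def test_monte_carlo_recovery(self):
        ci = np.array([10.0, 25.0, 50.0, 80.0])
        truth = lp.c4_pepc_limited(ci, 110.0, 80.0, 2.0)
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            fit = lp.fit_vpmax(make_curve(ci, truth + rng.normal(0, 0.5, 4)))
            errs.append(abs(fit.Vpmax - 110.0) / 110.0)
        assert np.median(errs) <= 0.10


class TestNRHFit:
    def test_noiseless_asymptote_recovery(self, c4_params):
        # spec'd generating values: phi=0.55, Asat=47, theta=0.7, offset=-2
        curve0 = lp.generate_aci_c4(c4_params, noise_sd=0.0, seed=0)
        A = lp.nrh(curve0.ci, 0.55, 47.0, 0.7, -2.0)
        fit = lp.fit_nrh_amax(make_curve(curve0.ci, A))
        assert fit.success
        assert fit.Amax == pytest.approx(45.0, rel=0.005)
        assert fit.phi == pytest.approx(0.55, rel=0.01)
        assert fit.theta == pytest.approx(0.7, rel=0.02)

    def test_theta_pinned_warns(self):
        ci = np.linspace(10, 500, 12)
        A = 0.5 * ci * 40 / (0.5 * ci + 40) - 2.0  # rectangular (theta -> 0)
        with pytest.warns(RuntimeWarning):
            fit = lp.fit_nrh_amax(make_curve(ci, A))
        assert fit.theta_pinned

    def test_monte_carlo_recovery(self, c4_params):
        ci = lp.generate_aci_c4(c4_params, noise_sd=0.0, seed=0).ci
        truth = lp.nrh(ci, 0.55, 47.0, 0.7, -2.0)
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(60):
            fit = lp.fit_nrh_amax(make_curve(ci, truth + rng.normal(0, 0.5, len(ci))))
            errs.append(abs(fit.Amax - 45.0) / 45.0)
        assert np.median(errs) <= 0.10

    def test_too_few_points(self):
        with pytest.raises(lp.FitError):
            lp.fit_nrh_amax(make_curve([10, 50, 100], [5, 15, 20]))
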