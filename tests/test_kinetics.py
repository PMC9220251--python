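import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteokin.kinetics import (
    KineticsError,
    MMParameters,
    ProgressCurve,
    RateObservation,
    extract_initial_rate,
    fit_mm,
    mm_velocity,
)


def make_curve(times, signal, **kw):
    defaults = dict(substrate_conc=2e-5, modulator_conc=0.0, enzyme_conc=2e-9)
    defaults.update(kw)
    return ProgressCurve(times=np.asarray(times, float), signal=np.asarray(signal, float), **defaults)


class TestMMVelocity:
    @pytest.mark.parametrize(
        "kcat,km,e0,s,expected",
        [
            (1.0, 2e-5, 2e-9, 2e-5, 1.0e-9),  # S = Km gives half of Vmax
            (1.0, 2e-5, 2e-9, 0.0, 0.0),  # no substrate, no turnover
            (1.0, 2e-5, 2e-9, 1e-4, 5e-5 / 3 * 1e-4),  # kcat*E0*S/(Km+S) directly
        ],
    )
    def test_closed_form(self, kcat, km, e0, s, expected):
        p = MMParameters(kcat=kcat, km=km)
        assert mm_velocity(p, s, e0) == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_inputs(self):
        p = MMParameters(kcat=1.0, km=2e-5)
        with pytest.raises(KineticsError):
            mm_velocity(p, -1e-6, 2e-9)
        with pytest.raises(KineticsError):
            mm_velocity(p, 1e-5, 0.0)
        with pytest.raises(KineticsError):
            mm_velocity(p, float("nan"), 2e-9)

    def test_monotone_in_substrate_and_linear_in_enzyme(self):
        p = MMParameters(kcat=2.3, km=3.6e-5)
        s = np.logspace(-7, -3, 40)
        v = mm_velocity(p, s, 2e-9)
        assert np.all(np.diff(v) > 0)
        assert mm_velocity(p, 2e-5, 4e-9) == pytest.approx(2 * mm_velocity(p, 2e-5, 2e-9), rel=1e-12)

    def test_half_vmax_at_km(self):
        p = MMParameters(kcat=7.7, km=1.1e-5)
        vmax = p.kcat * 2e-9
        assert mm_velocity(p, p.km, 2e-9) == pytest.approx(vmax / 2, rel=1e-12)


class TestExtractInitialRate:
    def test_exact_line_returns_generating_slope(self):
        t = np.linspace(0, 2700, 46)
        rate = extract_initial_rate(make_curve(t, 100 + 0.5 * t))
        assert rate.velocity == pytest.approx(0.5, rel=1e-12)
        assert rate.r_squared == pytest.approx(1.0, abs=1e-12)
        assert rate.window == (0.0, 2700.0)

    def test_constant_signal_flags_undefined_r2(self):
        t = np.linspace(0, 2700, 46)
        rate = extract_initial_rate(make_curve(t, np.full_like(t, 50.0)))
        assert rate.velocity == 0.0
        assert np.isnan(rate.r_squared)

    def test_calibration_converts_to_molar(self):
        t = np.linspace(0, 2700, 46)
        rate = extract_initial_rate(make_curve(t, 2000.0 * 1e-9 * t, calibration=2000.0))
        assert rate.velocity == pytest.approx(1e-9, rel=1e-12)

    def test_slow_exponential_slope_near_initial_rate(self):
        # F(t) = F_inf (1 - exp(-k t)) with k*t_max = 0.1 stays within 5%
        # of the true initial slope F_inf*k over the whole window
        t = np.linspace(0, 2700, 46)
        k = 0.1 / 2700
        f_inf = 1e4
        rate = extract_initial_rate(make_curve(t, f_inf * (1 - np.exp(-k * t))))
        assert rate.velocity == pytest.approx(f_inf * k, rel=0.05)
        # the first-decile window comes even closer
        rate10 = extract_initial_rate(make_curve(t[:6], f_inf * (1 - np.exp(-k * t[:6]))))
        assert rate10.velocity == pytest.approx(f_inf * k, rel=0.006)

    def test_adaptive_window_shrinks_on_curved_trace(self):
        t = np.linspace(0, 2700, 46)
        k = 3.0 / 2700  # strongly curved
        y = 1e4 * (1 - np.exp(-k * t))
        full = extract_initial_rate(make_curve(t, y), window_policy="full")
        adaptive = extract_initial_rate(make_curve(t, y), window_policy="adaptive")
        assert adaptive.n_points < full.n_points
        assert abs(adaptive.velocity - 1e4 * k) < abs(full.velocity - 1e4 * k)

    def test_too_few_points_rejected(self):
        with pytest.raises(KineticsError):
            extract_initial_rate(make_curve([0, 60, 120], [0, 1, 2]))


def simulated_rates(kcat, km, e0=2e-9, s_grid=(5e-6, 1e-5, 2.5e-5, 5e-5, 1e-4)):
    p = MMParameters(kcat=kcat, km=km)
    return [
        RateObservation(velocity=mm_velocity(p, s, e0), substrate_conc=s, modulator_conc=0.0, enzyme_conc=e0)
        for s in s_grid
    ]


class TestFitMM:
    def test_noiseless_recovery_both_methods_agree(self):
        obs = simulated_rates(kcat=1.0, km=3.6e-5)
        direct = fit_mm(obs, method="direct")
        recip = fit_mm(obs, method="double_reciprocal")
        assert direct.kcat == pytest.approx(1.0, rel=1e-8)
        assert direct.km == pytest.approx(3.6e-5, rel=1e-8)
        assert recip.kcat == pytest.approx(direct.kcat, rel=1e-8)
        assert recip.km == pytest.approx(direct.km, rel=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        log_kcat=st.floats(min_value=-3, max_value=3),
        log_km_rel=st.floats(min_value=-3, max_value=3),
    )
    def test_round_trip_over_scales(self, log_kcat, log_km_rel):
        kcat = 10.0**log_kcat
        km = 3.6e-5 * 10.0**log_km_rel
        # substrate grid spans the Km to keep the design informative
        s_grid = km * np.array([0.2, 0.5, 1.0, 2.0, 5.0])
        fit = fit_mm(simulated_rates(kcat, km, s_grid=s_grid))
        assert fit.kcat == pytest.approx(kcat, rel=1e-8)
        assert fit.km == pytest.approx(km, rel=1e-8)

    def test_under_determined_design_rejected(self):
        obs = simulated_rates(1.0, 3.6e-5, s_grid=(1e-5, 1e-4))
        with pytest.raises(KineticsError):
            fit_mm(obs + obs)  # 4 rows but only 2 distinct S

    def test_all_zero_velocities_rejected(self):
        obs = [
            RateObservation(velocity=0.0, substrate_conc=s, modulator_conc=0.0, enzyme_conc=2e-9)
            for s in (1e-5, 2e-5, 5e-5)
        ]
        with pytest.raises(KineticsError):
            fit_mm(obs)

    def test_mixed_modulator_concentrations_rejected(self):
        obs = simulated_rates(1.0, 3.6e-5)
        bad = obs[:-1] + [
            RateObservation(velocity=1e-9, substrate_conc=1e-4, modulator_conc=1e-6, enzyme_conc=2e-9)
        ]
        with pytest.raises(KineticsError):
            fit_mm(bad)
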