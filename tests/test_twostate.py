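import numpy as np
import pytest

from proteokin.inhibition import apparent_km
from proteokin.reference import TMPC_LIKE
from proteokin.twostate import (
    TwoStateParameters,
    efficiency_consistency_check,
    dose_response,
    efficiency_obs,
    interaction_ratios,
    kcat_obs,
    km_obs,
    state_populations,
)

from conftest import random_twostate


def make_params(**kw):
    defaults = dict(
        kcat_a=1.0,
        kcat_b=0.5,
        km_a=3.6e-5,
        km_b=3.6e-5,
        l_u=0.2,
        l_l=0.1,
        k_au=1e6,
        k_al=1e6,
        k_bu=1e7,
        k_bl=1e7,
        n_sites=3,
        m_sites=0,
    )
    defaults.update(kw)
    return TwoStateParameters(**defaults)


class TestKcatObs:
    def test_zero_modulator_closed_form(self):
        p = make_params(kcat_a=1.0, kcat_b=2.0, l_l=1.0)
        assert kcat_obs(p, 0.0) == pytest.approx(1.5, rel=1e-14)

    def test_equal_binding_constants_make_kcat_flat(self):
        p = make_params(k_al=5e6, k_bl=5e6)
        i = np.logspace(-8, -4, 30)
        assert np.allclose(kcat_obs(p, i), kcat_obs(p, 0.0), rtol=1e-12)

    def test_direct_evaluation(self):
        # (1*8 + 0.1*0.5*1331) / (8 + 0.1*1331) = 74.55/141.1
        p = make_params(kcat_a=1.0, kcat_b=0.5, l_l=0.1, k_al=1e6, k_bl=1e7)
        assert kcat_obs(p, 1e-6) == pytest.approx(74.55 / 141.1, rel=1e-12)

    def test_bounded_by_state_turnovers_for_random_parameters(self):
        rng = np.random.default_rng(42)
        i = np.logspace(-9, -3, 25)
        for _ in range(100):
            p = random_twostate(rng)
            v = np.asarray(kcat_obs(p, i))
            lo, hi = min(p.kcat_a, p.kcat_b), max(p.kcat_a, p.kcat_b)
            assert np.all(v >= lo * (1 - 1e-12)) and np.all(v <= hi * (1 + 1e-12))

    def test_monotone_with_saturating_limit(self):
        # kcat_b > kcat_a and K_BL > K_AL: nondecreasing with the stated limit
        p = make_params(kcat_a=1.0, kcat_b=2.0, l_l=0.1, k_al=1e6, k_bl=1e7)
        i = np.logspace(-9, -1, 200)
        v = np.asarray(kcat_obs(p, i))
        assert np.all(np.diff(v) >= -1e-15)
        limit = (p.kcat_a * p.k_al**3 + p.l_l * p.kcat_b * p.k_bl**3) / (p.k_al**3 + p.l_l * p.k_bl**3)
        assert v[-1] == pytest.approx(limit, rel=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            kcat_obs(make_params(), -1e-9)


class TestKmObs:
    def test_zero_modulator_closed_form(self):
        p = make_params(km_a=3.6e-5, l_u=0.2, l_l=0.1)
        assert km_obs(p, 0.0) == pytest.approx(3.6e-5 * 1.2 / 1.1, rel=1e-14)

    def test_reduces_to_competitive_form_when_degenerate(self):
        # all six binding constants equal, L_U = L_L, m = 1: Km0*(1 + I/KI)
        k = 1e6
        p = make_params(l_u=0.1, l_l=0.1, k_au=k, k_al=k, k_bu=k, k_bl=k, k_ai=k, k_bi=k, m_sites=1)
        assert km_obs(p, 1e-6) == pytest.approx(2 * 3.6e-5, rel=1e-12)

    def test_competitive_regime_eventually_increases(self):
        i = np.logspace(-7, -4, 60)
        km = np.asarray(km_obs(TMPC_LIKE, i))
        assert km[-1] > km[0]
        assert np.all(np.diff(km)[-20:] > 0)

    def test_equal_constant_reduction_over_random_draws(self):
        # the competitive-only limit holds for arbitrary k, L, Km and n
        rng = np.random.default_rng(7)
        i = np.concatenate([[0.0], np.logspace(-8, -4, 20)])
        for _ in range(100):
            k = 10.0 ** rng.uniform(4, 8)
            l = 10.0 ** rng.uniform(-3, 3)
            km0 = 10.0 ** rng.uniform(-6, -3)
            n = int(rng.integers(0, 5))
            p = make_params(
                km_a=km0, l_u=l, l_l=l, k_au=k, k_al=k, k_bu=k, k_bl=k, k_ai=k, k_bi=k,
                n_sites=n, m_sites=1,
            )
            expected = apparent_km(km0, 1.0 / k, i)
            assert np.allclose(km_obs(p, i), expected, rtol=1e-10)


class TestEfficiency:
    def test_ratio_mode_is_kcat_over_km(self):
        i = np.logspace(-8, -4, 30)
        eff = np.asarray(efficiency_obs(TMPC_LIKE, i))
        assert np.allclose(eff, np.asarray(kcat_obs(TMPC_LIKE, i)) / np.asarray(km_obs(TMPC_LIKE, i)), rtol=1e-14)

    def test_literal_agrees_in_degenerate_limit(self):
        p = make_params(k_au=2e6, k_al=2e6, k_bu=5e6, k_bl=5e6).with_detailed_balance()
        assert efficiency_obs(p, 0.0, mode="literal") == pytest.approx(
            efficiency_obs(p, 0.0, mode="ratio"), rel=1e-12
        )

    def test_literal_differs_with_competitive_sites(self):
        p = make_params(k_ai=1e6, k_bi=1e6, m_sites=1).with_detailed_balance()
        lit = efficiency_obs(p, 1e-6, mode="literal")
        rat = efficiency_obs(p, 1e-6, mode="ratio")
        assert abs(lit - rat) / rat > 1e-3


class TestInteractionRatios:
    def test_printed_ratios(self):
        p = make_params(k_au=3e5, k_al=1e6, k_bu=3e5, k_bl=1e6)
        r = interaction_ratios(p)
        assert (r.alpha, r.beta, r.gamma, r.delta) == pytest.approx((0.3, 0.3, 1.0, 1.0), rel=1e-12)

    def test_all_equal_gives_unity(self):
        p = make_params(k_au=2e6, k_al=2e6, k_bu=2e6, k_bl=2e6)
        r = interaction_ratios(p)
        assert (r.alpha, r.beta, r.gamma, r.delta) == pytest.approx((1.0, 1.0, 1.0, 1.0), rel=1e-12)

    def test_linkage_identity_alpha_over_beta(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = random_twostate(rng)
            r = interaction_ratios(p)
            assert r.alpha / r.beta == pytest.approx(r.delta / r.gamma, rel=1e-12)


class TestStatePopulations:
    def test_zero_modulator_unbound(self):
        p = make_params(l_u=0.25)
        assert state_populations(p, 0.0, substrate_bound=False) == pytest.approx(0.2, rel=1e-14)

    def test_zero_modulator_bound(self):
        p = make_params(l_l=1.0)
        assert state_populations(p, 0.0, substrate_bound=True) == pytest.approx(0.5, rel=1e-14)

    def test_saturating_shift_to_b_state(self):
        p = make_params(k_al=1e5, k_bl=1e7, l_l=0.1)
        assert state_populations(p, 1e-3, substrate_bound=True) == pytest.approx(1.0, abs=1e-3)

    def test_fraction_in_unit_interval(self):
        rng = np.random.default_rng(5)
        i = np.logspace(-9, -3, 20)
        for _ in range(50):
            p = random_twostate(rng)
            for bound in (True, False):
                f = np.asarray(state_populations(p, i, substrate_bound=bound))
                assert np.all((f >= 0) & (f <= 1))


class TestConsistencyCheck:
    def test_zero_in_degenerate_limit(self):
        p = make_params(k_au=2e6, k_al=2e6, k_bu=5e6, k_bl=5e6).with_detailed_balance()
        grid = np.logspace(-8, -4, 20)
        assert efficiency_consistency_check(p, grid) <= 1e-12

    def test_positive_with_active_competitive_site(self):
        grid = np.logspace(-7, -5, 20)
        assert efficiency_consistency_check(TMPC_LIKE, grid) > 0

    def test_invariant_under_reciprocal_rescaling(self):
        # rescaling all concentrations by c and all association constants by
        # 1/c leaves the (dimensionless) discrepancy unchanged
        grid = np.logspace(-7, -5, 15)
        c = 137.0
        p = TMPC_LIKE
        scaled = TwoStateParameters(
            kcat_a=p.kcat_a, kcat_b=p.kcat_b,
            km_a=p.km_a * c, km_b=p.km_b * c,
            l_u=p.l_u, l_l=p.l_l,
            k_au=p.k_au / c, k_al=p.k_al / c, k_bu=p.k_bu / c, k_bl=p.k_bl / c,
            k_ai=p.k_ai / c, k_bi=p.k_bi / c,
            n_sites=p.n_sites, m_sites=p.m_sites,
        )
        d1 = efficiency_consistency_check(p, grid)
        d2 = efficiency_consistency_check(scaled, grid * c)
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestInvariants:
    def test_no_sites_means_constant_observables(self):
        p = make_params(n_sites=0, m_sites=0)
        i = np.logspace(-8, -4, 30)
        dr = dose_response(p, np.concatenate([[0.0], i]))
        assert np.allclose(dr.kcat, dr.kcat[0], rtol=1e-14)
        assert np.allclose(dr.km, dr.km[0], rtol=1e-14)
        assert np.allclose(dr.efficiency, dr.efficiency[0], rtol=1e-14)

    def test_ratio_efficiency_times_km_equals_kcat(self):
        i = np.logspace(-8, -4, 30)
        eff = np.asarray(efficiency_obs(TMPC_LIKE, i))
        km = np.asarray(km_obs(TMPC_LIKE, i))
        assert np.allclose(eff * km, np.asarray(kcat_obs(TMPC_LIKE, i)), rtol=1e-13)

    def test_detailed_balance_helper(self):
        p = make_params(l_u=0.3, l_l=0.6, km_a=4e-5)
        q = p.with_detailed_balance()
        assert q.km_b == pytest.approx(2e-5, rel=1e-14)
        assert q.detailed_balance_satisfied
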