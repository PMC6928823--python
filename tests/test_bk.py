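"""BK_Ca rates, complex chains, and the reduction ladder."""

import numpy as np
import pytest

from cacomplex.bk import (
    BKRateParams,
    ComplexConfig,
    SIX_STATE_LABELS,
    bk_open_steady,
    bk_rates,
    complex_generator_1to1,
    complex_generator_k,
    full_ode_open_probability,
    ibk_current,
    mbk1_coeffs,
    mbk1_coeffs_instant,
    mbk_k_coeffs,
    mbk_k_coeffs_instant,
    pY_from_6state,
    pY_mixture,
    qss_open_probability,
)
from cacomplex.cav import CaVParams, cav_activation_steady
from cacomplex.markov import (
    ensemble_summary,
    mc_comparison_band,
    gillespie_ensemble,
    solve_master_equation_protocol,
)

VGRID = np.linspace(-80.0, 60.0, 29)


class TestBKRates:
    def test_half_open_where_rates_balance(self, bkp):
        # scan V for the balance point at fixed Ca, check p_inf = 1/2 there
        ca = 50.0
        vs = np.linspace(-100, 150, 2000)
        diff = [bk_rates(v, ca, bkp)[0] - bk_rates(v, ca, bkp)[1] for v in vs]
        v_half = vs[np.argmin(np.abs(diff))]
        assert bk_open_steady(v_half, ca, bkp) == pytest.approx(0.5, abs=0.01)

    def test_open_probability_increases_with_ca(self, bkp):
        for v in VGRID:
            p1 = bk_open_steady(v, 5.0, bkp)
            p2 = bk_open_steady(v, 50.0, bkp)
            assert p1 <= p2 + 1e-12

    def test_boltzmann_with_ca_independent_slope(self, bkp):
        # logit(p_inf) must be linear in V with slope 1/sV at every Ca
        for ca in (2.0, 20.0, 200.0):
            p = np.array([bk_open_steady(v, ca, bkp) for v in VGRID])
            logit = np.log(p / (1 - p))
            slopes = np.diff(logit) / np.diff(VGRID)
            np.testing.assert_allclose(slopes, 1.0 / bkp.sV, rtol=1e-8)

    def test_left_shift_with_ca(self, bkp):
        def vhalf(ca):
            return bkp.sV * np.log(
                bk_rates(0.0, ca, bkp)[1] / bk_rates(0.0, ca, bkp)[0]
            )

        assert vhalf(100.0) < vhalf(30.0) < vhalf(10.0)

    def test_background_opening_negligible(self, bkp, nano):
        # k+ at background Ca is < 1e-3 of k+ at the open-channel domain
        kp_bg = bk_rates(0.0, nano.Cac, bkp)[0]
        kp_open = bk_rates(0.0, 19.0, bkp)[0]
        assert kp_bg < 1e-3 * kp_open

    def test_negative_ca_rejected(self, bkp):
        with pytest.raises(ValueError):
            bk_rates(0.0, -1.0, bkp)


class TestSixStateComplex:
    def test_generator_valid(self, bkp, cavp, nano):
        m = complex_generator_1to1(0.0, bkp, cavp, nano)
        assert m.state_labels == SIX_STATE_LABELS
        np.testing.assert_allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        off = m.Q - np.diag(np.diag(m.Q))
        assert off.min() >= 0

    def test_inactivated_states_unreachable_without_inactivation(self, nano, bkp):
        cav_ni = CaVParams(gamma=0.0, deltaCoeff=0.0)
        q_of = lambda V: complex_generator_1to1(V, bkp, cav_ni, nano)  # noqa: E731
        p0 = np.zeros(6)
        p0[0] = 1.0
        probs = solve_master_equation_protocol(q_of, [(50.0, 0.0)], p0, np.linspace(0, 50, 6))
        assert np.max(probs[:, [2, 5]]) < 1e-12

    def test_pY_projection(self):
        p = np.zeros(6)
        p[0] = 1.0
        assert pY_from_6state(p) == 0.0
        p = np.zeros(6)
        p[4] = 1.0
        assert pY_from_6state(p) == 1.0
        assert pY_from_6state(np.full(6, 1 / 6)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            pY_from_6state(np.full(6, 0.2))

    def test_six_state_mc_within_four_se(self, bkp, cavp, nano):
        proto = [(10.0, -80.0), (60.0, 0.0)]
        grid = np.arange(0.0, 70.5, 1.0)
        q_of = lambda V: complex_generator_1to1(V, bkp, cavp, nano)  # noqa: E731
        p0 = np.zeros(6)
        p0[0] = 1.0
        paths = gillespie_ensemble(q_of, proto, 70.0, 1000, seed=21)
        summ = ensemble_summary(paths, [3, 4, 5], grid)
        exact = solve_master_equation_protocol(q_of, proto, p0, grid)[:, 3:].sum(axis=1)
        lo, hi = mc_comparison_band(exact, 1000)
        assert np.all((summ.mean >= lo) & (summ.mean <= hi))


class TestReductionCoefficients:
    def test_mbk1_zero_activation(self, bkp, cavp, nano):
        _, m_inf = mbk1_coeffs(0.0, 0.0, bkp, cavp, nano)
        assert m_inf == 0.0

    def test_mbk1_matches_general_solver(self, bkp, cavp, nano):
        for v in (-40.0, -10.0, 20.0):
            for m in (0.0, 0.4, 1.0):
                t1, i1 = mbk1_coeffs(v, m, bkp, cavp, nano)
                tk, ik = mbk_k_coeffs(v, 1, m, bkp, cavp, nano)
                assert tk == pytest.approx(t1, rel=1e-10)
                assert ik == pytest.approx(i1, rel=1e-10, abs=1e-14)

    def test_fast_cav_limit_reaches_instant_coeffs(self, bkp, nano):
        cav_fast = CaVParams(tauM=1e-6)
        for v in (-20.0, 0.0, 20.0):
            mInf, _ = cav_activation_steady(v, cav_fast)
            ti, mi = mbk1_coeffs_instant(v, bkp, cav_fast, nano)
            tq, mq = mbk1_coeffs(v, mInf, bkp, cav_fast, nano)
            assert ti == pytest.approx(tq, rel=1e-4)
            assert mi == pytest.approx(mq, rel=1e-4, abs=1e-12)

    def test_instant_coeffs_limits(self, bkp, cavp, nano):
        # mInf ~ 0: tau -> 1/kc-; mInf ~ 1: isolated open-CaV equilibrium
        from cacomplex.bk import _vertical_rates

        _, kc_m = bk_rates(-300.0, nano.Cac, bkp)
        tau, m_inf = mbk1_coeffs_instant(-300.0, bkp, cavp, nano)
        assert tau == pytest.approx(1.0 / kc_m, rel=1e-6)
        assert m_inf == pytest.approx(0.0, abs=1e-10)
        # k=1 at strong depolarization is dominated by the one-open state
        ko_p, ko_m = _vertical_rates(59.0, 1, bkp, nano)
        tau, m_inf = mbk_k_coeffs_instant(59.0, 1, bkp, cavp, nano)
        mInf, _ = cav_activation_steady(59.0, cavp)
        assert mInf > 0.998
        assert m_inf == pytest.approx(ko_p / (ko_p + ko_m), rel=5e-3)

    def test_instant_k_reduces_to_k1_closed_form(self, bkp, cavp, nano):
        for v in (-30.0, 0.0, 30.0):
            a = mbk_k_coeffs_instant(v, 1, bkp, cavp, nano)
            b = mbk1_coeffs_instant(v, bkp, cavp, nano)
            assert a == pytest.approx(b, rel=1e-12)

    def test_left_shift_with_stoichiometry(self, bkp, cavp, nano):
        for v in VGRID:
            m1 = mbk_k_coeffs_instant(v, 1, bkp, cavp, nano)[1]
            m2 = mbk_k_coeffs_instant(v, 2, bkp, cavp, nano)[1]
            m4 = mbk_k_coeffs_instant(v, 4, bkp, cavp, nano)[1]
            assert m4 >= m2 - 1e-12 and m2 >= m1 - 1e-12

    def test_no_open_cavs_no_activation(self, bkp, cavp, nano):
        _, m_inf = mbk_k_coeffs(-80.0, 3, 0.0, bkp, cavp, nano)
        assert m_inf < 1e-6


class TestComplexChainK:
    def test_k1_matches_six_state_submodel(self, bkp, cavp, nano):
        mk = complex_generator_k(0.0, 1, bkp, cavp, nano)
        m6 = complex_generator_1to1(0.0, bkp, cavp, nano)
        # order in k-chain: C1O0X, C0O1X, C1O0Y, C0O1Y == CX, OX, CY, OY
        sub = m6.Q[np.ix_([0, 1, 3, 4], [0, 1, 3, 4])]
        sub = sub - np.diag(np.diag(sub))
        qk = mk.Q - np.diag(np.diag(mk.Q))
        np.testing.assert_allclose(qk, sub, atol=1e-12)

    def test_cav_marginal_is_binomial(self, bkp, cavp, nano):
        # vertical BK moves do not alter CaV rates: the open-CaV count marginal
        # follows binomial(k, m(t)) exactly
        from math import comb

        k = 3
        proto = [(5.0, -80.0), (30.0, 0.0)]
        grid = np.arange(0.0, 35.2, 0.25)
        q_of = lambda V: complex_generator_k(V, k, bkp, cavp, nano)  # noqa: E731
        p0 = np.zeros(2 * (k + 1))
        p0[0] = 1.0
        probs = solve_master_equation_protocol(q_of, proto, p0, grid)
        # m(t) from the scalar activation ODE (exact per segment)
        from cacomplex.exocytosis import open_fraction

        m_t = open_fraction(proto, cavp, grid)
        m0, _ = cav_activation_steady(-80.0, cavp)
        m_t = m_t + (0 - m0) * np.exp(-grid / cavp.tauM)  # start closed, not at rest
        for i in range(k + 1):
            marginal = probs[:, i] + probs[:, k + 1 + i]
            binom = comb(k, i) * (1 - m_t) ** (k - i) * m_t**i
            np.testing.assert_allclose(marginal, binom, atol=1e-6)

    def test_gillespie_k4_within_four_se(self, bkp, cavp, nano):
        k = 4
        proto = [(10.0, -80.0), (60.0, 0.0)]
        grid = np.arange(0.0, 70.5, 1.0)
        q_of = lambda V: complex_generator_k(V, k, bkp, cavp, nano)  # noqa: E731
        paths = gillespie_ensemble(q_of, proto, 70.0, 1000, seed=33)
        summ = ensemble_summary(paths, list(range(k + 1, 2 * (k + 1))), grid)
        p0 = np.zeros(2 * (k + 1))
        p0[0] = 1.0
        exact = solve_master_equation_protocol(q_of, proto, p0, grid)[:, k + 1 :].sum(axis=1)
        lo, hi = mc_comparison_band(exact, 1000)
        assert np.all((summ.mean >= lo) & (summ.mean <= hi))

    def test_qss_tracks_full_ode(self, bkp, cavp, nano):
        proto = [(10.0, -80.0), (60.0, 0.0)]
        grid = np.arange(0.0, 70.05, 0.1)
        full = full_ode_open_probability(proto, 4, bkp, cavp, nano, grid)
        qss = qss_open_probability(proto, 4, bkp, cavp, nano, grid)
        assert np.max(np.abs(full - qss)) < 0.03


class TestMixtureAndCurrent:
    def test_mixture_limits(self):
        mbk = {1: 0.2, 2: 0.5, 3: 0.8}
        assert pY_mixture(1.0, mbk, 3) == pytest.approx(0.8)
        assert pY_mixture(0.0, mbk, 3) == 0.0
        assert pY_mixture(0.6, {1: 0.37}, 1) == pytest.approx(0.6 * 0.37)

    def test_mixture_in_unit_interval(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 6))
            mbk = {k: float(rng.random()) for k in range(1, n + 1)}
            h = float(rng.random())
            assert 0.0 <= pY_mixture(h, mbk, n) <= 1.0

    def test_ibk_zero_at_reversal(self):
        cfg = ComplexConfig(NBK=1000, gBKSingle=100.0)
        assert ibk_current(cfg.VK, 0.7, cfg) == 0.0

    def test_whole_cell_conductance_scale(self):
        # NBK=1000 channels at 100 pS -> 100 nS: 1 mV above VK at pY=1 gives 100 pA
        cfg = ComplexConfig(NBK=1000, gBKSingle=100.0)
        assert ibk_current(cfg.VK + 1.0, 1.0, cfg) == pytest.approx(100.0)
        cfg700 = ComplexConfig(NBK=700, gBKSingle=100.0)
        assert ibk_current(cfg700.VK + 1.0, 1.0, cfg700) == pytest.approx(70.0)

    def test_py_bounds_enforced(self):
        with pytest.raises(ValueError):
            ibk_current(0.0, 1.2, ComplexConfig())
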