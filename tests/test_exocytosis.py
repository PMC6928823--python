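"""Granule exocytosis chains, release probability, Ca influx and efficiency fits."""

import numpy as np
import pytest

from cacomplex.calibration import generate_voltage_fixture
from cacomplex.exocytosis import (
    GRANULE_LABELS,
    GranuleParams,
    cumulative_ca_influx,
    exo_probability,
    fit_efficiency,
    granule_cav_generator,
    granule_cav_labels,
    granule_generator,
    open_fraction,
)
from cacomplex.markov import (
    absorption_probability,
    mc_comparison_band,
    solve_master_equation,
    solve_master_equation_protocol,
)

P0_5 = np.array([1.0, 0.0, 0.0, 0.0, 0.0])


class TestGranuleChain:
    def test_matrix_structure(self, granule):
        m = granule_generator(10.0, granule)
        kca = granule.kPlusG * 10.0
        assert m.Q[0, 1] == pytest.approx(3 * kca)
        assert m.Q[1, 2] == pytest.approx(2 * kca)
        assert m.Q[2, 3] == pytest.approx(kca)
        assert m.Q[3, 4] == pytest.approx(granule.u)
        assert m.Q[1, 0] == pytest.approx(granule.kMinusG)
        assert m.Q[3, 2] == pytest.approx(3 * granule.kMinusG)
        np.testing.assert_allclose(m.Q.sum(axis=1), 0.0, atol=1e-14)
        np.testing.assert_array_equal(m.Q[4], 0.0)
        assert m.state_labels == GRANULE_LABELS

    def test_no_ca_no_release(self, granule):
        m = granule_generator(0.0, granule)
        p0 = np.array([0.0, 0.5, 0.5, 0.0, 0.0])
        probs = solve_master_equation(m, p0, np.linspace(0, 500, 6))
        assert probs[-1, 0] > 0.999  # drifts back to G0
        assert probs[-1, 4] < 1e-6

    def test_fast_fusion_invariant_enforced(self):
        with pytest.raises(ValueError, match="fast-fusion"):
            GranuleParams(kPlusG=0.01, kMinusG=0.3, u=1.0)

    def test_sigmoidal_onset_zero_initial_slope(self, granule):
        # sequential binding delays release after a Ca step
        m = granule_generator(20.0, granule)
        ts = np.array([0.0, 0.1, 8.0, 16.0, 32.0])
        pexo = absorption_probability(m, P0_5, ts)
        early_slope = pexo[1] / 0.1
        late_slope = (pexo[3] - pexo[2]) / 8.0
        assert early_slope < 0.01 * late_slope
        assert np.all(np.diff(pexo) >= 0)

    def test_phase_type_matches_master_equation(self, granule):
        m = granule_generator(15.0, granule)
        grid = np.linspace(0.0, 200.0, 21)
        me = solve_master_equation(m, P0_5, grid)[:, 4]
        pt = absorption_probability(m, P0_5, grid)
        np.testing.assert_allclose(me, pt, atol=1e-8)


class TestGranuleCavChain:
    def test_state_count_convention(self, granule, cavp, nano):
        for n in (1, 2, 4, 8):
            gp = granule.model_copy(update={"nCaV": n})
            m = granule_cav_generator(0.0, gp, cavp, nano)
            assert m.n_states == 4 * (n + 1) + 1
            assert len(granule_cav_labels(n, merge_fused=False)) == 5 * (n + 1)

    def test_merged_and_full_product_agree(self, granule, cavp, nano):
        gp = granule.model_copy(update={"nCaV": 2, "rG": 20.0})
        proto = [(5.0, -80.0), (200.0, 0.0)]
        grid = np.linspace(0.0, 205.0, 42)
        res = {}
        for merge in (True, False):
            q_of = lambda V: granule_cav_generator(V, gp, cavp, nano, merge_fused=merge)  # noqa: E731
            m0 = q_of(-80.0)
            p0 = np.zeros(m0.n_states)
            p0[m0.index("G0|0")] = 1.0
            probs = solve_master_equation_protocol(q_of, proto, p0, grid)
            if merge:
                res[merge] = probs[:, m0.index("Y")]
            else:
                idx = [m0.index(f"Y|{j}") for j in range(3)]
                res[merge] = probs[:, idx].sum(axis=1)
        np.testing.assert_allclose(res[True], res[False], atol=1e-9)

    def test_closed_cavs_decouple_to_background_chain(self, granule, cavp, nano):
        # V far below threshold: alpha ~ 0, the granule sees only Cac
        gp = granule.model_copy(update={"nCaV": 1})
        m = granule_cav_generator(-400.0, gp, cavp, nano)
        p0 = np.zeros(m.n_states)
        p0[m.index("G0|0")] = 1.0
        t = 5000.0
        coupled = solve_master_equation(m, p0, np.array([0.0, t]))[-1, m.index("Y")]
        bare = absorption_probability(granule_generator(nano.Cac, granule), P0_5, t)
        assert coupled == pytest.approx(bare, abs=1e-6)

    def test_inactivating_chain_is_15_states(self, granule, cavp, nano):
        m = granule_cav_generator(0.0, granule, cavp, nano, inactivating=True)
        assert m.n_states == 15
        np.testing.assert_allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        with pytest.raises(ValueError):
            granule_cav_generator(
                0.0, granule.model_copy(update={"nCaV": 2}), cavp, nano, inactivating=True
            )


class TestExoProbability:
    def test_basal_ca_release_ceiling(self, granule, nano):
        # granule chain held at the background Ca level for 10 s
        m = granule_generator(nano.Cac, granule)
        assert absorption_probability(m, P0_5, 10_000.0) < 0.01

    def test_nondecreasing(self, granule, cavp, nano):
        proto, _ = generate_voltage_fixture("bursting", t_end=10_000.0)
        gp = granule.model_copy(update={"nCaV": 2, "rG": 50.0})
        tr = exo_probability(proto, gp, cavp, nano, method="master")
        assert np.all(np.diff(tr["P_exo"]) >= -1e-10)

    def test_bursting_exceeds_spiking_at_10s(self, granule, cavp, nano):
        gp = granule.model_copy(update={"nCaV": 2, "rG": 100.0})
        ends = {}
        for pattern in ("spiking", "bursting"):
            proto, _ = generate_voltage_fixture(pattern, t_end=10_000.0)
            ends[pattern] = exo_probability(proto, gp, cavp, nano, method="master")["P_exo"][-1]
        assert ends["bursting"] >= ends["spiking"]

    def test_ssa_agrees_with_master(self, granule, cavp, nano):
        gp = granule.model_copy(update={"nCaV": 2, "rG": 20.0})
        proto = [(5.0, -80.0), (2000.0, 0.0)]
        grid = np.linspace(0.0, 2005.0, 41)
        me = exo_probability(proto, gp, cavp, nano, method="master", grid=grid)["P_exo"]
        ssa = exo_probability(proto, gp, cavp, nano, method="ssa", grid=grid,
                              n_paths=1000, seed=4)
        lo, hi = mc_comparison_band(me, 1000)
        assert np.all((ssa["P_exo"] >= lo) & (ssa["P_exo"] <= hi))

    def test_small_ensemble_warns_in_metadata(self, granule, cavp, nano):
        tr = exo_probability([(100.0, -80.0)], granule, cavp, nano, method="ssa",
                             n_paths=50, seed=0, grid=np.linspace(0, 100, 5))
        assert "warning" in tr.meta


class TestCaInflux:
    def test_zero_current_zero_charge(self, granule, cavp, nano):
        tr = cumulative_ca_influx([(1000.0, nano.VCa)], granule, cavp, nano)
        np.testing.assert_allclose(tr["QCa"], 0.0, atol=1e-12)

    def test_constant_current_rectangle(self, granule, cavp, nano):
        # fully open channel at fixed V: |i| * t
        grid = np.linspace(0.0, 100.0, 201)
        tr = cumulative_ca_influx([(100.0, 0.0)], granule, cavp, nano, grid=grid)
        m_eq, _ = __import__("cacomplex.cav", fromlist=["cav_activation_steady"]).cav_activation_steady(0.0, cavp)
        expected = granule.nCaV * nano.gCaSingle * m_eq * 60.0 * 1e-3 * 100.0
        assert tr["QCa"][-1] == pytest.approx(expected, rel=1e-6)

    def test_doubling_ncav_doubles_charge(self, granule, cavp, nano):
        proto, _ = generate_voltage_fixture("spiking", t_end=5000.0)
        q1 = cumulative_ca_influx(proto, granule.model_copy(update={"nCaV": 1}), cavp, nano)
        q2 = cumulative_ca_influx(proto, granule.model_copy(update={"nCaV": 2}), cavp, nano)
        np.testing.assert_allclose(q2["QCa"], 2.0 * q1["QCa"], rtol=1e-12)

    def test_nondecreasing(self, granule, cavp, nano):
        proto, _ = generate_voltage_fixture("bursting", t_end=5000.0)
        tr = cumulative_ca_influx(proto, granule, cavp, nano)
        assert np.all(np.diff(tr["QCa"]) >= 0)

    def test_open_fraction_tracks_boltzmann_at_steady_state(self, cavp):
        m = open_fraction([(50.0, -20.0)], cavp, np.linspace(0, 50, 11))
        from cacomplex.cav import cav_activation_steady

        assert m[-1] == pytest.approx(cav_activation_steady(-20.0, cavp)[0], rel=1e-9)


class TestEfficiencyFit:
    def test_generative_round_trip(self):
        q_true = 0.037
        qca = np.linspace(0.0, 120.0, 60)
        pexo = 1.0 - np.exp(-q_true * qca)
        fit = fit_efficiency(qca, pexo)
        assert fit.q == pytest.approx(q_true, rel=1e-6)
        assert fit.residual_rms < 1e-10
        assert fit.ci95[0] <= q_true <= fit.ci95[1]

    def test_degenerate_data_rejected(self):
        qca = np.linspace(0.0, 10.0, 20)
        with pytest.raises(ValueError, match="degenerate"):
            fit_efficiency(qca, np.zeros_like(qca))

    def test_charge_rescaling_halves_q(self):
        qca = np.linspace(0.0, 80.0, 40)
        pexo = 1.0 - np.exp(-0.05 * qca)
        q1 = fit_efficiency(qca, pexo).q
        q2 = fit_efficiency(2.0 * qca, pexo).q
        assert q2 == pytest.approx(q1 / 2.0, rel=1e-8)

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            fit_efficiency(np.linspace(0, 1, 5), np.linspace(0, 0.5, 5))

    def test_summary_mentions_units(self):
        qca = np.linspace(0.0, 50.0, 30)
        fit = fit_efficiency(qca, 1.0 - np.exp(-0.02 * qca))
        assert "1/fC" in fit.summary()
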