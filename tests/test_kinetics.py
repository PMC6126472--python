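"""Haldane rate laws, speciation, gas transfer, and batch simulations."""

import math

import numpy as np
import pytest

from chlamydyn import (
    BatchState,
    HaldaneParams,
    MixotrophicParams,
    co2_speciation,
    co2_transfer_rate,
    dual_haldane_mu,
    haldane_mu,
    haldane_peak,
    simulate_heterotrophic,
    simulate_mixotrophic,
)


class TestHaldaneLaw:
    def test_zero_and_half_saturation(self):
        p = HaldaneParams(mu_max=0.6, Ks=1.0, Ki=math.inf, Yx=0.5)
        assert haldane_mu(0.0, p) == 0.0
        assert haldane_mu(1.0, p) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            haldane_mu(-0.1, p)

    def test_peak_matches_dense_grid_search(self):
        p = HaldaneParams(mu_max=0.5, Ks=0.2, Ki=5.0, Yx=0.5)
        ac_star, mu_star = haldane_peak(p)
        assert ac_star == pytest.approx(math.sqrt(0.2 * 5.0))
        grid = np.linspace(0.0, 20.0, 200001)
        mu = haldane_mu(grid, p)
        k = int(np.argmax(mu))
        assert grid[k] == pytest.approx(ac_star, rel=1e-3)
        assert mu[k] == pytest.approx(mu_star, rel=1e-6)
        assert mu_star == pytest.approx(p.mu_max / (1 + 2 * math.sqrt(p.Ks / p.Ki)))

    def test_unimodal_increasing_then_decreasing(self):
        p = HaldaneParams(mu_max=1.0, Ks=0.5, Ki=2.0, Yx=0.5)
        ac_star, _ = haldane_peak(p)
        rising = np.linspace(0, ac_star, 500)
        falling = np.linspace(ac_star, 50, 500)
        assert np.all(np.diff(haldane_mu(rising, p)) >= -1e-12)
        assert np.all(np.diff(haldane_mu(falling, p)) <= 1e-12)

    def test_strictly_below_mu_max(self):
        p = HaldaneParams(mu_max=0.8, Ks=0.1, Ki=100.0, Yx=0.5)
        assert np.all(haldane_mu(np.linspace(0, 1000, 1000), p) < p.mu_max)


class TestDualHaldane:
    def test_either_substrate_zero_stops_growth(self):
        p = MixotrophicParams()
        assert dual_haldane_mu(0.0, 1e-3, p) == 0.0
        assert dual_haldane_mu(1.0, 0.0, p) == 0.0

    def test_quarter_of_mu_max_at_both_half_saturations(self):
        p = MixotrophicParams(mu_max=0.4, Ks_Ac=0.2, Ki_Ac=math.inf,
                              Ks_DIC=1e-3, Ki_DIC=math.inf)
        assert dual_haldane_mu(0.2, 1e-3, p) == pytest.approx(0.1)

    def test_factorizes_into_single_substrate_laws(self):
        p = MixotrophicParams(mu_max=0.3, Ks_Ac=0.1, Ki_Ac=8.0, Ks_DIC=2e-4, Ki_DIC=0.5)
        h_ac = HaldaneParams(mu_max=p.mu_max, Ks=p.Ks_Ac, Ki=p.Ki_Ac, Yx=1.0)
        h_dic = HaldaneParams(mu_max=p.mu_max, Ks=p.Ks_DIC, Ki=p.Ki_DIC, Yx=1.0)
        for ac, dic in [(0.3, 1e-3), (2.0, 1e-4), (0.05, 5e-2)]:
            expected = haldane_mu(ac, h_ac) * haldane_mu(dic, h_dic) / p.mu_max
            assert dual_haldane_mu(ac, dic, p) == pytest.approx(expected, rel=1e-12)


class TestCarbonateChemistry:
    def test_speciation_hand_value_and_limits(self):
        # at pH = pK1 half the DIC is CO2 (carbonate term K1*K2*10^(2pH) = 1e-4)
        co2 = co2_speciation(1e-3, pH=6.3, K1=10**-6.3, K2=10**-10.3)
        assert co2 == pytest.approx(1e-3 / (2.0 + 1e-4), rel=1e-12)
        assert co2_speciation(0.0, 7.0, 10**-6.3, 10**-10.3) == 0.0
        # very acid water: all DIC is dissolved CO2
        assert co2_speciation(1e-3, -10.0, 10**-6.3, 10**-10.3) == pytest.approx(1e-3, rel=1e-6)

    def test_speciation_monotone_decreasing_in_ph(self):
        phs = np.linspace(4.0, 11.0, 50)
        vals = [co2_speciation(1e-3, ph, 10**-6.3, 10**-10.3) for ph in phs]
        assert np.all(np.diff(vals) < 0)

    def test_transfer_rate_equilibrium_and_linearity(self):
        p = MixotrophicParams(kLa=4.0)
        eq = p.P / p.H_co2 * p.y_out_co2
        assert co2_transfer_rate(eq, p) == pytest.approx(0.0, abs=1e-15)
        assert co2_transfer_rate(0.0, p) == pytest.approx(p.kLa * eq)
        p2 = MixotrophicParams(kLa=8.0)
        assert co2_transfer_rate(0.0, p2) == pytest.approx(2 * co2_transfer_rate(0.0, p))


class TestHeterotrophicSimulation:
    def test_first_integral_without_maintenance(self):
        p = HaldaneParams(maintenance_m=0.0)
        x0 = BatchState(t=0.0, X=0.05, Ac=1.0)
        traj = simulate_heterotrophic(p, x0, t_end=120.0, dt=0.5)
        inv = traj.X + p.Yx * traj.Ac
        assert np.max(np.abs(inv - inv[0])) < 1e-6

    def test_exponential_closed_form_in_the_saturated_limit(self):
        p = HaldaneParams(mu_max=0.1, Ks=1e-9, Ki=math.inf, Yx=0.5, maintenance_m=0.0)
        x0 = BatchState(t=0.0, X=0.01, Ac=100.0)  # ample substrate
        traj = simulate_heterotrophic(p, x0, t_end=20.0, dt=0.5)
        expected = 0.01 * np.exp(p.mu_max * traj.times)
        assert np.max(np.abs(traj.X - expected) / expected) < 1e-6

    def test_no_substrate_means_constant_biomass(self):
        p = HaldaneParams()
        traj = simulate_heterotrophic(p, BatchState(0.0, 0.2, 0.0), 24.0, 1.0)
        assert np.all(traj.X == 0.2)
        assert np.all(traj.Ac == 0.0)

    def test_growth_and_maintenance_stop_after_exhaustion(self):
        p = HaldaneParams(mu_max=0.2, Ks=0.01, Yx=0.5, maintenance_m=0.01)
        traj = simulate_heterotrophic(p, BatchState(0.0, 0.05, 0.3), 200.0, 1.0)
        assert traj.Ac[-1] == 0.0
        assert len(traj.solver_meta["clamp_events"]) == 1
        te = traj.solver_meta["clamp_events"][0]
        after = traj.times > te
        assert np.ptp(traj.X[after]) < 1e-9  # X frozen past exhaustion

    def test_lag_phase_holds_the_initial_state(self):
        p = HaldaneParams()
        traj = simulate_heterotrophic(p, BatchState(0.0, 0.05, 1.0), 40.0, 1.0, t_lag=10.0)
        early = traj.times <= 10.0
        assert np.all(traj.X[early] == 0.05)
        assert np.all(traj.Ac[early] == 1.0)
        assert traj.X[-1] > 0.05

    def test_euler_halving_converges_first_order(self):
        p = HaldaneParams(maintenance_m=0.0)
        x0 = BatchState(0.0, 0.05, 1.0)
        ref = simulate_heterotrophic(p, x0, 60.0, 0.5)  # adaptive reference
        errs = []
        for dt in (2.0, 1.0, 0.5):
            e = simulate_heterotrophic(p, x0, 60.0, dt, method="euler")
            errs.append(np.max(np.abs(e.X - ref.interp(e.times)["X"])))
        assert 1.5 < errs[0] / errs[1] < 2.5
        assert 1.5 < errs[1] / errs[2] < 2.5

    @pytest.mark.parametrize("seed", range(5))
    def test_states_stay_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        p = HaldaneParams(
            mu_max=float(rng.uniform(0.02, 0.5)),
            Ks=float(rng.uniform(0.01, 1.0)),
            Ki=float(rng.uniform(1.0, 50.0)),
            Yx=float(rng.uniform(0.2, 1.0)),
            maintenance_m=float(rng.uniform(0.0, 0.02)),
        )
        traj = simulate_heterotrophic(p, BatchState(0.0, 0.05, 2.0), 150.0, 0.5)
        assert np.all(traj.X >= 0)
        assert np.all(traj.Ac >= 0)


class TestMixotrophicSimulation:
    def test_two_first_integrals_without_transfer_or_maintenance(self):
        p = MixotrophicParams(kLa=0.0, maintenance_m=0.0)
        x0 = BatchState(0.0, 0.05, 1.0, C_DIC=0.05)
        traj = simulate_mixotrophic(p, x0, t_end=10.0, dt=0.1)
        assert traj.Ac[-1] > 0 and traj.C_DIC[-1] > 0  # pre-exhaustion window
        inv1 = traj.X + p.Yx * traj.Ac
        inv2 = traj.X + p.Mx * traj.C_DIC
        assert np.max(np.abs(inv1 - inv1[0])) < 1e-6
        assert np.max(np.abs(inv2 - inv2[0])) < 1e-6

    def test_pinned_dic_reduces_to_scaled_heterotrophic_model(self):
        dic = 0.02
        p = MixotrophicParams(mu_max=0.1, Ks_Ac=0.05, Ki_Ac=math.inf,
                              Ks_DIC=1e-3, Ki_DIC=math.inf, Yx=0.5,
                              maintenance_m=0.0, Mx=1e12, kLa=0.0)
        factor = dic / (p.Ks_DIC + dic)
        h = HaldaneParams(mu_max=p.mu_max * factor, Ks=p.Ks_Ac, Ki=math.inf,
                          Yx=0.5, maintenance_m=0.0)
        x0 = BatchState(0.0, 0.05, 1.0, C_DIC=dic)
        mixo = simulate_mixotrophic(p, x0, 80.0, 0.5)
        hetero = simulate_heterotrophic(h, BatchState(0.0, 0.05, 1.0), 80.0, 0.5)
        assert np.max(np.abs(mixo.X - hetero.X)) < 1e-5
        assert np.max(np.abs(mixo.Ac - hetero.Ac)) < 1e-5

    def test_dead_culture_relaxes_dic_to_gas_equilibrium(self):
        p = MixotrophicParams(kLa=2.0)
        eq_co2 = p.P / p.H_co2 * p.y_out_co2
        denom = 1.0 + p.K1 * 10**p.pH + p.K1 * p.K2 * 10 ** (2 * p.pH)
        eq_dic = eq_co2 * denom  # speciation inverted at fixed pH
        x0 = BatchState(0.0, 0.0, 0.5, C_DIC=0.0)
        traj = simulate_mixotrophic(p, x0, 80.0, 0.5)
        assert np.all(traj.X == 0.0)
        assert np.all(np.diff(traj.C_DIC) >= -1e-9)  # monotone up to solver noise
        assert traj.C_DIC[-1] == pytest.approx(eq_dic, rel=1e-3)

    def test_requires_dic_in_initial_state(self):
        with pytest.raises(ValueError):
            simulate_mixotrophic(MixotrophicParams(), BatchState(0.0, 0.1, 1.0), 10.0, 0.5)


def test_batch_state_rejects_negative_values():
    with pytest.raises(ValueError):
        BatchState(t=0.0, X=-0.1, Ac=1.0)
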