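"""SOA dynamic FBA: kinetic bounds, Euler updates, convergence, diauxie."""

import math

import numpy as np
import pytest

from chlamydyn import (
    BatchState,
    ConfigurationError,
    DFBAConfig,
    FBAProblem,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    UptakeKinetics,
    apply_condition,
    condition_preset,
    convergence_study,
    demo_dfba_config,
    kinetic_bounds,
    matched_haldane_params,
    run_dfba,
    simulate_heterotrophic,
    yield_coupled_toy,
)
from chlamydyn.synth import ACETATE_MW


def _toy_config(G=100, ac0=1.0, vmax=2.0, Ks=0.1, Ki=math.inf, tf=10.0):
    return DFBAConfig(
        t0=0.0, tf=tf, G=G, X0=0.05, z0={"acetate": ac0},
        tracked_exchanges={"EX_ac_e": "acetate"},
        kinetics={"acetate": UptakeKinetics(vmax=vmax, Ks=Ks, Ki=Ki)},
        species_mw={"acetate": ACETATE_MW},
    )


class TestKineticBounds:
    def test_zero_concentration_forbids_uptake(self):
        problem = FBAProblem(network=yield_coupled_toy())
        cfg = _toy_config()
        bounds = kinetic_bounds((0.1, {"acetate": 0.0}), cfg, problem)
        assert bounds["EX_ac_e"][0] == 0.0

    def test_half_saturation_gives_half_capacity(self):
        problem = FBAProblem(network=yield_coupled_toy())
        cfg = _toy_config(vmax=2.0, Ks=0.1)
        bounds = kinetic_bounds((0.1, {"acetate": 0.1}), cfg, problem)
        assert bounds["EX_ac_e"][0] == pytest.approx(-1.0)

    def test_bound_is_unimodal_with_peak_at_sqrt_ks_ki(self):
        cfg = _toy_config(vmax=5.0, Ks=0.2, Ki=5.0)
        problem = FBAProblem(network=yield_coupled_toy())
        grid = np.linspace(1e-4, 20, 5000)
        caps = np.array([
            -kinetic_bounds((0.1, {"acetate": float(a)}), cfg, problem)["EX_ac_e"][0]
            for a in grid
        ])
        peak = grid[np.argmax(caps)]
        assert peak == pytest.approx(math.sqrt(0.2 * 5.0), rel=1e-2)
        k = int(np.argmax(caps))
        assert np.all(np.diff(caps[:k]) >= -1e-12)
        assert np.all(np.diff(caps[k:]) <= 1e-12)

    def test_unmapped_species_is_a_configuration_error(self):
        problem = FBAProblem(network=yield_coupled_toy())
        with pytest.raises(ConfigurationError, match="glucose"):
            DFBAConfig(
                t0=0, tf=1, G=1, X0=0.1, z0={"glucose": 1.0},
                tracked_exchanges={"EX_ac_e": "acetate"},
            )
        cfg = _toy_config()
        cfg.kinetics["acetate"] = UptakeKinetics(vmax=1, Ks=0.1, inhibitor="urea",
                                                 K_inhibit=0.1)
        with pytest.raises(ConfigurationError, match="urea"):
            kinetic_bounds((0.1, {"acetate": 1.0}), cfg, problem)


class TestRunDFBA:
    def test_matches_ode_oracle_on_yield_coupled_toy(self):
        a = 2.0
        net = yield_coupled_toy(a)
        up = UptakeKinetics(vmax=2.0, Ks=0.1)
        cfg = _toy_config(G=800)
        traj = run_dfba(FBAProblem(network=net), cfg)
        ode = simulate_heterotrophic(matched_haldane_params(up, a),
                                     BatchState(0.0, 0.05, 1.0), 10.0, 0.05)
        rel = np.max(np.abs(traj.X - ode.interp(traj.times)["X"])) / ode.X.max()
        assert rel < 0.02

    def test_empty_medium_flatlines_and_arrests(self):
        cfg = _toy_config(ac0=0.0)
        traj = run_dfba(FBAProblem(network=yield_coupled_toy()), cfg)
        assert traj.termination == "growth_arrested"
        assert np.all(traj.X == traj.X[0])
        assert np.all(traj.mu == 0.0)

    def test_mass_consistency_first_order_in_dt(self):
        """X + (yield-equivalent of acetate) drifts O(dt) along the run."""
        a = 2.0
        Yx = 1000.0 / (a * ACETATE_MW)
        drifts = []
        for G in (50, 100, 200):
            traj = run_dfba(FBAProblem(network=yield_coupled_toy(a)), _toy_config(G=G))
            inv = traj.X + Yx * traj.z["acetate"]
            drifts.append(np.max(np.abs(inv - inv[0])))
        assert drifts[2] < drifts[0]
        assert drifts[0] / drifts[2] > 2.0  # roughly first order

    def test_biomass_never_decreases(self):
        traj = run_dfba(FBAProblem(network=yield_coupled_toy()), _toy_config(G=200))
        assert np.all(np.diff(traj.X) >= -1e-12)

    def test_identical_runs_are_bit_identical(self):
        p = FBAProblem(network=yield_coupled_toy())
        t1 = run_dfba(p, _toy_config(G=64))
        t2 = run_dfba(p, _toy_config(G=64))
        assert np.array_equal(t1.X, t2.X)
        assert np.array_equal(t1.z["acetate"], t2.z["acetate"])
        assert np.array_equal(t1.mu, t2.mu)

    def test_structurally_infeasible_interval_terminates_with_index(self):
        # forced uptake into a dead end: infeasible even at zero growth
        mets = [Metabolite(id="A_e"), Metabolite(id="B_c")]
        rxns = [
            Reaction(id="EX_A", stoichiometry={"A_e": -1.0},
                     lower_bound=-5.0, upper_bound=-5.0),
            Reaction(id="B", stoichiometry={"B_c": -1.0}, lower_bound=0.0,
                     category="biomass"),
        ]
        net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id="B")
        net.infer_categories()
        cfg = DFBAConfig(t0=0, tf=1, G=4, X0=0.1, z0={"acetate": 1.0},
                         tracked_exchanges={"EX_A": "acetate"},
                         species_mw={"acetate": ACETATE_MW})
        # keep the forced uptake: the kinetic bound may not relax lb=ub=-5
        cfg.kinetics = {}
        traj = run_dfba(FBAProblem(network=net), cfg)
        assert traj.termination == "infeasible_at"
        assert traj.infeasible_index == 0


class TestConvergenceStudy:
    def test_error_halves_per_doubling_of_g(self):
        a = 2.0
        up = UptakeKinetics(vmax=2.0, Ks=0.1)
        ode = simulate_heterotrophic(matched_haldane_params(up, a),
                                     BatchState(0.0, 0.05, 1.0), 10.0, 0.02)
        table = convergence_study(FBAProblem(network=yield_coupled_toy(a)),
                                  _toy_config(), [25, 50, 100, 200], ode)
        assert np.all((table["ratio"].iloc[1:] > 1.5) & (table["ratio"].iloc[1:] < 2.5))
        assert not table["non_monotone"].iloc[1:].any()

    def test_reference_run_has_zero_error_against_itself(self):
        p = FBAProblem(network=yield_coupled_toy())
        ref = run_dfba(p, _toy_config(G=100))
        table = convergence_study(p, _toy_config(), [100], ref)
        assert table["error"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_diauxic_pattern_on_the_demo_network(demo):
    """Acetate is consumed first; inorganic-carbon uptake switches on only
    after acetate exhaustion, and growth continues on CO2."""
    cfg = demo_dfba_config()
    problem = apply_condition(demo, condition_preset("mixotrophic"))
    traj = run_dfba(problem, cfg)
    ac = traj.z["acetate"]
    assert np.all(np.diff(ac) <= 1e-12)  # monotone depletion
    exhausted = np.flatnonzero(ac <= 1e-9)
    assert exhausted.size > 0, "acetate never exhausted within the horizon"
    k = int(exhausted[0])
    co2 = np.array([s.fluxes["EX_co2_e"] for s in traj.flux_snapshots])
    assert abs(co2[0]) < 1.0  # CO2 barely used while acetate is abundant
    assert co2[k:].mean() < -10.0  # strong CO2 uptake afterwards
    assert traj.X[-1] > traj.X[k] * 1.05  # growth continues on CO2
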