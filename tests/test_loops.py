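"""Thermodynamically infeasible cycles: detection, null-space weights,
resolution policies."""

import numpy as np
import pytest

from chlamydyn import (
    CurationError,
    FBAProblem,
    FVAConfig,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    ToyNetworkSpec,
    detect_tics,
    generate_network,
    resolve_tics,
    run_fva,
    solve_fba,
)


def _net(mets, rxns, objective=None):
    net = MetabolicNetwork(metabolites=[Metabolite(id=m) for m in mets],
                           reactions=rxns, objective_id=objective)
    net.infer_categories()
    net.validate()
    return net


def _two_cycle():
    return _net(
        ["A_c", "B_c"],
        [
            Reaction(id="F", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0),
            Reaction(id="R", stoichiometry={"B_c": -1.0, "A_c": 1.0}, lower_bound=0.0),
        ],
    )


def test_reversible_pair_is_one_tic_with_unit_weights():
    tics = detect_tics(_two_cycle())
    assert len(tics) == 1
    assert set(tics[0].reaction_ids) == {"F", "R"}
    w = tics[0].weights
    assert abs(w[0]) == pytest.approx(abs(w[1]), abs=1e-10)


def test_three_cycle_weights_proportional_to_ones():
    net = _net(
        ["A_c", "B_c", "C_c"],
        [
            Reaction(id="AB", stoichiometry={"A_c": -1.0, "B_c": 1.0}),
            Reaction(id="BC", stoichiometry={"B_c": -1.0, "C_c": 1.0}),
            Reaction(id="CA", stoichiometry={"C_c": -1.0, "A_c": 1.0}),
        ],
    )
    tics = detect_tics(net)
    assert len(tics) == 1
    assert set(tics[0].reaction_ids) == {"AB", "BC", "CA"}
    w = tics[0].weights
    assert np.allclose(np.abs(w), np.abs(w[0]), atol=1e-10)


def test_acyclic_chain_is_loopless(demo):
    net = _net(
        ["A_c", "B_c", "C_c", "A_e", "C_e"],
        [
            Reaction(id="EX_A", stoichiometry={"A_e": -1.0}),
            Reaction(id="TA", stoichiometry={"A_e": -1.0, "A_c": 1.0}, lower_bound=0.0),
            Reaction(id="AB", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0),
            Reaction(id="BC", stoichiometry={"B_c": -1.0, "C_c": 1.0}, lower_bound=0.0),
            Reaction(id="TC", stoichiometry={"C_c": -1.0, "C_e": 1.0}, lower_bound=0.0),
            Reaction(id="EX_C", stoichiometry={"C_e": -1.0}),
        ],
    )
    assert detect_tics(net) == []
    assert detect_tics(demo) == []  # the curated demo network is loopless


@pytest.mark.parametrize("seed", range(10))
def test_null_space_weights_annihilate_the_submatrix(seed):
    spec = ToyNetworkSpec(inject_tics=(2, 3), seed=seed)
    net, _ = generate_network(spec)
    for tic in detect_tics(net):
        S_sub = net.stoichiometric_matrix(list(tic.reaction_ids))
        assert np.max(np.abs(S_sub @ tic.weights)) <= 1e-10


def test_detection_is_order_independent():
    spec = ToyNetworkSpec(inject_tics=(3, 2), seed=7)
    net, _ = generate_network(spec)
    supports = {frozenset(t.reaction_ids) for t in detect_tics(net)}
    shuffled = MetabolicNetwork(
        metabolites=list(reversed(net.metabolites)),
        reactions=list(reversed(net.reactions)),
        objective_id=net.objective_id,
    )
    shuffled.infer_categories()
    assert {frozenset(t.reaction_ids) for t in detect_tics(shuffled)} == supports


def test_duplicate_removal_resolves_a_duplicated_reaction():
    net = _net(
        ["A_c", "B_c"],
        [
            Reaction(id="R1", stoichiometry={"A_c": -1.0, "B_c": 1.0}),
            Reaction(id="R2", stoichiometry={"A_c": -1.0, "B_c": 1.0}),
        ],
    )
    cured, report = resolve_tics(net, policy=("duplicate_removal",))
    assert detect_tics(cured) == []
    assert [a for _, a, _ in report.actions] == ["duplicate_removal"]
    assert cured.n_reactions == 1
    assert report.final_null_space_dim == 0


def test_directionality_hint_fixes_a_wrongly_reversible_reaction():
    """Loop from a reaction that databases say is irreversible: the hint
    pins its lower bound at zero and the cycle disappears."""
    net = _net(
        ["A_c", "B_c"],
        [
            Reaction(id="GOOD", stoichiometry={"A_c": -1.0, "B_c": 2.0}, lower_bound=0.0),
            Reaction(id="WRONG", stoichiometry={"A_c": -1.0, "B_c": 2.0}),  # reversible
        ],
    )
    assert len(detect_tics(net)) == 1
    cured, report = resolve_tics(net, hints={"WRONG": "forward"},
                                 policy=("directionality_revision", "blocking"))
    # the hint alone must fix it: no blocking recorded
    dir_actions = [(r, a) for r, a, _ in report.actions]
    assert ("WRONG", "directionality_revision") in dir_actions
    assert all(a != "blocking" for _, a in dir_actions)
    assert detect_tics(cured) == []
    assert cured.reaction("WRONG").lower_bound == 0.0


def test_blocking_names_exactly_one_member_of_a_three_cycle():
    net = _net(
        ["A_c", "B_c", "C_c"],
        [
            Reaction(id="AB", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0),
            Reaction(id="BC", stoichiometry={"B_c": -1.0, "C_c": 1.0}, lower_bound=0.0),
            Reaction(id="CA", stoichiometry={"C_c": -1.0, "A_c": 1.0}, lower_bound=0.0),
        ],
    )
    cured, report = resolve_tics(net, policy=("blocking",))
    blocked = [r for r, a, _ in report.actions if a == "blocking"]
    assert len(blocked) == 1
    assert blocked[0] in {"AB", "BC", "CA"}
    assert detect_tics(cured) == []


def test_unresolvable_configuration_raises_with_surviving_cycles():
    net = _net(
        ["A_c", "B_c", "C_c"],
        [
            Reaction(id="AB", stoichiometry={"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0),
            Reaction(id="BC", stoichiometry={"B_c": -1.0, "C_c": 1.0}, lower_bound=0.0),
            Reaction(id="CA", stoichiometry={"C_c": -1.0, "A_c": 1.0}, lower_bound=0.0),
        ],
    )
    with pytest.raises(CurationError) as exc:
        resolve_tics(net, policy=("duplicate_removal",))
    assert len(exc.value.tics) == 1


@pytest.mark.parametrize("seed", range(5))
def test_curation_preserves_the_biomass_optimum(seed):
    """Planted cycles sit off the productive pathways, so removing them
    must not change the growth optimum."""
    spec = ToyNetworkSpec(inject_tics=(2, 3), seed=seed)
    net, _ = generate_network(spec)
    before = solve_fba(FBAProblem(network=net)).objective_value
    cured, _ = resolve_tics(net)
    after = solve_fba(FBAProblem(network=cured)).objective_value
    assert after == pytest.approx(before, abs=1e-6)


def test_loop_law_holds_after_curation():
    """In a curated network no internal flux range (exchanges closed)
    touches the +/-1000 default bound."""
    net, _ = generate_network(ToyNetworkSpec(inject_tics=(2, 3, 4), seed=11))
    cured, _ = resolve_tics(net)
    closed = {r.id: (0.0, 0.0) for r in cured.exchanges()}
    internal = [r.id for r in cured.internal_reactions()]
    fva = run_fva(
        FBAProblem(network=cured, objective={internal[0]: 1.0}, bound_overrides=closed),
        FVAConfig(fraction_of_optimum=0.0, reactions=internal),
    )
    for rid, (lo, hi) in fva.ranges.items():
        assert hi < 1000.0 - 1e-6, rid
        assert lo > -1000.0 + 1e-6, rid
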