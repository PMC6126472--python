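"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from chlamydyn import FBAProblem, MetabolicNetwork, Metabolite, Reaction, demo_network


@pytest.fixture(scope="session")
def demo():
    return demo_network()


def chain_network(uptake: float = 10.0) -> MetabolicNetwork:
    """EX_A -(uptake)-> A_e -> A_c -> B_c -> biomass; optimum = uptake."""
    mets = [Metabolite(id=m) for m in ("A_e", "A_c", "B_c")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A_e": -1.0},
                 lower_bound=-uptake, upper_bound=1000.0),
        Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="R1", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="BIOMASS", stoichiometry={"B_c": -1.0},
                 lower_bound=0.0, upper_bound=1000.0, category="biomass"),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id="BIOMASS")
    net.infer_categories()
    net.validate()
    return net


def vertex_enumeration_optimum(problem: FBAProblem) -> float | None:
    """Brute-force LP oracle: enumerate the vertices of {v : Sv=0, lb<=v<=ub}.

    A vertex pins at least n - rank(S) variables at a bound; the rest are
    solved from Sv = 0.  Independent of the HiGHS solve path.  Returns the
    maximal objective over feasible vertices, or None if no vertex is
    feasible.  Only practical for a handful of free dimensions.
    """
    S = problem.network.stoichiometric_matrix()
    lb, ub = problem.effective_bounds()
    c = problem.objective_vector()
    m, n = S.shape
    r = np.linalg.matrix_rank(S, tol=1e-10)
    d = n - r
    if d > 8:
        raise ValueError(f"too many free dimensions for enumeration: {d}")

    best = None
    for pinned in combinations(range(n), d):
        pinned = list(pinned)
        free = [j for j in range(n) if j not in pinned]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free, tol=1e-10) < len(free):
            continue
        for sides in product((0, 1), repeat=d):
            v = np.zeros(n)
            for j, side in zip(pinned, sides):
                v[j] = ub[j] if side else lb[j]
            rhs = -S[:, pinned] @ v[pinned]
            sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best
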