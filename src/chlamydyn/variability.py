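"""Flux variability analysis and blocked-reaction detection.

FVA maximizes and minimizes each reaction flux in turn, subject to the
steady-state and bound constraints, with the biomass flux pinned at a
fraction f of its FBA maximum.  A fraction of 0 leaves biomass free — the
medium alone constrains the network — which is the setting for blocked-
reaction detection: a reaction is blocked when both its minimum and maximum
flux are zero under the examined condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .fba import FBAProblem, FEASIBILITY_TOL, solve_fba

__all__ = ["FVAConfig", "FVAResult", "FVAError", "run_fva", "find_blocked"]


class FVAError(RuntimeError):
    """FVA could not be run (e.g. infeasible after fixing biomass)."""


@dataclass
class FVAConfig:
    """fraction_of_optimum is the f in v_biomass = f * v_biomass_max; an
    optional reaction subset restricts which ranges are computed."""

    fraction_of_optimum: float = 1.0
    reactions: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_of_optimum <= 1.0:
            raise ValueError("fraction_of_optimum must be in [0, 1]")


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    biomass_fixed_at: float | None = None

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]


def _minmax(S: np.ndarray, bounds: list, j: int, n: int) -> tuple[float, float]:
    out = []
    for sense in (1.0, -1.0):
        c = np.zeros(n)
        c[j] = sense  # +1 minimizes, -1 maximizes v_j
        res = linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs",
            options={
                "primal_feasibility_tolerance": FEASIBILITY_TOL,
                "dual_feasibility_tolerance": FEASIBILITY_TOL,
            },
        )
        if res.status != 0:
            raise FVAError(f"LP for reaction index {j} returned status {res.status}")
        out.append(sense * res.fun)
    vmin, vmax = out
    return min(vmin, vmax), max(vmin, vmax)


def run_fva(problem: FBAProblem, config: FVAConfig | None = None) -> FVAResult:
    """Per-reaction flux ranges with biomass fixed at f times its optimum.

    With f > 0 the biomass flux is pinned (equality) at f * optimum for all
    2n LPs; with f = 0 biomass is unconstrained.  Raises FVAError if the
    problem is infeasible, or infeasible after fixing biomass.
    """
    config = config or FVAConfig()
    network = problem.network
    lb, ub = problem.effective_bounds()

    fixed_at = None
    if config.fraction_of_optimum > 0.0:
        sol = solve_fba(problem)
        if sol.status != "optimal":
            raise FVAError(f"FBA is {sol.status}; cannot fix biomass for FVA")
        fixed_at = config.fraction_of_optimum * sol.objective_value
        for rid, w in problem.objective.items():
            if w:
                j = network.rxn_index[rid]
                lb[j] = ub[j] = fixed_at / w
    S = network.stoichiometric_matrix()
    bounds = list(zip(lb, ub))

    targets = config.reactions or [r.id for r in network.reactions]
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = network.rxn_index[rid]
        try:
            ranges[rid] = _minmax(S, bounds, j, network.n_reactions)
        except FVAError as exc:
            raise FVAError(
                f"FVA infeasible for {rid!r} with biomass fixed at {fixed_at}: {exc}"
            ) from exc
    return FVAResult(ranges=ranges, biomass_fixed_at=fixed_at)


def find_blocked(result: FVAResult, tolerance: float = 1e-9) -> set[str]:
    """Reactions whose flux range is (0, 0) within ``tolerance``.

    Meaningful when the FVA was run with fraction_of_optimum 0: blocked
    means blocked under the medium, not at the growth optimum.
    """
    return {
        rid
        for rid, (lo, hi) in result.ranges.items()
        if abs(lo) <= tolerance and abs(hi) <= tolerance
    }
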