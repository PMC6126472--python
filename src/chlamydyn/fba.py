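"""Steady-state flux balance analysis.

Solves max c'v subject to S v = 0, LB <= v <= UB with the HiGHS LP solver.
Sign convention, used everywhere in this package: exchange flux < 0 is
uptake (an allowed uptake of 12 mmol/gDW/h means the exchange lower bound is
-12), flux > 0 is secretion.

Growth-condition presets encode the three *C. reinhardtii* setups:
photoautotrophic (CO2 + light, mitochondrial ATP production blocked),
heterotrophic (acetate only, chloroplast ATP production blocked) and
mixotrophic (both substrates, nothing blocked).  The ids of the exchange and
ATP-production reactions are configuration, not constants: genome-scale
reconstructions each use their own namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = [
    "FBAProblem",
    "FluxDistribution",
    "ConditionPreset",
    "ConfigurationError",
    "condition_preset",
    "apply_condition",
    "solve_fba",
    "FEASIBILITY_TOL",
]

#: LP feasibility/optimality tolerance passed to HiGHS
FEASIBILITY_TOL = 1e-9


class ConfigurationError(KeyError):
    """A preset or override names a reaction the network does not contain."""


@dataclass
class FBAProblem:
    """A network plus objective weights, bound overrides and blocked reactions."""

    network: MetabolicNetwork
    objective: dict[str, float] | None = None
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    blocked_reactions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.objective is None:
            if self.network.objective_id is None:
                raise ValueError("network has no objective reaction and none was given")
            self.objective = {self.network.objective_id: 1.0}
        for rid in list(self.objective) + list(self.bound_overrides) + list(self.blocked_reactions):
            if rid not in self.network.rxn_index:
                raise ConfigurationError(f"unknown reaction id {rid!r}")
        for rid, (lb, ub) in self.bound_overrides.items():
            if lb > ub:
                raise ValueError(f"override for {rid!r} has lower {lb} > upper {ub}")

    def effective_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-reaction (lower, upper) after overrides and blocks."""
        lb = np.array([r.lower_bound for r in self.network.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.network.reactions], dtype=float)
        idx = self.network.rxn_index
        for rid, (lo, hi) in self.bound_overrides.items():
            lb[idx[rid]], ub[idx[rid]] = lo, hi
        for rid in self.blocked_reactions:
            lb[idx[rid]] = ub[idx[rid]] = 0.0
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.network.n_reactions)
        for rid, w in self.objective.items():
            c[self.network.rxn_index[rid]] = w
        return c

    def with_overrides(self, extra: dict[str, tuple[float, float]]) -> "FBAProblem":
        return replace(self, bound_overrides={**self.bound_overrides, **extra})


@dataclass
class FluxDistribution:
    """Outcome of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def solve_fba(problem: FBAProblem) -> FluxDistribution:
    """Maximize the objective over {v : S v = 0, LB <= v <= UB}.

    Returns status "optimal" with the LP maximum (unique even when the flux
    vector is not), "infeasible", or "unbounded" with a diagnostic listing
    reactions with infinite effective bounds (the candidate unbounded rays).
    Individual fluxes of an optimal solution are one vertex of the alternate
    optima; only the objective value is contractual.
    """
    S = problem.network.stoichiometric_matrix()
    lb, ub = problem.effective_bounds()
    c = problem.objective_vector()
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={
            "primal_feasibility_tolerance": FEASIBILITY_TOL,
            "dual_feasibility_tolerance": FEASIBILITY_TOL,
        },
    )
    if res.status == 2:
        return FluxDistribution("infeasible", None, message=res.message)
    if res.status == 3:
        rays = [
            r.id
            for r, lo, hi in zip(problem.network.reactions, lb, ub)
            if np.isinf(lo) or np.isinf(hi)
        ]
        return FluxDistribution(
            "unbounded", None,
            message=f"objective unbounded; reactions with infinite bounds: {rays}",
        )
    if res.status != 0:
        return FluxDistribution("infeasible", None, message=res.message)
    fluxes = {r.id: v for r, v in zip(problem.network.reactions, res.x)}
    return FluxDistribution("optimal", -res.fun, fluxes=fluxes)


@dataclass
class ConditionPreset:
    """Exchange bounds and ATP-production blocking rules for one growth
    condition.  Bounds are (lower, upper) in mmol/gDW/h, uptake negative."""

    name: str
    co2_exchange: tuple[float, float]
    acetate_exchange: tuple[float, float]
    light_exchange: tuple[float, float]
    atp_mito_blocked: bool
    atp_chloro_blocked: bool
    # reaction ids — configuration, defaulting to this package's demo namespace
    co2_id: str = "EX_co2_e"
    acetate_id: str = "EX_ac_e"
    light_id: str = "EX_photon_e"
    atp_mito_id: str = "ATPM_MITO"
    atp_chloro_id: str = "ATPS_CHLORO"


def condition_preset(name: str, **overrides) -> ConditionPreset:
    """Standard presets for the three growth conditions.

    Input fluxes follow the reported setups: photoautotrophic CO2 uptake up
    to 12, heterotrophic acetate uptake up to 10, mixotrophic both.  Light is
    left unconstrained where present (its magnitude is experiment-specific
    and configurable); heterotrophic cultures are dark, so light is closed.
    Keyword overrides replace any field (typically the reaction ids).
    """
    presets = {
        "photoautotrophic": ConditionPreset(
            name="photoautotrophic",
            co2_exchange=(-12.0, 1000.0),
            acetate_exchange=(0.0, 0.0),
            light_exchange=(-1000.0, 0.0),
            atp_mito_blocked=True,
            atp_chloro_blocked=False,
        ),
        "heterotrophic": ConditionPreset(
            name="heterotrophic",
            co2_exchange=(0.0, 1000.0),
            acetate_exchange=(-10.0, 1000.0),
            light_exchange=(0.0, 0.0),
            atp_mito_blocked=False,
            atp_chloro_blocked=True,
        ),
        "mixotrophic": ConditionPreset(
            name="mixotrophic",
            co2_exchange=(-12.0, 1000.0),
            acetate_exchange=(-10.0, 1000.0),
            light_exchange=(-1000.0, 0.0),
            atp_mito_blocked=False,
            atp_chloro_blocked=False,
        ),
    }
    aliases = {"photo": "photoautotrophic", "hetero": "heterotrophic", "mixo": "mixotrophic"}
    key = aliases.get(name, name)
    if key not in presets:
        raise ValueError(f"unknown condition {name!r}")
    preset = presets[key]
    for k, v in overrides.items():
        if not hasattr(preset, k):
            raise TypeError(f"ConditionPreset has no field {k!r}")
        setattr(preset, k, v)
    return preset


def apply_condition(network: MetabolicNetwork, preset: ConditionPreset) -> FBAProblem:
    """Build the FBA problem for a growth condition.

    Exchange bounds are set uptake-negative; the ATP-production reactions
    named by the preset are added to the blocked set when the condition
    requires it.  A missing reaction id raises ConfigurationError naming it.
    """
    overrides: dict[str, tuple[float, float]] = {}
    for rid, bounds in [
        (preset.co2_id, preset.co2_exchange),
        (preset.acetate_id, preset.acetate_exchange),
        (preset.light_id, preset.light_exchange),
    ]:
        if rid not in network.rxn_index:
            raise ConfigurationError(
                f"condition {preset.name!r}: exchange reaction {rid!r} not in network"
            )
        overrides[rid] = bounds
    blocked: set[str] = set()
    for flag, rid, what in [
        (preset.atp_mito_blocked, preset.atp_mito_id, "mitochondrial ATP production"),
        (preset.atp_chloro_blocked, preset.atp_chloro_id, "chloroplast ATP production"),
    ]:
        if flag:
            if rid not in network.rxn_index:
                raise ConfigurationError(
                    f"condition {preset.name!r}: {what} reaction {rid!r} not in network"
                )
            blocked.add(rid)
    return FBAProblem(network=network, bound_overrides=overrides, blocked_reactions=blocked)
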