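"""Phenotype phase planes: FBA growth rate over a grid of two fixed fluxes.

Each grid cell fixes both axis reactions to exact values (lower = upper,
the phenotype-phase-plane convention) and records the biomass optimum;
infeasible cells are masked, not errors.  Typical axes are substrate
exchanges (acetate vs CO2 uptake) or a substrate against an ATP-producing
reaction, reproducing growth response surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label

from .fba import ConditionPreset, ConfigurationError, FBAProblem, apply_condition, solve_fba
from .network import MetabolicNetwork

__all__ = ["ScanSpec", "ScanResult", "ScanOptimum", "scan", "summarize_optimum"]


@dataclass
class ScanSpec:
    """Two scan axes (reaction id, lower, upper, n_points >= 2), an optional
    growth-condition preset, and extra fixed bound overrides."""

    axis1: tuple[str, float, float, int]
    axis2: tuple[str, float, float, int]
    condition: ConditionPreset | None = None
    fixed_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for axis in (self.axis1, self.axis2):
            rid, lo, hi, n = axis
            if n < 2:
                raise ValueError(f"axis {rid!r} needs at least 2 points")
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"axis {rid!r} range must be finite")


@dataclass
class ScanResult:
    grid1: np.ndarray
    grid2: np.ndarray
    mu: np.ndarray  # shape (len(grid1), len(grid2)); NaN where infeasible
    infeasible_mask: np.ndarray
    axis_ids: tuple[str, str] = ("", "")


@dataclass
class ScanOptimum:
    argmax_cells: list[tuple[int, int]]
    max_mu: float
    plateau_mask: np.ndarray


def scan(network: MetabolicNetwork, spec: ScanSpec) -> ScanResult:
    """Evaluate the growth optimum on the spec's grid."""
    if spec.condition is not None:
        base = apply_condition(network, spec.condition)
        base = base.with_overrides(spec.fixed_overrides)
    else:
        base = FBAProblem(network=network, bound_overrides=dict(spec.fixed_overrides))
    for rid in (spec.axis1[0], spec.axis2[0]):
        if rid not in network.rxn_index:
            raise ConfigurationError(f"scan axis reaction {rid!r} not in network")

    id1, lo1, hi1, n1 = spec.axis1
    id2, lo2, hi2, n2 = spec.axis2
    grid1 = np.linspace(lo1, hi1, n1)
    grid2 = np.linspace(lo2, hi2, n2)
    mu = np.full((n1, n2), np.nan)
    infeasible = np.zeros((n1, n2), dtype=bool)
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            sol = solve_fba(base.with_overrides({id1: (v1, v1), id2: (v2, v2)}))
            if sol.status == "optimal":
                mu[i, j] = sol.objective_value
            else:
                infeasible[i, j] = True
    return ScanResult(grid1=grid1, grid2=grid2, mu=mu, infeasible_mask=infeasible,
                      axis_ids=(id1, id2))


def summarize_optimum(result: ScanResult, tolerance: float = 1e-6) -> ScanOptimum:
    """Maximizing cell(s) and the connected plateau around them.

    All feasible cells within ``tolerance`` of the maximum are maximizers;
    the plateau is their 4-connected component(s) containing a maximizer.
    Raises ValueError if every cell is infeasible.
    """
    feasible = ~result.infeasible_mask
    if not feasible.any():
        raise ValueError("all scan cells are infeasible")
    max_mu = float(np.nanmax(result.mu))
    at_max = feasible & (result.mu >= max_mu - tolerance)
    cells = [tuple(map(int, ij)) for ij in np.argwhere(at_max)]
    labels, _ = label(at_max)
    keep = {labels[ij] for ij in cells}
    plateau = np.isin(labels, sorted(keep)) & at_max
    return ScanOptimum(argmax_cells=cells, max_mu=max_mu, plateau_mask=plateau)
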