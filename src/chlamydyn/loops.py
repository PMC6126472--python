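"""Detection and resolution of thermodynamically infeasible cycles (TICs).

The loop law: around a closed cycle the thermodynamic driving forces sum to
zero, so no net steady-state flux can circulate.  A stoichiometrically
balanced internal cycle violates it whenever the LP lets the cycle spin at
the artificial +/-1000 mmol/gDW/h bounds.

Detection closes every exchange reaction (so any surviving flux is
necessarily cyclic), runs FVA over the internal reactions, flags those whose
range touches the default bound (and spans more than 1e-6), assembles the
stoichiometric submatrix over the flagged reactions, and reads each
independent null-space basis vector — the weights alpha with S_sub @ alpha
= 0 — as one cycle.  Resolution applies, in a configurable order,
directionality revision (from a hint table), removal of duplicated
reactions, and as a last resort blocking of a cycle member, re-detecting
between iterations until the null space is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .fba import FBAProblem
from .network import MetabolicNetwork, duplicate_key
from .variability import FVAConfig, run_fva

__all__ = [
    "TIC",
    "CurationReport",
    "CurationError",
    "detect_tics",
    "resolve_tics",
]

ACTIONS = ("directionality_revision", "duplicate_removal", "blocking")
_RANGE_TOL = 1e-6  # flagged ranges must differ by more than this
_SV_CUTOFF = 1e-10  # singular-value cutoff, relative to the largest
_SUPPORT_TOL = 1e-9  # weight magnitude below which a reaction is not in the cycle


@dataclass
class TIC:
    """One thermodynamically infeasible cycle: the reactions involved and
    the null-space weights alpha such that S restricted to them maps alpha
    to zero."""

    reaction_ids: tuple[str, ...]
    weights: np.ndarray
    resolved_by: str | None = None


@dataclass
class CurationReport:
    iterations: int = 0
    tics_found_per_iteration: list[int] = field(default_factory=list)
    actions: list[tuple[str, str, str]] = field(default_factory=list)  # (rxn, action, rationale)
    final_null_space_dim: int = 0


class CurationError(RuntimeError):
    def __init__(self, message: str, tics: list[TIC]):
        super().__init__(message)
        self.tics = tics


def _connected_components(network: MetabolicNetwork, rxn_ids: list[str]) -> list[list[str]]:
    """Group reactions sharing a metabolite (union-find over the candidates)."""
    parent = {r: r for r in rxn_ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    by_met: dict[str, str] = {}
    for rid in rxn_ids:
        for met in network.reaction(rid).stoichiometry:
            if met in by_met:
                ra, rb = find(by_met[met]), find(rid)
                if ra != rb:
                    parent[ra] = rb
            else:
                by_met[met] = rid
    groups: dict[str, list[str]] = {}
    for rid in rxn_ids:
        groups.setdefault(find(rid), []).append(rid)
    return list(groups.values())


def detect_tics(network: MetabolicNetwork) -> list[TIC]:
    """Find all thermodynamically infeasible cycles; empty list = loopless.

    Exchange reactions are excluded as candidates and closed during the FVA,
    so a nonzero range can only come from an internal cycle.  The null space
    is computed per connected component of the flagged submatrix (SVD,
    singular values below 1e-10 of the largest treated as zero), so disjoint
    cycles are reported separately.
    """
    network = network.copy()
    network.infer_categories()
    internal = [r.id for r in network.internal_reactions()]
    if not internal:
        return []
    closed = {r.id: (0.0, 0.0) for r in network.exchanges()}
    problem = FBAProblem(
        network=network,
        objective={internal[0]: 1.0},  # placeholder; fraction 0 ignores it
        bound_overrides=closed,
    )
    fva = run_fva(problem, FVAConfig(fraction_of_optimum=0.0, reactions=internal))

    bound = network.default_bound
    flagged = [
        rid
        for rid, (lo, hi) in fva.ranges.items()
        if (hi >= bound - _RANGE_TOL or lo <= -bound + _RANGE_TOL)
        and (hi - lo) > _RANGE_TOL
    ]
    if not flagged:
        return []

    tics: list[TIC] = []
    for group in _connected_components(network, sorted(flagged)):
        group = sorted(group)
        S_sub = network.stoichiometric_matrix(group)
        basis = null_space(S_sub, rcond=_SV_CUTOFF)
        for k in range(basis.shape[1]):
            w = basis[:, k]
            support = np.abs(w) > _SUPPORT_TOL * max(np.abs(w).max(), 1.0)
            ids = tuple(rid for rid, s in zip(group, support) if s)
            if ids:
                tics.append(TIC(reaction_ids=ids, weights=w[support]))
    return tics


def _null_dim(network: MetabolicNetwork, tics: list[TIC]) -> int:
    ids = sorted({r for t in tics for r in t.reaction_ids})
    if not ids:
        return 0
    return null_space(network.stoichiometric_matrix(ids), rcond=_SV_CUTOFF).shape[1]


def resolve_tics(
    network: MetabolicNetwork,
    tics: list[TIC] | None = None,
    policy: tuple[str, ...] = ACTIONS,
    hints: dict[str, str] | None = None,
    max_iterations: int = 100,
) -> tuple[MetabolicNetwork, CurationReport]:
    """Iteratively remove all TICs from a copy of the network.

    ``policy`` is an ordered subset of {directionality_revision,
    duplicate_removal, blocking}; each iteration applies the first action
    type with an applicable change, then re-detects.  ``hints`` maps a
    reaction id to its database-supported direction ("forward" -> lower
    bound 0, "reverse" -> upper bound 0).  Blocking picks the reaction in
    the smallest cycle (ties by id) to minimize collateral damage.

    Returns the curated network and a report; raises CurationError (carrying
    the surviving cycles) when TICs remain but no action applies.
    """
    for action in policy:
        if action not in ACTIONS:
            raise ValueError(f"unknown curation action {action!r}")
    hints = hints or {}
    net = network.copy()
    report = CurationReport()
    applied_hints: set[str] = set()

    current = detect_tics(net) if tics is None else list(tics)
    for _ in range(max_iterations):
        report.iterations += 1
        report.tics_found_per_iteration.append(len(current))
        if not current:
            report.final_null_space_dim = 0
            return net, report

        acted = False
        for action in policy:
            if action == "directionality_revision":
                for tic in current:
                    for rid in tic.reaction_ids:
                        if rid in hints and rid not in applied_hints:
                            rxn = net.reaction(rid)
                            if hints[rid] == "forward" and rxn.lower_bound < 0:
                                rxn.lower_bound = 0.0
                            elif hints[rid] == "reverse" and rxn.upper_bound > 0:
                                rxn.upper_bound = 0.0
                            else:
                                continue
                            applied_hints.add(rid)
                            report.actions.append(
                                (rid, action, f"database direction: {hints[rid]}")
                            )
                            acted = True
            elif action == "duplicate_removal":
                in_cycles = sorted({r for t in current for r in t.reaction_ids})
                keys: dict[tuple, str] = {}
                for rxn in net.reactions:
                    k = duplicate_key(rxn)
                    keep = keys.get(k)
                    if keep is None:
                        keys[k] = rxn.id
                        continue
                    if rxn.id in in_cycles or keep in in_cycles:
                        drop = max(keep, rxn.id)
                        keys[k] = min(keep, rxn.id)
                        net.remove_reaction(drop)
                        report.actions.append(
                            (drop, action, f"duplicate of {keys[k]} (possibly reversed)")
                        )
                        acted = True
            elif action == "blocking":
                smallest: dict[str, int] = {}
                for tic in current:
                    for rid in tic.reaction_ids:
                        size = len(tic.reaction_ids)
                        smallest[rid] = min(smallest.get(rid, size), size)
                victim = min(smallest, key=lambda r: (smallest[r], r))
                rxn = net.reaction(victim)
                rxn.lower_bound = rxn.upper_bound = 0.0
                report.actions.append(
                    (victim, action, f"member of a {smallest[victim]}-reaction cycle")
                )
                acted = True
            if acted:
                break

        if not acted:
            report.final_null_space_dim = _null_dim(net, current)
            raise CurationError(
                f"{len(current)} cycle(s) remain but no action in {policy} applies",
                current,
            )
        current = detect_tics(net)

    report.final_null_space_dim = _null_dim(net, current)
    if current:
        raise CurationError("iteration limit reached with cycles remaining", current)
    return net, report
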