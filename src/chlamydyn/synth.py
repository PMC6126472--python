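"""Synthetic networks and growth curves for offline testing and validation.

Toy networks have a feasible linear "spine" (substrate uptake -> central
chain -> biomass drain) plus seeded random branches, with optionally
planted thermodynamically infeasible cycles (on fresh metabolites, so they
never carry productive flux) and orphan dead-end reactions.  Every
generator is deterministic for a seed and returns a ground-truth manifest
naming what was planted.

Synthetic batch curves are simulated with the kinetics module, sampled at
regular time points and corrupted with mean-one multiplicative lognormal
noise (concentration errors are positive and roughly proportional).

``demo_network`` is a hand-built 11-reaction mixotrophic toy used by the
examples: acetate assimilation yields carbon and ATP (the "mitochondrial"
route), photons drive chloroplast ATP synthesis and CO2 fixation, and the
three growth-condition presets reproduce the qualitative ordering
photoautotrophic < heterotrophic < mixotrophic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .dfba import DFBAConfig, UptakeKinetics
from .kinetics import (
    BatchState,
    HaldaneParams,
    MixotrophicParams,
    simulate_heterotrophic,
    simulate_mixotrophic,
)
from .network import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "ToyNetworkSpec",
    "CurveSpec",
    "generate_network",
    "generate_curves",
    "demo_network",
    "demo_dfba_config",
    "yield_coupled_toy",
    "matched_haldane_params",
    "ACETATE_MW",
]

ACETATE_MW = 60.052  # g/mol


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Recipe for a seeded toy network.

    ``inject_tics`` lists the sizes of cycles to plant (e.g. ``(2, 3)``);
    ``inject_orphans`` counts dead-end reactions to plant; branches are
    extra random forward conversions that keep the spine acyclic.
    """

    n_core_metabolites: int = 5
    n_exchanges: int = 1
    n_branches: int = 2
    biomass_precursors: tuple[tuple[str, float], ...] | None = None
    inject_tics: tuple[int, ...] = ()
    inject_orphans: int = 0
    uptake_bound: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_metabolites < 2:
            raise ValueError("need at least 2 core metabolites")
        if self.n_exchanges < 1:
            raise ValueError("need at least one exchange")
        if any(s < 2 for s in self.inject_tics):
            raise ValueError("planted cycles need at least 2 reactions")


def generate_network(spec: ToyNetworkSpec) -> tuple[MetabolicNetwork, dict]:
    """Build the toy network and its ground-truth manifest.

    Without injections the network is feasible with a positive biomass
    optimum; planted cycle supports and orphan reactions are listed in the
    manifest for recall/false-positive checks.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_core_metabolites
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    core = [f"M{i}_c" for i in range(k)]
    mets += [Metabolite(id=m) for m in core]

    substrate_exchanges = []
    for j in range(spec.n_exchanges):
        sub_e, sub_c = f"sub{j}_e", f"sub{j}_c"
        mets += [Metabolite(id=sub_e), Metabolite(id=sub_c)]
        target = 0 if j == 0 else int(rng.integers(0, k - 1))
        rxns += [
            Reaction(id=f"EX_sub{j}", stoichiometry={sub_e: -1.0},
                     lower_bound=-spec.uptake_bound, upper_bound=1000.0),
            Reaction(id=f"TR_sub{j}", stoichiometry={sub_e: -1.0, sub_c: 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            Reaction(id=f"CV_sub{j}", stoichiometry={sub_c: -1.0, core[target]: 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
        ]
        substrate_exchanges.append(f"EX_sub{j}")

    for i in range(k - 1):
        rxns.append(Reaction(id=f"CHAIN_{i}", stoichiometry={core[i]: -1.0, core[i + 1]: 1.0},
                             lower_bound=0.0, upper_bound=1000.0))

    for b in range(spec.n_branches):
        if k < 3:
            break
        i = int(rng.integers(0, k - 2))
        j = int(rng.integers(i + 2, k)) if i + 2 < k else k - 1
        rxns.append(Reaction(id=f"BR_{b}", stoichiometry={core[i]: -1.0, core[j]: 1.0},
                             lower_bound=0.0, upper_bound=1000.0))

    precursors = spec.biomass_precursors or ((core[-1].removesuffix("_c"), 1.0),)
    if len(precursors) > k:
        raise ValueError("more biomass precursors than core metabolites")
    stoich = {}
    for base, coeff in precursors:
        met = f"{base}_c"
        if met not in core:
            raise ValueError(f"biomass precursor {base!r} is not a core metabolite")
        stoich[met] = -float(coeff)
    rxns.append(Reaction(id="BIOMASS", stoichiometry=stoich, lower_bound=0.0,
                         upper_bound=1000.0, category="biomass"))

    tic_supports: list[list[str]] = []
    for t, size in enumerate(spec.inject_tics):
        loop = [f"L{t}_{j}_c" for j in range(size)]
        mets += [Metabolite(id=m) for m in loop]
        support = []
        for j in range(size):
            rid = f"TIC{t}_{j}"
            rxns.append(Reaction(
                id=rid,
                stoichiometry={loop[j]: -1.0, loop[(j + 1) % size]: 1.0},
                lower_bound=0.0, upper_bound=1000.0,
            ))
            support.append(rid)
        tic_supports.append(support)

    orphan_reactions = []
    for i in range(spec.inject_orphans):
        a, b = f"orphA{i}_c", f"orphB{i}_c"
        mets += [Metabolite(id=a), Metabolite(id=b)]
        rid = f"ORPH_{i}"
        rxns.append(Reaction(id=rid, stoichiometry={a: -1.0, b: 1.0},
                             lower_bound=0.0, upper_bound=1000.0))
        orphan_reactions.append(rid)

    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id="BIOMASS",
                           id=f"toy_seed{spec.seed}")
    net.infer_categories()
    net.validate()
    manifest = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "biomass_id": "BIOMASS",
        "substrate_exchanges": substrate_exchanges,
        "tic_supports": tic_supports,
        "orphan_reactions": orphan_reactions,
    }
    return net, manifest


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one synthetic batch experiment.

    Defaults emulate a TAP-medium batch: ~1 g/L acetate, a 10 h lag,
    substrate exhaustion within ~3 days, 2% multiplicative noise.
    """

    model: str = "heterotrophic"
    true_params: HaldaneParams | MixotrophicParams = field(default_factory=HaldaneParams)
    x0: BatchState = field(default_factory=lambda: BatchState(t=0.0, X=0.05, Ac=1.0))
    t_end: float = 80.0
    n_points: int = 20
    noise_cv: float = 0.02
    t_lag: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least 2 sample points")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def generate_curves(spec: CurveSpec) -> tuple[list[BatchState], HaldaneParams | MixotrophicParams]:
    """Simulate, sample and perturb one batch experiment.

    Returns the noisy observations (time-ordered BatchState records) and
    the ground-truth parameters.  Noise is mean-one lognormal with the
    requested coefficient of variation; the same seed reproduces the same
    data bit for bit.
    """
    t_obs = np.linspace(spec.x0.t, spec.t_end, spec.n_points)
    dt = (spec.t_end - spec.x0.t) / max(spec.n_points * 20, 200)
    if spec.model == "heterotrophic":
        traj = simulate_heterotrophic(spec.true_params, spec.x0, spec.t_end, dt,
                                      t_lag=spec.t_lag)
    elif spec.model == "mixotrophic":
        traj = simulate_mixotrophic(spec.true_params, spec.x0, spec.t_end, dt,
                                    t_lag=spec.t_lag)
    else:
        raise ValueError(f"unknown model {spec.model!r}")
    clean = traj.interp(t_obs)

    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))

    def noisy(arr: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return arr
        return arr * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=arr.shape)

    X = noisy(clean["X"])
    Ac = noisy(clean["Ac"])
    DIC = noisy(clean["C_DIC"]) if "C_DIC" in clean else None
    states = [
        BatchState(t=float(t), X=float(x), Ac=float(a),
                   C_DIC=None if DIC is None else float(d))
        for t, x, a, d in zip(t_obs, X, Ac, DIC if DIC is not None else np.zeros_like(X))
    ]
    return states, spec.true_params


# ---------------------------------------------------------------------------
# hand-built demonstration networks
# ---------------------------------------------------------------------------

def demo_network() -> MetabolicNetwork:
    """An 11-reaction mixotrophic toy of the *C. reinhardtii* core economy.

    Acetate assimilation (``ATPM_MITO``) yields fixed carbon and ATP;
    photons drive chloroplast ATP synthesis (``ATPS_CHLORO``) and CO2
    fixation (``CBB``, 2 ATP per CO2); biomass drains 40 carbon + 40 ATP
    per unit flux, so with the standard presets (CO2 uptake 12, acetate
    uptake 10) the growth optima are 0.3, 0.5 and 0.8 1/h for the photo-,
    hetero- and mixotrophic conditions.  The stoichiometry is deliberately
    minimal, not elementally balanced.
    """
    mets = [Metabolite(id=m) for m in (
        "ac_e", "co2_e", "photon_e", "ac_c", "co2_h", "photon_h",
        "atp_h", "atp_c", "cx_h", "cx_c",
    )]
    fwd = dict(lower_bound=0.0, upper_bound=1000.0)
    rxns = [
        Reaction(id="EX_ac_e", stoichiometry={"ac_e": -1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction(id="EX_co2_e", stoichiometry={"co2_e": -1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction(id="EX_photon_e", stoichiometry={"photon_e": -1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction(id="ACt", stoichiometry={"ac_e": -1.0, "ac_c": 1.0}, **fwd),
        Reaction(id="CO2t", stoichiometry={"co2_e": -1.0, "co2_h": 1.0}, **fwd),
        Reaction(id="PHOt", stoichiometry={"photon_e": -1.0, "photon_h": 1.0}, **fwd),
        Reaction(id="ATPM_MITO", name="acetate assimilation + mitochondrial ATP production",
                 stoichiometry={"ac_c": -1.0, "cx_c": 2.0, "atp_c": 2.0}, **fwd),
        Reaction(id="ATPS_CHLORO", name="chloroplast ATP synthesis",
                 stoichiometry={"photon_h": -1.0, "atp_h": 1.0}, **fwd),
        Reaction(id="ATPt", stoichiometry={"atp_h": -1.0, "atp_c": 1.0}, **fwd),
        Reaction(id="CBB", name="CO2 fixation",
                 stoichiometry={"co2_h": -1.0, "atp_h": -2.0, "cx_h": 1.0}, **fwd),
        Reaction(id="CXt", stoichiometry={"cx_h": -1.0, "cx_c": 1.0}, **fwd),
        Reaction(id="BIOMASS", stoichiometry={"cx_c": -40.0, "atp_c": -40.0},
                 lower_bound=0.0, upper_bound=1000.0, category="biomass"),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id="BIOMASS",
                           id="chlamy_demo")
    net.infer_categories()
    net.validate()
    return net


def demo_dfba_config(t0: float = 0.0, tf: float = 10.0, G: int = 200,
                     X0: float = 0.02, acetate0: float = 0.4,
                     dic0: float = 0.05) -> DFBAConfig:
    """DFBA setup for the demo network showing sequential substrate use.

    Acetate uptake is Haldane-limited; CO2/DIC uptake carries an acetate-
    repression factor (K_I = 0.01 g/L), so inorganic carbon consumption
    only switches on once acetate is nearly exhausted — the diauxic pattern
    of mixotrophic batch cultures.
    """
    return DFBAConfig(
        t0=t0, tf=tf, G=G, X0=X0,
        z0={"acetate": acetate0, "DIC": dic0},
        tracked_exchanges={"EX_ac_e": "acetate", "EX_co2_e": "DIC"},
        kinetics={
            "acetate": UptakeKinetics(vmax=10.0, Ks=0.05),
            "DIC": UptakeKinetics(vmax=12.0, Ks=1e-4, inhibitor="acetate",
                                  K_inhibit=0.01),
        },
        species_mw={"acetate": ACETATE_MW},
        species_units={"acetate": "g/L", "DIC": "mol/L"},
    )


def yield_coupled_toy(acetate_per_biomass: float = 2.0) -> MetabolicNetwork:
    """Three-reaction chain whose growth is exactly yield-coupled to acetate
    uptake: biomass flux = uptake / ``acetate_per_biomass``.  Its DFBA
    trajectory has a closed-form ODE counterpart (see
    ``matched_haldane_params``)."""
    mets = [Metabolite(id="ac_e"), Metabolite(id="ac_c")]
    rxns = [
        Reaction(id="EX_ac_e", stoichiometry={"ac_e": -1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction(id="ACt", stoichiometry={"ac_e": -1.0, "ac_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="BIOMASS", stoichiometry={"ac_c": -acetate_per_biomass},
                 lower_bound=0.0, upper_bound=1000.0, category="biomass"),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id="BIOMASS",
                           id="yield_coupled_toy")
    net.infer_categories()
    net.validate()
    return net


def matched_haldane_params(uptake: UptakeKinetics, acetate_per_biomass: float,
                           mw: float = ACETATE_MW) -> HaldaneParams:
    """Heterotrophic parameters whose ODE reproduces the yield-coupled toy's
    DFBA limit: mu_max = vmax / a, same Ks/Ki (concentration units), yield
    Yx = 1000 / (a * MW) g biomass per g acetate, no maintenance."""
    return HaldaneParams(
        mu_max=uptake.vmax / acetate_per_biomass,
        Ks=uptake.Ks,
        Ki=uptake.Ki,
        Yx=1000.0 / (acetate_per_biomass * mw),
        maintenance_m=0.0,
    )
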