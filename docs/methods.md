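# Methods

This note records the models implemented in `chlamydyn`, the choices made
where the underlying science leaves the design open, and what the test
suite does and does not demonstrate.

## Network model and statistics

A `MetabolicNetwork` holds ordered metabolites and reactions; the
stoichiometric matrix *S* (m × n) is derived on demand. Metabolite ids are
compartment-tagged with a one-letter suffix over the ten compartments of
the *C. reinhardtii* reconstruction (extracellular `e`, cytosol `c`,
chloroplast `h`, mitochondria `m`, nucleus `n`, eyespot `s`, flagellum `f`,
glyoxysome `x`, thylakoid lumen `l`, Golgi `g`). In SBML the compartment
attribute wins over the suffix. Reaction categories are inferred when
untagged: an exchange touches exactly one metabolite; a transport moves
identical base ids between exactly two compartments with no chemical change
(this includes antiporters); explicit tags are never overwritten, and
biomass is only ever explicit or implied by the objective.

`compute_stats` assigns internal reactions to the compartment of their
reactants (majority vote, lexicographic tie-break), tallies exchanges as
extracellular and counts transports separately, so compartment fractions
sum to ≤ 1. The reactant-side rule is a convention — a reconstruction
spanning compartments has no canonical "home" — and per-compartment
reaction fractions should be read as approximate for multi-compartment
reactions.

Duplicate reactions are recognized by a canonical stoichiometry key:
coefficients divided by the coefficient of the lexicographically smallest
metabolite (so any real scaling cancels), rationalized
(`Fraction.limit_denominator(1e6)`), reduced to the smallest integer
vector, sign-canonicalized. A reaction and its exact reverse share a key,
which is what duplicate-based cycle resolution needs.

The tabular dialect is UTF-8 TSV with `[metabolites]` and `[reactions]`
sections and `a A_c + b B_c <=> c C_c` equations (`-->` irreversible);
`# objective:` and `# default_bound:` directives carry the remaining state,
so `load(write(x))` reproduces `x` up to ordering in both formats.

## FBA and condition presets

The LP max *c*ᵀ*v*, *Sv* = 0, LB ≤ v ≤ UB is solved with HiGHS through
`scipy.optimize.linprog` at feasibility/optimality tolerances 1e-9; test
comparisons of objective values use 1e-6. Only the objective value is
contractual: flux vectors are one vertex of the alternate-optima face, and
uniqueness claims for individual fluxes must come from a zero-width FVA
range. Uptake is negative throughout ("CO₂ flux −12" means uptake of 12
mmol/gDW/h).

The growth-condition presets encode the condition-specific constraints:
photoautotrophic (CO₂ uptake ≤ 12, no acetate, light open, mitochondrial
ATP production blocked), heterotrophic (acetate ≤ 10, light closed,
chloroplast ATP production blocked), mixotrophic (both substrates, nothing
blocked). The ids of the exchange and ATP reactions are configuration with
demo-network defaults, because every reconstruction has its own namespace.
Light flux magnitude is left unconstrained by default; it is
experiment-specific and the presets accept overrides.

## FVA, blocked reactions, and cycles

`run_fva` pins the biomass flux at *f* × optimum (equality) during all 2n
LPs. With *f* = 0 the biomass is left free rather than pinned at zero:
blocked-reaction detection asks what the *medium* forbids, and forcing zero
growth would misclassify biomass-coupled reactions. A reaction is blocked
when |min| and |max| ≤ tolerance (default 1e-9).

Cycle detection closes every exchange, so any remaining degree of freedom
is a closed internal cycle, then flags internal reactions whose range
touches ±`default_bound` (1000 mmol/gDW/h) and spans more than 1e-6. The
null space of the flagged submatrix is computed per connected component
(reactions sharing metabolites) by SVD with a relative singular-value
cutoff of 1e-10; component-wise bases keep disjoint cycles in separate
basis vectors, which a global SVD would be free to mix. Each basis vector,
restricted to its support (relative weight > 1e-9), is one reported cycle
with its weights α satisfying S·α = 0.

Resolution applies, per iteration, the first applicable action of the
policy (default order: directionality revision from a hint table, duplicate
removal, blocking), then re-detects, until no cycle remains. Blocking
picks the reaction whose smallest containing cycle is smallest, ties broken
by id — a deterministic choice that minimizes collateral damage. Curation
never touches exchanges, and the tests verify the biomass optimum is
unchanged when the planted cycles carry no productive flux. Automatic
direction assignment from Gibbs energies is out of scope; hints are an
input table.

## Batch kinetics

Heterotrophic: µ = µ_max·Ac/(Ks + Ac + Ac²/Ki), dX/dt = µX,
−dAc/dt = (1/Yx)dX/dt + mX. Mixotrophic: the product of acetate and DIC
Haldane factors, dC_DIC/dt = −(1/Mx)dX/dt + N_CO2, and the same acetate
balance. **Maintenance sign:** the two published forms of the acetate
balance differ in the sign of the maintenance term, and a
maintenance term that *produces* acetate violates mass balance, so both
models implement maintenance as consumption.

Gas transfer is N_CO2 = kLa·(P/H·y_out − [CO₂]) with speciation
[CO₂] = C_DIC/(1 + K₁10^pH + K₁K₂10^2pH) at fixed pH (default 6.8, inside
the 6.3–7.5 band typical of these cultures; a constant because no pH
dynamics are modelled). H is expressed so P/H is a concentration in the
DIC unit (Pa·L/mol for mol/L). K₁, K₂ default to the carbonate
equilibrium constants (pK 6.3, 10.3). No gas-phase balance is integrated;
y_out is a constant input.

Integration uses adaptive RK45 (`solve_ivp`, rtol 1e-8) with substrate
exhaustion as a terminal event in the heterotrophic model: past it, Ac = 0
and X is frozen (growth stops and maintenance uptake is suspended — cells
cannot take up acetate that is not there). The mixotrophic integrator
clamps concentrations inside the rate function instead, because DIC can
recover through gas transfer after exhaustion and a terminal event would
have to restart; clamp times are recorded in `solver_meta`. A fixed-step
Euler variant exists for parity with the dynamic-FBA update rule. A lag
phase is an optional dead time t_lag during which the state is held — the
rate laws themselves contain no lag term.

Default kinetic constants (µ_max 0.045 1/h, Ks 0.05 g/L, Ki ∞, Yx 0.5 g/g,
m 0.001) are representative of a TAP batch (≈1 g/L acetate, ~10 h lag,
exhaustion within ~3 days, final density ≈0.55 g/L); published fitted
values for this organism are not available, so these are a one-time
modelling choice, not constants to be quoted.

## Parameter estimation

`fit_params` minimizes weighted residuals (each series scaled by its mean
magnitude) between simulated and observed X/Ac(/DIC) series, searching
positive parameters in log₁₀ space with box bounds, a heuristic first
start (growth-rate slope, yield from ΔX/ΔAc) plus latin-hypercube restarts
(seeded), via `scipy.optimize.least_squares` (TRF). Standard errors come
from the Gauss–Newton curvature; a curvature whose condition exceeds 1e4
(smallest/largest singular value < 1e-4) triggers a non-identifiability
warning naming the sloppiest parameter combination. This threshold
separates the genuinely degenerate cases (constant biomass; Ki with data
that never reach inhibitory concentrations) from fits whose data cover the
inhibition regime. With the generator's defaults the lag is part of the
experimental protocol and is passed as known dead time; it can also be
fitted (`fit_lag=True`).

## Dynamic FBA (SOA)

Per interval: kinetic uptake bounds → one FBA (biomass objective) → explicit
Euler update X ← X + µXΔt, z ← z + vXΔt·conv, clamp at zero. The update is
written with uptake-negative fluxes, so consumed species decrease; the
equivalent textbook form with the opposite sign convention carries a minus
sign. The unit bridge conv is MW/1000 for g/L species and 1/1000 for mol/L
species (fluxes are mmol/gDW/h, X is gDW/L). Euler is the contract — it is
what the printed update rule states — and the convergence study quantifies
its O(Δt) error against the ODE oracle on a yield-coupled toy where the
two descriptions coincide in the limit.

An infeasible interval is re-solved with biomass forced to zero; if even
that is infeasible the run stops with `infeasible_at` and the interval
index. A run whose final interval has µ ≈ 0 reports `growth_arrested`.
Objective weights beyond biomass are not implemented.

The uptake rule is Haldane-shaped per species, with an optional repression
factor K_I/(K_I + [inhibitor]). The repression factor is this package's
device for expressing substrate preference: plain FBA consumes all
available substrates simultaneously, so the sequential (diauxic) pattern —
acetate first, CO₂-supported growth after exhaustion — requires the
kinetic layer to suppress inorganic-carbon uptake while acetate is
abundant, analogous to catabolite repression. The demo configuration uses
K_I = 0.01 g/L acetate.

## Synthetic data

Toy networks are a feasible spine (exchange → transport → conversion chain
→ biomass drain) plus seeded forward-only branches (acyclic by
construction), with planted cycles on fresh metabolites (so they cannot
carry productive flux) and orphan dead-end reactions; the manifest records
every planted structure for recall/false-positive scoring. Curves are
simulated trajectories sampled at regular times with mean-one
multiplicative lognormal noise (σ from the requested CV) — concentrations
are positive with roughly proportional error; no error model is published
for the underlying measurements.

What passing tests show: the LP path is exact against vertex enumeration;
cycle detection is exact on planted ground truth; the integrators respect
their conservation laws and closed forms; SOA converges to the ODE limit
at first order; µ_max is recoverable to <5% median error at 2% noise.
What they do not show: behaviour on a genome-scale reconstruction
(thousands of reactions, degenerate optima, numerically awkward
stoichiometry), realistic measurement error structure, or the biology of
the real organism beyond the qualitative orderings encoded in the demo
network (photoautotrophic < heterotrophic < mixotrophic growth; diauxic
substrate use).

## Problem sizes and numerical defaults

Property suites use 100 seeded toys (LP oracle, cycle recall) and 50
replicate curves (recovery); the DFBA convergence study uses G ∈ {25, 50,
100, 200} over 10 h. LP tolerances 1e-9; FVA bound-touch tolerance 1e-6;
null-space cutoff 1e-10 relative; blocked tolerance 1e-9; ODE rtol 1e-8.
These sizes keep the full validation run in minutes on one core while
leaving each statistical check comfortably powered.

## Known limitations

* Biomass composition, light kinetics, temperature and pH dynamics are not
  modelled; light is a preset bound, pH a constant.
* `resolve_tics` blocking can, in pathological networks, block a
  productive reaction; the report names every action so curation is
  auditable.
* FVA solves 2n LPs from scratch; fine for toys and adequate (minutes) for
  genome scale, but no warm-starting.
* The SOA update is explicit Euler by contract; stiff kinetics would need
  smaller Δt rather than a better scheme.
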