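"""Haldane batch-growth kinetics: heterotrophic and mixotrophic models.

Heterotrophic growth on acetate follows the Haldane (substrate-inhibition)
law

    mu = mu_max * Ac / (Ks + Ac + Ac^2 / Ki)
    dX/dt = mu * X
    -d[Ac]/dt = (1/Yx) dX/dt + m X

with X the algal density (g/L), Ac the acetate concentration (g/L), Yx the
biomass yield on acetate (g/g) and m the maintenance coefficient
(g acetate / g biomass / h).

The mixotrophic model multiplies two Haldane factors (acetate and dissolved
inorganic carbon, DIC) and adds a gas-liquid CO2 balance at fixed pH:

    dX/dt     = mu_max * f(C_DIC) * f(Ac) * X
    d[C_DIC]/dt = -(1/Mx) dX/dt + N_CO2
    d[Ac]/dt  = -(1/Yx) dX/dt - m X
    N_CO2     = kLa * (P/H_co2 * y_out - [CO2])
    [CO2]     = [C_DIC] / (1 + K1 10^pH + K1 K2 10^(2 pH))

Maintenance is implemented as acetate *consumption* in both models (mass
balance requires it; see docs/methods.md).  Substrate exhaustion is an
event: the concentration clamps at zero, growth stops and maintenance
uptake is suspended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "HaldaneParams",
    "MixotrophicParams",
    "BatchState",
    "Trajectory",
    "haldane_mu",
    "haldane_peak",
    "dual_haldane_mu",
    "co2_speciation",
    "co2_transfer_rate",
    "simulate_heterotrophic",
    "simulate_mixotrophic",
]


@dataclass(frozen=True)
class HaldaneParams:
    """Kinetic constants of heterotrophic growth on acetate.

    Defaults are representative of a *C. reinhardtii* TAP batch culture
    (acetate ~1 g/L, final density ~0.55 g/L, exhaustion within ~3 days);
    they are a modelling choice, not published constants.
    """

    mu_max: float = 0.045  # 1/h
    Ks: float = 0.05  # g/L acetate saturation constant
    Ki: float = math.inf  # g/L acetate inhibition constant (inf = disabled)
    Yx: float = 0.5  # g biomass / g acetate
    maintenance_m: float = 0.001  # g acetate / (g biomass h)

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks", "Ki", "Yx"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.maintenance_m < 0:
            raise ValueError("maintenance_m must be non-negative")


@dataclass(frozen=True)
class MixotrophicParams:
    """Kinetic and gas-transfer constants of the mixotrophic model.

    H_co2 is expressed so that P / H_co2 is a concentration in the same
    units as C_DIC (Pa*L/mol when DIC is mol/L).  K1 and K2 are the
    carbonate equilibrium constants (defaults pK1 = 6.3, pK2 = 10.3);
    y_out_co2 is the CO2 molar fraction of the sparged gas.
    """

    mu_max: float = 0.08  # 1/h
    Ks_Ac: float = 0.05  # g/L
    Ki_Ac: float = math.inf  # g/L
    Ks_DIC: float = 1e-4  # mol/L
    Ki_DIC: float = math.inf  # mol/L
    Yx: float = 0.5  # g/g
    maintenance_m: float = 0.001  # g/(g h)
    Mx: float = 24.0  # g biomass per C-mol
    kLa: float = 5.0  # 1/h
    P: float = 101325.0  # Pa
    H_co2: float = 2.94e6  # Pa L / mol
    y_out_co2: float = 0.10  # molar fraction
    K1: float = 10**-6.3
    K2: float = 10**-10.3
    pH: float = 6.8

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks_Ac", "Ki_Ac", "Ks_DIC", "Ki_DIC", "Yx", "Mx",
                     "P", "H_co2", "K1", "K2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kLa < 0 or self.maintenance_m < 0:
            raise ValueError("kLa and maintenance_m must be non-negative")
        if not 0.0 <= self.y_out_co2 <= 1.0:
            raise ValueError("y_out_co2 must be a molar fraction in [0, 1]")


@dataclass(frozen=True)
class BatchState:
    """Culture state at one time point; concentrations are non-negative."""

    t: float  # h
    X: float  # g/L
    Ac: float  # g/L
    C_DIC: float | None = None  # mol/L, mixotrophic only

    def __post_init__(self) -> None:
        if self.X < 0 or self.Ac < 0 or (self.C_DIC is not None and self.C_DIC < 0):
            raise ValueError("state variables must be non-negative")


@dataclass
class Trajectory:
    """Time-indexed solution of a batch simulation."""

    times: np.ndarray
    X: np.ndarray
    Ac: np.ndarray
    C_DIC: np.ndarray | None
    params_used: HaldaneParams | MixotrophicParams
    solver_meta: dict = field(default_factory=dict)

    @property
    def states(self) -> list[BatchState]:
        dic = self.C_DIC if self.C_DIC is not None else [None] * len(self.times)
        return [
            BatchState(t=float(t), X=max(float(x), 0.0), Ac=max(float(a), 0.0),
                       C_DIC=None if d is None else max(float(d), 0.0))
            for t, x, a, d in zip(self.times, self.X, self.Ac, dic)
        ]

    def interp(self, t: np.ndarray) -> dict[str, np.ndarray]:
        out = {
            "X": np.interp(t, self.times, self.X),
            "Ac": np.interp(t, self.times, self.Ac),
        }
        if self.C_DIC is not None:
            out["C_DIC"] = np.interp(t, self.times, self.C_DIC)
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.times, "X": self.X, "Ac": self.Ac}
        if self.C_DIC is not None:
            data["C_DIC"] = self.C_DIC
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def haldane_mu(Ac, p: HaldaneParams):
    """Specific growth rate mu(Ac) = mu_max Ac / (Ks + Ac + Ac^2/Ki).

    Saturates at low Ks, is inhibited at high acetate; strictly below
    mu_max.  Accepts scalars or arrays; negative concentrations are a
    domain error.
    """
    Ac = np.asarray(Ac, dtype=float)
    if np.any(Ac < 0):
        raise ValueError("acetate concentration must be non-negative")
    mu = p.mu_max * Ac / (p.Ks + Ac + Ac**2 / p.Ki)
    return float(mu) if mu.ndim == 0 else mu


def haldane_peak(p: HaldaneParams) -> tuple[float, float]:
    """(argmax, max) of the Haldane law: Ac* = sqrt(Ks Ki), mu* = mu_max /
    (1 + 2 sqrt(Ks/Ki)).  With Ki = inf the law is monotone (argmax inf)."""
    if math.isinf(p.Ki):
        return math.inf, p.mu_max
    ac_star = math.sqrt(p.Ks * p.Ki)
    return ac_star, p.mu_max / (1.0 + 2.0 * math.sqrt(p.Ks / p.Ki))


def dual_haldane_mu(Ac, C_DIC, p: MixotrophicParams):
    """mu_max times the product of the acetate and DIC Haldane factors."""
    Ac = np.asarray(Ac, dtype=float)
    C_DIC = np.asarray(C_DIC, dtype=float)
    if np.any(Ac < 0) or np.any(C_DIC < 0):
        raise ValueError("concentrations must be non-negative")
    f_ac = Ac / (p.Ks_Ac + Ac + Ac**2 / p.Ki_Ac)
    f_dic = C_DIC / (p.Ks_DIC + C_DIC + C_DIC**2 / p.Ki_DIC)
    mu = p.mu_max * f_ac * f_dic
    return float(mu) if mu.ndim == 0 else mu


def co2_speciation(C_DIC, pH: float, K1: float, K2: float):
    """Dissolved CO2 from total inorganic carbon at fixed pH:
    [CO2] = C_DIC / (1 + K1 10^pH + K1 K2 10^(2 pH)); monotone decreasing
    in pH (more carbon sits as bicarbonate/carbonate)."""
    C_DIC = np.asarray(C_DIC, dtype=float)
    denom = 1.0 + K1 * 10.0**pH + K1 * K2 * 10.0 ** (2.0 * pH)
    out = C_DIC / denom
    return float(out) if out.ndim == 0 else out


def co2_transfer_rate(co2, p: MixotrophicParams):
    """Volumetric gas-liquid transfer N_CO2 = kLa (P/H_co2 * y_out - [CO2]);
    positive = absorption, zero at equilibrium."""
    co2 = np.asarray(co2, dtype=float)
    out = p.kLa * (p.P / p.H_co2 * p.y_out_co2 - co2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_EXHAUST = 1e-12

Method = Literal["rk45", "euler"]


def _grid(t0: float, t_end: float, dt: float) -> np.ndarray:
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round((t_end - t0) / dt))
    grid = t0 + dt * np.arange(n + 1)
    if grid[-1] < t_end - 1e-12:
        grid = np.append(grid, t_end)
    return grid


def simulate_heterotrophic(
    p: HaldaneParams,
    x0: BatchState,
    t_end: float,
    dt: float,
    t_lag: float = 0.0,
    method: Method = "rk45",
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the two-state heterotrophic model and sample every ``dt``.

    An optional lag (dead time) holds the state at its initial value for
    ``t_lag`` hours.  Acetate exhaustion is detected as an event: past it,
    Ac = 0 and X is constant (growth and maintenance stop).  ``method``
    "rk45" is an adaptive Runge-Kutta with event detection; "euler" is the
    fixed-step explicit scheme matching the dynamic-FBA update rule.
    """
    grid = _grid(x0.t, t_end, dt)
    meta: dict = {"method": method, "dt": dt, "t_lag": t_lag, "clamp_events": []}

    def rhs(t, y):
        X, Ac = y
        mu = haldane_mu(max(Ac, 0.0), p)
        dX = mu * X
        dAc = -(dX / p.Yx + p.maintenance_m * X)
        return [dX, dAc]

    t_start = x0.t + t_lag
    X_arr = np.full_like(grid, x0.X, dtype=float)
    Ac_arr = np.full_like(grid, x0.Ac, dtype=float)

    if x0.Ac <= _EXHAUST or t_start >= t_end:
        return Trajectory(grid, X_arr, np.maximum(Ac_arr, 0.0), None, p, meta)

    active = grid >= t_start
    t_eval = grid[active]

    if method == "euler":
        X, Ac = x0.X, x0.Ac
        Xs, Acs = [], []
        prev_t = t_start
        for t in t_eval:
            h = t - prev_t
            if h > 0 and Ac > 0:
                dX, dAc = rhs(prev_t, [X, Ac])
                X += dX * h
                Ac += dAc * h
                if Ac <= 0:
                    Ac = 0.0
                    meta["clamp_events"].append(float(t))
            prev_t = t
            Xs.append(X)
            Acs.append(Ac)
        X_arr[active], Ac_arr[active] = Xs, Acs
        return Trajectory(grid, X_arr, Ac_arr, None, p, meta)

    def exhausted(t, y):
        return y[1]

    exhausted.terminal = True
    exhausted.direction = -1

    sol = solve_ivp(
        rhs, (t_start, t_end), [x0.X, x0.Ac], t_eval=t_eval,
        events=exhausted, rtol=rtol, atol=atol, dense_output=True, method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message} (last t={sol.t[-1] if len(sol.t) else t_start})")
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("non-finite state encountered during integration")

    n_got = sol.y.shape[1]
    idx = np.flatnonzero(active)
    X_arr[idx[:n_got]] = sol.y[0]
    Ac_arr[idx[:n_got]] = sol.y[1]
    if sol.status == 1:  # substrate exhausted before t_end
        te = float(sol.t_events[0][0])
        Xe = float(sol.sol(te)[0])
        meta["clamp_events"].append(te)
        X_arr[idx[n_got:]] = Xe
        Ac_arr[idx[n_got:]] = 0.0
        # grid nodes just after the event inside the solved span
        past = grid[idx[:n_got]] >= te
        X_arr[idx[:n_got][past]] = Xe
        Ac_arr[idx[:n_got][past]] = 0.0
    return Trajectory(grid, X_arr, np.maximum(Ac_arr, 0.0), None, p, meta)


def simulate_mixotrophic(
    p: MixotrophicParams,
    x0: BatchState,
    t_end: float,
    dt: float,
    t_lag: float = 0.0,
    method: Method = "rk45",
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the three-state mixotrophic model (X, Ac, C_DIC).

    Speciation is evaluated each step at fixed pH.  Concentrations clamp at
    zero: growth needs both substrates (the Haldane product is zero if
    either is exhausted), acetate maintenance consumption stops with the
    acetate, and the DIC pool keeps exchanging with the gas phase, so DIC
    may recover after exhaustion if the sparged gas carries CO2.
    """
    if x0.C_DIC is None:
        raise ValueError("mixotrophic initial state needs C_DIC")
    grid = _grid(x0.t, t_end, dt)
    meta: dict = {"method": method, "dt": dt, "t_lag": t_lag, "clamp_events": []}

    def rhs(t, y):
        X, Ac, DIC = y
        Acc, DICc = max(Ac, 0.0), max(DIC, 0.0)
        if t < x0.t + t_lag:
            mu = 0.0
        else:
            mu = dual_haldane_mu(Acc, DICc, p)
        dX = mu * X
        dAc = -(dX / p.Yx + p.maintenance_m * X) if Ac > 0 else 0.0
        n_co2 = co2_transfer_rate(co2_speciation(DICc, p.pH, p.K1, p.K2), p)
        dDIC = -dX / p.Mx + n_co2
        if DIC <= 0:
            dDIC = max(dDIC, 0.0)
        return [dX, dAc, dDIC]

    y0 = [x0.X, x0.Ac, x0.C_DIC]
    if method == "euler":
        y = np.array(y0, dtype=float)
        out = np.empty((3, len(grid)))
        out[:, 0] = y
        for k in range(1, len(grid)):
            h = grid[k] - grid[k - 1]
            y = y + h * np.array(rhs(grid[k - 1], y))
            for i in (1, 2):
                if y[i] < 0:
                    y[i] = 0.0
                    meta["clamp_events"].append(float(grid[k]))
            out[:, k] = y
        return Trajectory(grid, out[0], out[1], out[2], p, meta)

    sol = solve_ivp(rhs, (grid[0], grid[-1]), y0, t_eval=grid, rtol=rtol, atol=atol,
                    method="RK45")
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("non-finite state encountered during integration")
    X, Ac, DIC = sol.y
    for name, arr in (("Ac", Ac), ("C_DIC", DIC)):
        crossing = np.flatnonzero((arr[:-1] > 0) & (arr[1:] <= 0))
        meta["clamp_events"].extend(float(grid[i + 1]) for i in crossing)
    return Trajectory(grid, X, np.maximum(Ac, 0.0), np.maximum(DIC, 0.0), p, meta)
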