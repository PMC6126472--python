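"""Nonlinear least-squares estimation of batch-growth kinetic parameters.

Observed trajectories (time, biomass, substrate concentrations) are fitted
by simulating the heterotrophic or mixotrophic model and minimizing the
weighted residual between simulated and observed series.  Positive
parameters are searched in log space; a latin-hypercube multi-start (fixed
seed) guards against local minima; per-parameter standard errors come from
the Gauss-Newton curvature at the optimum.  A singular curvature triggers a
non-identifiability warning naming the sloppy parameter combination
(typically Ks-Ki on data that never reaches inhibitory concentrations).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import (
    BatchState,
    HaldaneParams,
    MixotrophicParams,
    Trajectory,
    simulate_heterotrophic,
    simulate_mixotrophic,
)

__all__ = ["FitResult", "NonIdentifiableWarning", "fit_params"]


class NonIdentifiableWarning(UserWarning):
    """The data do not constrain some direction of parameter space."""


@dataclass
class FitResult:
    params: HaldaneParams | MixotrophicParams
    t_lag: float
    cost: float
    stderr: dict[str, float] = field(default_factory=dict)
    free_names: list[str] = field(default_factory=list)
    n_starts: int = 0
    warnings: list[str] = field(default_factory=list)


_HETERO_FREE = ("mu_max", "Ks", "Ki", "Yx", "maintenance_m")
_MIXO_FREE = ("mu_max", "Ks_Ac", "Ki_Ac", "Ks_DIC", "Ki_DIC", "Yx", "Mx", "maintenance_m")

# log10 search boxes, scaled by the data where concentration-like
_LOG_BOUNDS = {
    "mu_max": (-3.0, 0.5),
    "Ks": (-4.0, 1.5),
    "Ki": (-2.0, 6.0),
    "Ks_Ac": (-4.0, 1.5),
    "Ki_Ac": (-2.0, 6.0),
    "Ks_DIC": (-7.0, 0.0),
    "Ki_DIC": (-5.0, 3.0),
    "Yx": (-1.5, 1.0),
    "Mx": (0.0, 2.5),
    "maintenance_m": (-5.0, -0.5),
}


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True)
    if isinstance(data, Trajectory):
        return data.to_frame()
    if isinstance(data, Iterable):
        rows = []
        for st in data:
            if not isinstance(st, BatchState):
                raise TypeError("data must be BatchState records, a DataFrame or a Trajectory")
            row = {"t": st.t, "X": st.X, "Ac": st.Ac}
            if st.C_DIC is not None:
                row["C_DIC"] = st.C_DIC
            rows.append(row)
        return pd.DataFrame(rows)
    raise TypeError(f"cannot interpret data of type {type(data)!r}")


def _heuristic_init(df: pd.DataFrame, model: str) -> dict[str, float]:
    t, X = df["t"].to_numpy(), df["X"].to_numpy()
    Ac = df["Ac"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        dlogX = np.diff(np.log(np.maximum(X, 1e-12))) / np.maximum(np.diff(t), 1e-9)
    mu0 = float(np.clip(np.nanmax(dlogX, initial=1e-3), 1e-3, 2.0))
    d_ac = Ac[0] - Ac.min()
    yx0 = float(np.clip((X.max() - X[0]) / d_ac, 0.05, 5.0)) if d_ac > 1e-9 else 0.5
    ac_scale = max(Ac.max(), 1e-6)
    init = {
        "mu_max": mu0,
        "Yx": yx0,
        "maintenance_m": 1e-3,
        "Ks": 0.1 * ac_scale,
        "Ki": 50.0 * ac_scale,
        "Ks_Ac": 0.1 * ac_scale,
        "Ki_Ac": 50.0 * ac_scale,
    }
    if model == "mixotrophic" and "C_DIC" in df:
        dic_scale = max(df["C_DIC"].max(), 1e-9)
        init.update({"Ks_DIC": 0.1 * dic_scale, "Ki_DIC": 50.0 * dic_scale, "Mx": 24.0})
    # lag: first time biomass clearly leaves its initial value
    grown = np.flatnonzero(X > X[0] * 1.05)
    init["t_lag"] = float(t[grown[0] - 1] - t[0]) if len(grown) and grown[0] > 0 else 0.0
    return init


def fit_params(
    data,
    model: str = "heterotrophic",
    fixed: dict[str, float] | None = None,
    fit_lag: bool = False,
    n_starts: int = 4,
    seed: int = 0,
    max_nfev: int = 200,
) -> FitResult:
    """Fit Haldane growth parameters to observed batch data.

    ``data`` holds >= 6 time points of (t, X, Ac[, C_DIC]).  ``fixed`` pins
    any subset of parameters (and may supply ``t_lag``); the remainder are
    free.  With ``fit_lag`` the dead-time offset is estimated too.  Returns
    the best multi-start solution with residual cost and standard errors.
    """
    df = _as_frame(data)
    if len(df) < 6:
        raise ValueError("need at least 6 time points to fit")
    if (df[["X", "Ac"]].to_numpy() < 0).any():
        raise ValueError("concentrations must be non-negative")
    fixed = dict(fixed or {})
    if model == "heterotrophic":
        names, cls = _HETERO_FREE, HaldaneParams
    elif model == "mixotrophic":
        names, cls = _MIXO_FREE, MixotrophicParams
        if "C_DIC" not in df:
            raise ValueError("mixotrophic fit needs a C_DIC column")
    else:
        raise ValueError(f"unknown model {model!r}")

    t_lag_fixed = float(fixed.pop("t_lag", 0.0))
    free = [n for n in names if n not in fixed]
    if fit_lag:
        free = free + ["t_lag"]
    if not free:
        raise ValueError("no free parameters")

    t_obs = df["t"].to_numpy(dtype=float)
    span = t_obs[-1] - t_obs[0]
    dt_sim = max(span / 400.0, 1e-3)
    series = ["X", "Ac"] + (["C_DIC"] if model == "mixotrophic" else [])
    scales = {s: max(float(np.abs(df[s]).mean()), 1e-9) for s in series}
    obs = np.concatenate([df[s].to_numpy(dtype=float) / scales[s] for s in series])

    defaults = {f.name: getattr(cls(), f.name) for f in dataclasses.fields(cls)}

    def build(theta: np.ndarray) -> tuple[HaldaneParams | MixotrophicParams, float]:
        vals = dict(defaults)
        vals.update(fixed)
        lag = t_lag_fixed
        for name, v in zip(free, theta):
            if name == "t_lag":
                lag = v
            else:
                vals[name] = 10.0**v
        return cls(**vals), lag

    x0_states = BatchState(
        t=float(t_obs[0]), X=float(df["X"].iloc[0]), Ac=float(df["Ac"].iloc[0]),
        C_DIC=float(df["C_DIC"].iloc[0]) if model == "mixotrophic" else None,
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            p, lag = build(theta)
        except ValueError:
            return np.full_like(obs, 1e3)
        sim_fn = simulate_heterotrophic if model == "heterotrophic" else simulate_mixotrophic
        try:
            traj = sim_fn(p, x0_states, float(t_obs[-1]), dt_sim, t_lag=lag,
                          rtol=1e-7, atol=1e-10)
        except RuntimeError:
            return np.full_like(obs, 1e3)
        sim = traj.interp(t_obs)
        return np.concatenate([sim[s] / scales[s] for s in series]) - obs

    init = _heuristic_init(df, model)
    lo = np.array([0.0 if n == "t_lag" else _LOG_BOUNDS[n][0] for n in free])
    hi = np.array([max(span / 2, 1e-6) if n == "t_lag" else _LOG_BOUNDS[n][1] for n in free])

    starts = []
    theta0 = np.array([
        np.clip(init[n] if n == "t_lag" else math.log10(max(init.get(n, defaults.get(n, 1.0)), 1e-12)),
                l, h)
        for n, l, h in zip(free, lo, hi)
    ])
    starts.append(theta0)
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        for row in sampler.random(n_starts - 1):
            starts.append(lo + row * (hi - lo))

    best = None
    for theta in starts:
        res = least_squares(residuals, theta, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=max_nfev)
        if best is None or res.cost < best.cost:
            best = res

    params, lag = build(best.x)
    result = FitResult(params=params, t_lag=lag, cost=float(best.cost),
                       free_names=list(free), n_starts=len(starts))

    # curvature-based identifiability and standard errors
    J = best.jac
    U, sv, Vt = np.linalg.svd(J, full_matrices=False)
    ndata, k = len(obs), len(free)
    if sv[0] <= 0 or sv[-1] / sv[0] < 1e-4:
        v = Vt[-1]
        order = np.argsort(-np.abs(v))
        combo = " + ".join(f"{v[i]:+.2f}*{free[i]}" for i in order[:2])
        msg = f"fit is not identifiable along {combo} (singular curvature)"
        warnings.warn(msg, NonIdentifiableWarning, stacklevel=2)
        result.warnings.append(msg)
    with np.errstate(divide="ignore"):
        inv_sv2 = np.where(sv > 1e-8 * sv[0], 1.0 / sv**2, 0.0)
    sigma2 = 2.0 * best.cost / max(ndata - k, 1)
    cov = (Vt.T * inv_sv2) @ Vt * sigma2
    for i, name in enumerate(free):
        se_log = math.sqrt(max(cov[i, i], 0.0))
        if name == "t_lag":
            result.stderr[name] = se_log
        else:
            value = 10.0 ** best.x[i]
            result.stderr[name] = value * math.log(10.0) * se_log
    return result
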