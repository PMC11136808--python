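"""Simplified estimation stage: MAP etas and pooled fixed-effect fits.

This is an identifiability surface for the implemented model, not a
re-estimation of the published fit: per-subject random effects are
recovered as maximum-a-posteriori (empirical Bayes) estimates given the
population parameters, and fixed effects are recovered by pooled maximum
likelihood with all etas held at zero on synthetic datasets.  Both paths
share one Gaussian likelihood kernel; BLQ-flagged observations are
excluded throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataset import PKDataset
from .model import PopulationParameters, resolve_individual, ruv_prop_variance
from .simulate import simulate_individual

__all__ = ["FitSpec", "FitResult", "map_ebe", "fit_pooled", "profile_objective",
           "neg2ll"]

_LOG2PI = math.log(2.0 * math.pi)

#: hard upper caps for naturally bounded parameters (fractions)
_PARAM_CAPS = {"VLmax": 0.99, "fu": 1.0}


def _default_bounds(name: str, value: float) -> tuple:
    hi = min(value * 100.0, _PARAM_CAPS.get(name, math.inf))
    return (value / 100.0, hi)


def neg2ll(obs, pred, tad, theta: PopulationParameters,
           error_model: str = "combined_tv",
           sigma2_prop: float = 0.0025) -> float:
    """Shared -2 log-likelihood kernel of the Gaussian error models.

    ``combined_tv`` uses the model's time-varying proportional plus
    additive residual variances; ``proportional`` a constant relative
    variance ``sigma2_prop``; ``proportional+additive`` adds the
    model's additive term to the constant proportional one.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.maximum(np.asarray(pred, dtype=float), 1e-10)
    if error_model == "combined_tv":
        var = (ruv_prop_variance(tad, theta.RUV_early, theta.RUV_late,
                                 theta.RUV_rate) * pred ** 2 + theta.RUV_add)
    elif error_model == "proportional":
        var = sigma2_prop * pred ** 2
    elif error_model == "proportional+additive":
        var = sigma2_prop * pred ** 2 + theta.RUV_add
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    var = np.maximum(var, 1e-12)
    return float(np.sum(_LOG2PI + np.log(var) + (obs - pred) ** 2 / var))


def _prepare_subject(ds: PKDataset, sid, blq_policy: str = "exclude"):
    """Extract the static per-subject pieces the likelihood needs."""
    obs = ds.observations
    obs = obs[obs.ID == sid]
    if blq_policy == "exclude":
        obs = obs[obs.BLQ == 0]
    regimen = ds.regimen_for(sid)
    cov = ds.covariates_for(sid)
    times = obs.TIME.to_numpy(dtype=float)
    grid = np.unique(np.concatenate([[0.0], times]))
    return {
        "id": sid,
        "regimen": regimen,
        "cov": cov,
        "times": times,
        "grid": grid,
        "tad": obs.TAD.to_numpy(dtype=float),
        "dv": obs.DV.to_numpy(dtype=float),
    }


def _predict(prep, theta, eta, solver_opts):
    ip = resolve_individual(theta, prep["cov"], eta)
    prof = simulate_individual(prep["regimen"], ip, grid=prep["grid"],
                               solver_opts=solver_opts)
    return prof.conc_at(prep["times"])


def map_ebe(
    subject_data: PKDataset,
    theta: PopulationParameters,
    omegas=None,
    error_model: str = "combined_tv",
    sigma2_prop: float = 0.0025,
    sid=None,
    solver_opts: dict | None = None,
) -> np.ndarray:
    """MAP (empirical Bayes) estimate of one subject's (CL, V0, MTT) etas.

    Maximises the Gaussian observation log-likelihood plus the
    log-normal prior on the etas.  With no quantifiable observations
    (all BLQ) the estimate shrinks to the prior mode at zero.
    """
    omegas = np.asarray(theta.omegas if omegas is None else omegas, dtype=float)
    ids = subject_data.df.ID.unique()
    if sid is None:
        if len(ids) != 1:
            raise ValueError("pass sid= for a multi-subject dataset")
        sid = ids[0]
    prep = _prepare_subject(subject_data, sid)
    if len(prep["dv"]) == 0:
        # nothing quantifiable: the posterior is the prior, mode at zero
        return np.zeros(3)
    opts = solver_opts or {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}
    # zero-variance omegas pin the corresponding eta at 0
    free = omegas > 0
    pen = np.where(free, 1.0 / np.maximum(omegas, 1e-30), 0.0)

    def objective(x):
        eta = np.where(free, x, 0.0)
        pred = _predict(prep, theta, eta, opts)
        return (neg2ll(prep["dv"], pred, prep["tad"], theta,
                       error_model, sigma2_prop)
                + float(np.sum(pen * eta ** 2)))

    # finite-difference step well above the ODE-solver noise floor
    res = minimize(objective, np.zeros(3), method="L-BFGS-B",
                   bounds=[(-3.0, 3.0)] * 3,
                   options={"ftol": 1e-13, "gtol": 1e-9, "eps": 1e-6,
                            "maxiter": 200})
    best_x, best_f = res.x, res.fun
    if not res.success:
        polish = minimize(objective, best_x, method="Nelder-Mead",
                          options={"xatol": 1e-7, "fatol": 1e-10,
                                   "maxiter": 400})
        if polish.fun <= best_f:
            best_x, best_f = polish.x, polish.fun
        elif res.status not in (1, 2):
            raise RuntimeError(
                f"MAP optimisation failed for subject {sid}: {res.message}")
    return np.where(free, best_x, 0.0)


@dataclass
class FitSpec:
    """What to estimate in a pooled fixed-effect fit.

    ``free`` maps parameter names (fields of
    :class:`~balopk.model.PopulationParameters`) to initial values.
    Optimisation runs on the log scale with multi-start jitter; the
    best objective wins, ties broken by the first start.
    """

    free: dict
    bounds: dict = field(default_factory=dict)
    error_model: str = "proportional"
    sigma2_prop: float = 0.0025
    blq_policy: str = "exclude"
    n_starts: int = 5
    jitter_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name, val in self.free.items():
            if val <= 0:
                raise ValueError(f"initial value for {name} must be positive")
            lo, hi = self.bounds.get(name, _default_bounds(name, val))
            if not lo <= val <= hi:
                raise ValueError(f"initial value for {name} outside bounds")

    def bounds_for(self, name: str) -> tuple:
        return self.bounds.get(name, _default_bounds(name, self.free[name]))


@dataclass
class FitResult:
    estimates: dict
    objective: float
    converged: bool
    rse: dict                 # relative standard errors, %
    trace: list               # accepted objective values, best start
    n_obs: int
    flags: list
    start_objectives: list


#: parameters whose identifiability requires multiple dose levels
_DOSE_RANGE_PARAMS = {"VLmax", "VL_A50", "Kgut", "S"}


def _pooled_objective_factory(preps, theta0, names, spec, solver_opts):
    def build_theta(x):
        return theta0.with_(**{n: math.exp(v) for n, v in zip(names, x)})

    def objective(x):
        theta = build_theta(x)
        total = 0.0
        for prep in preps:
            pred = _predict(prep, theta, np.zeros(3), solver_opts)
            total += neg2ll(prep["dv"], pred, prep["tad"], theta,
                            spec.error_model, spec.sigma2_prop)
        return total

    return build_theta, objective


def fit_pooled(
    dataset: PKDataset,
    spec: FitSpec,
    theta0: PopulationParameters | None = None,
    solver_opts: dict | None = None,
) -> FitResult:
    """Pooled maximum-likelihood fit of free fixed effects (etas at 0).

    Deterministic given the spec's seed and starts.  Relative standard
    errors come from a central-difference Hessian of -2LL at the
    optimum on the log scale.
    """
    theta0 = theta0 or PopulationParameters()
    opts = solver_opts or {"method": "LSODA", "rtol": 1e-6, "atol": 1e-9}
    names = list(spec.free)
    flags = []
    dose_levels = dataset.doses.AMT.nunique()
    if dose_levels < 2 and _DOSE_RANGE_PARAMS & set(names):
        flags.append(
            f"non-identifiable request: {sorted(_DOSE_RANGE_PARAMS & set(names))} "
            f"free with a single dose level")

    preps = [_prepare_subject(dataset, sid, spec.blq_policy)
             for sid in dataset.df.ID.unique()]
    preps = [p for p in preps if len(p["dv"]) > 0]
    n_obs = sum(len(p["dv"]) for p in preps)
    build_theta, objective = _pooled_objective_factory(
        preps, theta0, names, spec, opts)

    x0 = np.array([math.log(spec.free[n]) for n in names])
    log_bounds = [tuple(math.log(b) for b in spec.bounds_for(n))
                  for n in names]
    rng = np.random.default_rng(spec.seed)
    starts = [x0] + [x0 + rng.standard_normal(len(x0)) * spec.jitter_sd
                     for _ in range(spec.n_starts - 1)]
    starts = [np.clip(s, [b[0] for b in log_bounds], [b[1] for b in log_bounds])
              for s in starts]

    best = None
    start_objs = []
    for s in starts:
        trace: list[float] = []

        def cb(xk):
            trace.append(objective(xk))

        res = minimize(objective, s, method="L-BFGS-B", bounds=log_bounds,
                       callback=cb,
                       options={"ftol": 1e-12, "gtol": 1e-8, "eps": 1e-6,
                                "maxiter": 300})
        start_objs.append(float(res.fun))
        if best is None or res.fun < best[0].fun - 1e-9:
            best = (res, trace)
    res, trace = best

    # numeric Hessian of -2LL on the log scale -> RSE of the estimates
    rse = {}
    h = 1e-4
    x = res.x
    try:
        k = len(x)
        H = np.zeros((k, k))
        f0 = objective(x)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                fpp = objective(x + ei + ej)
                fpm = objective(x + ei - ej)
                fmp = objective(x - ei + ej)
                fmm = objective(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        cov = 2.0 * np.linalg.inv(H)
        sd_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        rse = {n: 100.0 * s for n, s in zip(names, sd_log)}
    except np.linalg.LinAlgError:
        flags.append("Hessian singular; RSEs unavailable")

    estimates = {n: math.exp(v) for n, v in zip(names, res.x)}
    if not math.isfinite(res.fun):
        raise RuntimeError("objective not finite at the reported estimates")
    # replicated optimum across independent starts also counts as converged
    # (line searches on an ODE-noise floor can end with a formal failure)
    replicated = sum(o < res.fun + 0.5 for o in start_objs) >= min(2, len(start_objs))
    return FitResult(estimates=estimates, objective=float(res.fun),
                     converged=bool(res.success or replicated), rse=rse,
                     trace=trace, n_obs=n_obs, flags=flags,
                     start_objectives=start_objs)


def profile_objective(
    dataset: PKDataset,
    spec: FitSpec,
    parameter: str,
    grid,
    theta0: PopulationParameters | None = None,
    solver_opts: dict | None = None,
) -> pd.DataFrame:
    """-2LL profile over one parameter, re-optimising the others.

    Each grid point is fitted with a single warm start from the
    previous solution (or the spec initials for the first point).
    """
    if parameter not in spec.free:
        raise ValueError(f"{parameter} is not a free parameter of the spec")
    others = {n: v for n, v in spec.free.items() if n != parameter}
    theta0 = theta0 or PopulationParameters()
    rows = []
    warm = dict(others)
    for value in grid:
        base = theta0.with_(**{parameter: float(value)})
        if others:
            sub = FitSpec(free=dict(warm),
                          bounds={n: spec.bounds[n] for n in others
                                  if n in spec.bounds},
                          error_model=spec.error_model,
                          sigma2_prop=spec.sigma2_prop,
                          blq_policy=spec.blq_policy,
                          n_starts=1, seed=spec.seed)
            fit = fit_pooled(dataset, sub, theta0=base, solver_opts=solver_opts)
            obj = fit.objective
            warm = fit.estimates
        else:
            preps = [_prepare_subject(dataset, sid, spec.blq_policy)
                     for sid in dataset.df.ID.unique()]
            opts = solver_opts or {"method": "LSODA", "rtol": 1e-6, "atol": 1e-9}
            obj = sum(neg2ll(p["dv"],
                             _predict(p, base, np.zeros(3), opts),
                             p["tad"], base, spec.error_model,
                             spec.sigma2_prop)
                      for p in preps if len(p["dv"]) > 0)
        rows.append({"value": float(value), "objective": float(obj)})
    return pd.DataFrame(rows)
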