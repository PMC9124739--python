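"""Nonlinear mixed-effects estimation for the disposition/adsorption model.

The marginal likelihood over the single lognormal random effect on clearance
is approximated per subject by the Laplace method: the conditional joint
density in eta is maximised (safeguarded Newton, started at 0) and the
log-determinant curvature correction added.  The reported objective function
value (OFV) is -2 log-likelihood *excluding* the n*log(2*pi) constant, the
common pharmacometric convention; differences between nested models are
convention-free and are what model selection uses (chi-square likelihood
ratio test, e.g. a drop of more than 3.84 points for one extra parameter at
alpha 0.05).

Confidence intervals come from log-likelihood profiling: a parameter is
stepped away from its estimate, all other free parameters re-optimised, and
the bound located by bisection where the profiled OFV rises by the
chi-square quantile (2.706 for a 90% interval) above the minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import StudyDataset
from .model import Segments, build_segments, predict_concentrations
from .params import AdsorptionModel, PKParameters

__all__ = [
    "ModelSpec",
    "FitResult",
    "neg2_loglik",
    "fit",
    "lrt",
    "LRTResult",
    "profile_ci",
    "shrinkage",
    "gof_table",
]

# parameter-box defaults; positive parameters are optimised on log scale
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "cl_typical": (1e-3, 50.0),
    "v": (1.0, 500.0),
    "cov_effluent": (-4.9e-4, 0.01),
    "k_max": (1e-6, 5.0),
    "a_max": (1.0, 1e4),
    "a50": (1.0, 1e4),
    "theta_cyto": (1e-6, 100.0),
    "omega_cl": (1e-4, 2.0),
    "sigma_add": (1e-3, 50.0),
}
_LOG_SCALE = {"cl_typical", "v", "k_max", "a_max", "a50", "theta_cyto",
              "omega_cl", "sigma_add"}

_MODEL_PARAMS = {
    AdsorptionModel.NONE: [],
    AdsorptionModel.CATEGORICAL: ["theta_cyto"],
    AdsorptionModel.LINEAR: ["k_max", "a_max"],
    AdsorptionModel.HYPERBOLIC: ["k_max", "a50"],
}


class SpecError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which model variant to fit and how.

    ``fixed`` maps parameter names to frozen values (e.g. V and the effluent
    covariate slope in the final model); everything else the variant needs
    is estimated.  ``error_model`` selects the residual-variability model
    (``additive`` default, ``proportional``, ``combined``).
    """

    adsorption_model: AdsorptionModel = AdsorptionModel.NONE
    effluent_covariate: bool = True
    fixed: Dict[str, float] = field(default_factory=dict)
    init: Dict[str, float] = field(default_factory=dict)
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    error_model: str = "additive"

    def __post_init__(self) -> None:
        self.adsorption_model = AdsorptionModel(self.adsorption_model)
        if self.error_model not in ("additive", "proportional", "combined"):
            raise SpecError(f"unknown error model {self.error_model!r}")
        bad = set(self.fixed) & set(self.init)
        if bad:
            raise SpecError(f"parameters both fixed and initialised: {sorted(bad)}")
        for name, value in self.init.items():
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS[name])
            if not lo <= value <= hi:
                raise SpecError(f"init for {name} = {value} outside bounds [{lo}, {hi}]")

    @property
    def parameter_names(self) -> List[str]:
        names = ["cl_typical", "v"]
        if self.effluent_covariate:
            names.append("cov_effluent")
        names += _MODEL_PARAMS[self.adsorption_model]
        names += ["omega_cl", "sigma_add"]
        if self.error_model == "combined":
            names.append("sigma_prop")
        return names

    @property
    def free_names(self) -> List[str]:
        return [n for n in self.parameter_names if n not in self.fixed]

    def build_params(self, values: Dict[str, float]) -> PKParameters:
        d = {"adsorption_model": self.adsorption_model}
        merged = {**self.fixed, **values}
        for n in self.parameter_names:
            if n in ("sigma_prop",):
                continue
            if n == "cov_effluent":
                d[n] = merged.get(n, 0.0)
            else:
                d[n] = merged[n]
        if not self.effluent_covariate:
            d["cov_effluent"] = 0.0
        return PKParameters(**d)


@dataclass
class LRTResult:
    delta_ofv: float
    df: int
    significant: bool
    p_value: float
    threshold: float


@dataclass
class FitResult:
    """Estimates, objective value, empirical Bayes etas and diagnostics."""

    spec: ModelSpec
    estimates: PKParameters
    values: Dict[str, float]
    ofv: float
    etas: Dict[str, float]
    eta_shrinkage: Optional[float]
    converged: bool
    n_obs: int
    message: str = ""
    profile_cis: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "values": self.values,
            "ofv": self.ofv,
            "etas": self.etas,
            "eta_shrinkage": self.eta_shrinkage,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "profile_cis": {k: list(v) for k, v in self.profile_cis.items()},
            "ofv_convention": "-2LL excluding n*log(2*pi)",
            "diagnostics": self.diagnostics,
        }


class _SubjectData:
    """Precompiled per-subject design: segments + observation vector."""

    def __init__(self, sid: str, ds: StudyDataset):
        events = ds.events_for(sid)
        obs = [(e.time, e.dv) for e in events if e.evid == 0 and e.mdv == 0]
        self.sid = sid
        self.obs_t = np.array([t for t, _ in obs])
        self.y = np.array([y for _, y in obs])
        horizon = max(self.obs_t.max() if len(obs) else 0.0, 0.0)
        self.seg: Segments = build_segments(events, horizon=horizon)


def _compile(ds: StudyDataset) -> List[_SubjectData]:
    ds.require_estimable()
    return [_SubjectData(sid, ds) for sid in ds.subject_ids]


def _residual_var(spec: ModelSpec, values: Dict[str, float], f: np.ndarray) -> np.ndarray:
    sig = values["sigma_add"]
    if spec.error_model == "additive":
        return np.full_like(f, sig**2)
    if spec.error_model == "proportional":
        return (sig * np.maximum(np.abs(f), 1e-6)) ** 2
    return sig**2 + (values.get("sigma_prop", 0.0) * np.maximum(np.abs(f), 1e-6)) ** 2


def _conditional_m2ll(eta: float, sub: _SubjectData, params: PKParameters,
                      spec: ModelSpec, values: Dict[str, float]) -> float:
    """-2 log of (residual density x eta prior), without 2*pi constants."""
    f = predict_concentrations(params, eta, sub.seg, sub.obs_t)
    var = _residual_var(spec, values, f)
    r = sub.y - f
    out = float(np.sum(r * r / var) + np.sum(np.log(var)))
    omega = params.omega_cl
    if omega > 0:
        out += eta * eta / omega**2
    return out


def _inner_eta(sub: _SubjectData, params: PKParameters, spec: ModelSpec,
               values: Dict[str, float], tol: float = 1e-10) -> Tuple[float, float, float]:
    """Posterior mode of eta with curvature; returns (eta*, g(eta*), g''(eta*)).

    Safeguarded Newton from 0 with central finite differences, falling back
    to a bounded scalar minimisation if Newton leaves its trust region.
    """
    omega = params.omega_cl
    g = lambda e: _conditional_m2ll(e, sub, params, spec, values)
    if omega == 0.0:
        val = g(0.0)
        return 0.0, val, math.inf
    h = 1e-4
    eta = 0.0
    lo, hi = -6.0 * omega - 1.0, 6.0 * omega + 1.0
    ok = False
    for _ in range(60):
        g0, gp, gm = g(eta), g(eta + h), g(eta - h)
        d1 = (gp - gm) / (2 * h)
        d2 = (gp - 2 * g0 + gm) / (h * h)
        if not np.isfinite(d1) or not np.isfinite(d2) or d2 <= 0:
            break
        step = -d1 / d2
        step = max(min(step, 0.5 * (hi - eta)), 0.5 * (lo - eta))
        eta_new = eta + step
        if abs(step) < tol:
            eta = eta_new
            ok = True
            break
        eta = eta_new
    if not ok and abs(eta) > 5.0 * omega + 0.5:
        res = optimize.minimize_scalar(g, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        eta = float(res.x)
    g0, gp, gm = g(eta), g(eta + h), g(eta - h)
    d2 = (gp - 2 * g0 + gm) / (h * h)
    if not np.isfinite(d2) or d2 <= 0:
        d2 = 2.0 / omega**2
    return eta, g0, d2


def neg2_loglik(
    spec: ModelSpec,
    values: Dict[str, float],
    ds: StudyDataset,
    _compiled: Optional[List[_SubjectData]] = None,
    return_etas: bool = False,
):
    """Laplace-approximate marginal -2 log-likelihood (OFV).

    Convention: the n*log(2*pi) additive constant is dropped, so only
    differences between models fitted to the same data are meaningful.
    A failed inner optimisation marks the point as rejected (OFV = +inf).
    """
    subs = _compiled if _compiled is not None else _compile(ds)
    try:
        params = spec.build_params(values)
    except Exception:
        return (math.inf, {}) if return_etas else math.inf
    values = {**spec.fixed, **values}
    omega = params.omega_cl
    total = 0.0
    etas: Dict[str, float] = {}
    for sub in subs:
        try:
            eta, gval, d2 = _inner_eta(sub, params, spec, values)
        except Exception:
            return (math.inf, {}) if return_etas else math.inf
        if not np.isfinite(gval):
            return (math.inf, {}) if return_etas else math.inf
        if omega > 0:
            # OFV_i = g(eta*) + log(omega^2 * g''(eta*) / 2)
            total += gval + math.log(omega**2 * d2 / 2.0)
        else:
            total += gval
        etas[sub.sid] = eta
    return (total, etas) if return_etas else total


def _transform(spec: ModelSpec, values: Dict[str, float]) -> np.ndarray:
    return np.array(
        [math.log(values[n]) if n in _LOG_SCALE else values[n]
         for n in spec.free_names]
    )


def _untransform(spec: ModelSpec, x: np.ndarray) -> Dict[str, float]:
    return {
        n: (math.exp(v) if n in _LOG_SCALE else float(v))
        for n, v in zip(spec.free_names, x)
    }


_DEFAULT_INIT = {
    "cl_typical": 3.0, "v": 80.0, "cov_effluent": 1e-4, "k_max": 0.05,
    "a_max": 500.0, "a50": 300.0, "theta_cyto": 1.0, "omega_cl": 0.2,
    "sigma_add": 3.0, "sigma_prop": 0.2,
}


def fit(
    spec: ModelSpec,
    ds: StudyDataset,
    start: Optional[Dict[str, float]] = None,
    maxiter: int = 2000,
    profile: Sequence[str] = (),
    level: float = 0.90,
) -> FitResult:
    """Bounded local minimisation of the Laplace OFV (Nelder-Mead on the
    transformed scale).  Deterministic given the start and the dataset;
    non-convergence is flagged, never silently accepted."""
    subs = _compile(ds)
    free = spec.free_names
    if not free:
        raise SpecError("nothing to estimate: all parameters fixed")
    n_obs = sum(len(s.y) for s in subs)
    if n_obs < len(free):
        raise SpecError(
            f"{n_obs} observations cannot identify {len(free)} free parameters"
        )
    init = {n: spec.init.get(n, _DEFAULT_INIT[n]) for n in free}
    if start:
        init.update({n: v for n, v in start.items() if n in free})
    x0 = _transform(spec, init)
    bounds = []
    for n in free:
        lo, hi = spec.bounds.get(n, DEFAULT_BOUNDS[n])
        bounds.append((math.log(lo), math.log(hi)) if n in _LOG_SCALE else (lo, hi))

    def objective(x: np.ndarray) -> float:
        return neg2_loglik(spec, _untransform(spec, x), ds, _compiled=subs)

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead", bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-7, "adaptive": True},
    )
    values = _untransform(spec, res.x)
    ofv, etas = neg2_loglik(spec, values, ds, _compiled=subs, return_etas=True)
    params = spec.build_params(values)
    shr = None
    if params.omega_cl > 0 and len(etas) >= 2:
        shr = shrinkage_from_etas(list(etas.values()), params.omega_cl)
    result = FitResult(
        spec=spec, estimates=params, values={**spec.fixed, **values}, ofv=ofv,
        etas=etas, eta_shrinkage=shr, converged=bool(res.success), n_obs=n_obs,
        message=str(res.message),
        diagnostics={"nfev": int(res.nfev), "nit": int(res.nit)},
    )
    for name in profile:
        result.profile_cis[name] = profile_ci(spec, ds, result, name, level=level)
    return result


def lrt(ofv_reduced: float, ofv_full: float, df: int = 1, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio test for nested models.

    Significant iff ofv_full - ofv_reduced < -chi2_{df, 1-alpha} (strict;
    a drop of exactly 3.84 for df=1 is *not* significant)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    threshold = float(stats.chi2.ppf(1.0 - alpha, df))
    delta = ofv_full - ofv_reduced
    p = float(stats.chi2.sf(max(-delta, 0.0), df))
    return LRTResult(
        delta_ofv=float(delta), df=df, significant=bool(delta < -threshold),
        p_value=p, threshold=threshold,
    )


def profile_ci(
    spec: ModelSpec,
    ds: StudyDataset,
    fit_result: FitResult,
    param_name: str,
    level: float = 0.90,
    ofv_tol: float = 0.05,
    maxiter_inner: int = 150,
) -> Tuple[float, float]:
    """Profile-likelihood confidence interval for one free parameter.

    Each side brackets the OFV crossing (estimate stepped geometrically for
    log-scale parameters) and bisects until the profiled OFV is within
    ``ofv_tol`` of the chi-square cutoff, re-optimising all other free
    parameters at every step.  A side that never crosses inside the
    parameter box is reported at the box edge (one-sided interval)."""
    if param_name not in spec.free_names:
        raise SpecError(f"{param_name} is not a free parameter of this spec")
    if level <= 0.0:
        est0 = fit_result.values[param_name]
        return (est0, est0)
    subs = _compile(ds)
    rise = float(stats.chi2.ppf(level, 1))
    target = fit_result.ofv + rise
    others = [n for n in spec.free_names if n != param_name]
    est = fit_result.values[param_name]
    warm = {n: fit_result.values[n] for n in others}
    lo_b, hi_b = spec.bounds.get(param_name, DEFAULT_BOUNDS[param_name])
    log_scale = param_name in _LOG_SCALE

    def profiled(value: float, warm_vals: Dict[str, float]) -> Tuple[float, Dict[str, float]]:
        if not others:
            v = dict(warm_vals)
            v[param_name] = value
            return neg2_loglik(spec, v, ds, _compiled=subs), warm_vals
        sub_spec = ModelSpec(
            adsorption_model=spec.adsorption_model,
            effluent_covariate=spec.effluent_covariate,
            fixed={**spec.fixed, param_name: value},
            bounds=spec.bounds, error_model=spec.error_model,
        )
        x0 = _transform_sub(sub_spec, warm_vals)
        bnds = []
        for n in sub_spec.free_names:
            lo, hi = sub_spec.bounds.get(n, DEFAULT_BOUNDS[n])
            bnds.append((math.log(lo), math.log(hi)) if n in _LOG_SCALE else (lo, hi))
        res = optimize.minimize(
            lambda x: neg2_loglik(sub_spec, _untransform(sub_spec, x), ds, _compiled=subs),
            x0, method="Nelder-Mead", bounds=bnds,
            options={"maxiter": maxiter_inner, "xatol": 1e-4, "fatol": 1e-4},
        )
        vals = _untransform(sub_spec, res.x)
        return float(res.fun), vals

    def _transform_sub(sub_spec, vals):
        return np.array(
            [math.log(vals[n]) if n in _LOG_SCALE else vals[n]
             for n in sub_spec.free_names]
        )

    def solve_side(direction: int) -> float:
        # bracket
        step = 1.6 if log_scale else max(abs(est), 1.0) * 0.5
        inner_v, inner_ofv, warm_v = est, fit_result.ofv, dict(warm)
        value = est
        for _ in range(40):
            if log_scale:
                value = value * step if direction > 0 else value / step
            else:
                value = value + direction * step
            value = min(max(value, lo_b), hi_b)
            ofv_v, warm_v = profiled(value, warm_v)
            if ofv_v >= target:
                outer_v, outer_ofv = value, ofv_v
                break
            inner_v, inner_ofv = value, ofv_v
            if value in (lo_b, hi_b):
                return value  # one-sided: no crossing inside the box
        else:
            return value
        for _ in range(60):
            if abs(outer_v - inner_v) <= 2e-3 * max(abs(inner_v), abs(outer_v), 1e-12):
                break
            if log_scale:
                mid = math.sqrt(inner_v * outer_v)
            else:
                mid = 0.5 * (inner_v + outer_v)
            ofv_m, warm_v = profiled(mid, warm_v)
            if abs(ofv_m - target) < ofv_tol:
                return mid
            if ofv_m < target:
                inner_v = mid
            else:
                outer_v = mid
        return 0.5 * (inner_v + outer_v) if not log_scale else math.sqrt(inner_v * outer_v)

    lower = solve_side(-1)
    upper = solve_side(+1)
    lower = min(lower, est)
    upper = max(upper, est)
    return (lower, upper)


def shrinkage_from_etas(etas: Sequence[float], omega: float) -> float:
    """Eta-shrinkage in percent: 100 * (1 - SD(EBE)/omega)."""
    if omega <= 0:
        raise ValueError("shrinkage undefined for omega = 0")
    return 100.0 * (1.0 - float(np.std(etas, ddof=1)) / omega)


def shrinkage(fit_result: FitResult, ds: Optional[StudyDataset] = None) -> float:
    omega = fit_result.estimates.omega_cl
    if omega <= 0:
        raise ValueError("shrinkage undefined for omega = 0")
    return shrinkage_from_etas(list(fit_result.etas.values()), omega)


def gof_table(fit_result: FitResult, ds: StudyDataset) -> pd.DataFrame:
    """Per-observation goodness-of-fit quantities.

    PRED: typical-subject prediction (eta = 0); IPRED: empirical-Bayes
    individual prediction; RES/IRES the corresponding residuals; IWRES the
    individual residual scaled by the residual SD; CWRES the conditional
    weighted residual from the first-order linearisation of the model around
    the EBE."""
    subs = _compile(ds)
    spec, params = fit_result.spec, fit_result.estimates
    values = fit_result.values
    omega = params.omega_cl
    rows = []
    for sub in subs:
        eta = fit_result.etas.get(sub.sid, 0.0)
        pred = predict_concentrations(params, 0.0, sub.seg, sub.obs_t)
        ipred = predict_concentrations(params, eta, sub.seg, sub.obs_t)
        var = _residual_var(spec, values, ipred)
        h = 1e-4
        dfde = (
            predict_concentrations(params, eta + h, sub.seg, sub.obs_t)
            - predict_concentrations(params, eta - h, sub.seg, sub.obs_t)
        ) / (2 * h)
        if omega > 0:
            cov = omega**2 * np.outer(dfde, dfde) + np.diag(var)
            mean_lin = ipred - dfde * eta
            L = np.linalg.cholesky(cov)
            cwres = np.linalg.solve(L, sub.y - mean_lin)
        else:
            cwres = (sub.y - pred) / np.sqrt(var)
        for k in range(len(sub.y)):
            rows.append(
                {
                    "id": sub.sid, "time": sub.obs_t[k], "dv": sub.y[k],
                    "pred": pred[k], "ipred": ipred[k],
                    "res": sub.y[k] - pred[k], "ires": sub.y[k] - ipred[k],
                    "iwres": (sub.y[k] - ipred[k]) / math.sqrt(var[k]),
                    "cwres": float(cwres[k]), "eta": eta,
                }
            )
    return pd.DataFrame(rows)
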