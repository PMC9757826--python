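"""Model specification, likelihood assembly, and maximum-likelihood fitting.

A :class:`ModelSpec` combines a utility family (EV, AU, non-linear EU/PT
variants, selective integration, adaptive gain, divisive normalisation) with
a response process: 'static' (softmax over utilities, binomial likelihood of
per-condition choice proportions), 'ffi' (joint choice/RT likelihood of the
feedforward-inhibition race), or 'dual' (dual-route race).  Fitting uses
bounded multi-start local optimisation with Latin-hypercube starting values
and is deterministic under a seed.  Trials where the distractor was chosen,
and non-responses, are excluded from all likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import race as _race
from .race import DualRouteParams, FFIParams, LIKELIHOOD_FLOOR
from .trials import TrialTable, add_condition_keys
from .utility import (
    AdaptiveGainParams,
    DistortionParams,
    SIParams,
    adaptive_gain_transform,
    distort_magnitude,
    distort_probability,
    divisive_normalize,
    selective_integration_gate,
)

__all__ = [
    "SoftmaxParams",
    "ModelSpec",
    "FitResult",
    "CVResult",
    "model_spec",
    "softmax_choice_prob",
    "binomial_loglik",
    "joint_loglik",
    "static_loglik",
    "compute_utilities",
    "fit_model",
    "crossvalidate",
    "bic",
    "MODEL_NAMES",
]


@dataclass(frozen=True)
class SoftmaxParams:
    """Softmax decision noise: inverse temperature beta >= 0."""

    beta: float

    def __post_init__(self):
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError("beta must be finite and >= 0")


# Default parameter bounds; the task's attributes live on [0, 1] scales.
DEFAULT_BOUNDS = {
    "lam": (0.0, 1.0),
    "beta": (0.0, 100.0),
    "k": (1e-3, 50.0),
    "theta": (0.05, 10.0),
    "c": (0.0, 1.0),
    "fMI": (0.0, 1.0),
    "I0": (0.0, 10.0),
    "tnd": (0.0, None),  # upper bound resolved to 0.9 * min observed RT
    "w": (0.0, 1.0),
    "w2": (0.0, 1.0),
    "w3": (0.0, 1.0),
    "s": (0.01, 2.0),
    "b": (-1.0, 1.0),
    "eta": (0.05, 20.0),
    "p0": (0.01, 0.99),
    "gamma": (0.05, 20.0),
    "tau": (0.05, 20.0),
}

_FAMILY_PARAMS = {
    "ev": [],
    "au": ["lam"],
    "au_nonlinear": ["lam", "eta", "p0", "gamma"],
    "eu": ["gamma"],
    "pt": ["gamma", "tau"],
    "dn": [],
    "si": ["lam", "w2", "w3"],
    "si_binary": ["lam", "w"],
    "adaptive_gain": ["lam", "s", "b"],
}

_DYNAMICS_PARAMS = {
    "static": ["beta"],
    "ffi": ["k", "theta", "c", "tnd"],
    "dual": ["k", "theta", "fMI", "tnd"],
}


@dataclass
class ModelSpec:
    """A utility family plus a response process, with free/fixed parameters."""

    name: str
    family: str
    dynamics: str
    free: dict = field(default_factory=dict)   # name -> (lo, hi)
    fixed: dict = field(default_factory=dict)  # name -> value
    options: dict = field(default_factory=dict)

    @property
    def param_names(self):
        return list(self.free)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def params_from_vector(self, x) -> dict:
        p = dict(self.fixed)
        p.update(dict(zip(self.free, np.asarray(x, dtype=float))))
        return p

    def resolve_bounds(self, trials) -> list:
        """Finite bounds for every free parameter (tnd capped by observed RTs)."""
        bounds = []
        for name, (lo, hi) in self.free.items():
            if name == "tnd" and hi is None:
                rts = _included(trials_frame(trials), self.dynamics)["rt"].to_numpy(float)
                rts = rts[np.isfinite(rts)]
                hi = 0.9 * float(rts.min()) if len(rts) else 1.0
            bounds.append((lo, hi))
        return bounds


#: model registry names usable from configs and the CLI
MODEL_NAMES = [
    f"{fam}_{dyn}"
    for fam in _FAMILY_PARAMS
    for dyn in _DYNAMICS_PARAMS
]


def model_spec(name: str, fixed: dict | None = None, bounds: dict | None = None,
               options: dict | None = None) -> ModelSpec:
    """Build a ModelSpec from a registry name like 'au_static' or 'si_ffi'.

    The family is everything before the final underscore-separated dynamics
    token ('static', 'ffi' or 'dual').  ``fixed`` pins parameters (removing
    them from the free list); ``bounds`` overrides defaults per parameter.
    """
    parts = name.rsplit("_", 1)
    if len(parts) != 2 or parts[1] not in _DYNAMICS_PARAMS or parts[0] not in _FAMILY_PARAMS:
        raise ValueError(f"unknown model name {name!r}")
    family, dynamics = parts
    if family == "dn" and dynamics == "dual":
        raise ValueError("the dual-route model already embeds divisive normalisation")
    fixed = dict(fixed or {})
    names = _FAMILY_PARAMS[family] + _DYNAMICS_PARAMS[dynamics]
    free = {}
    for p in names:
        if p in fixed:
            continue
        lo, hi = (bounds or {}).get(p, DEFAULT_BOUNDS[p])
        free[p] = (lo, hi)
    return ModelSpec(name, family, dynamics, free, fixed, dict(options or {}))


# -- utilities per trial ---------------------------------------------------

def trials_frame(trials) -> pd.DataFrame:
    return trials.df if isinstance(trials, TrialTable) else trials


def _attr_matrices(df: pd.DataFrame, include_d: bool):
    cols_x = ["hx", "lx"] + (["dx"] if include_d else [])
    cols_p = ["hp", "lp"] + (["dp"] if include_d else [])
    return df[cols_x].to_numpy(float), df[cols_p].to_numpy(float)


def compute_utilities(df: pd.DataFrame, family: str, params: dict,
                      options: dict | None = None, include_d: bool = False) -> np.ndarray:
    """Per-trial utilities of the alternatives.

    Returns (n, 2) utilities of [H, L] (or (n, 3) including D when
    ``include_d``).  Context-dependent families (si, adaptive_gain, dn) use
    the full displayed choice set — including the unavailable distractor on
    ternary rows — to transform the attribute values, regardless of
    ``include_d`` in the output.
    """
    options = options or {}
    tern = (df["condition"] == "ternary").to_numpy()
    n_out = 3 if include_d else 2
    out = np.full((len(df), n_out), np.nan)

    def context_apply(fn):
        """Apply a context transform separately to binary and ternary rows."""
        for mask, with_d in ((~tern, False), (tern, True)):
            if not mask.any():
                continue
            x, p = _attr_matrices(df.loc[mask], with_d)
            u = fn(x, p)
            out[mask, : min(n_out, u.shape[1])] = u[:, :n_out]

    if family == "ev":
        x, p = _attr_matrices(df, include_d)
        out = x * p
    elif family in ("au", "au_nonlinear"):
        x, p = _attr_matrices(df, include_d)
        if family == "au_nonlinear":
            x = distort_magnitude(x, params["gamma"])
            p = distort_probability(
                p, "log-odds", DistortionParams(eta=params["eta"], p0=params["p0"])
            )
        out = params["lam"] * x + (1.0 - params["lam"]) * p
    elif family == "eu":
        x, p = _attr_matrices(df, include_d)
        out = distort_magnitude(x, params["gamma"]) * p
    elif family == "pt":
        x, p = _attr_matrices(df, include_d)
        pd_ = distort_probability(p, "kt", DistortionParams(tau=params["tau"]))
        out = distort_magnitude(x, params["gamma"]) * pd_
    elif family == "dn":
        def fn(x, p):
            return divisive_normalize(x * p)
        context_apply(fn)
    elif family in ("si", "si_binary"):
        w2 = params.get("w2", params.get("w"))
        w3 = params.get("w3", w2)
        # canonicalise so the likelihood stays smooth when the optimiser
        # wanders across w2 = w3
        lo, hi = min(w2, w3), max(w2, w3)
        si = SIParams(lo, hi)
        context_apply(lambda x, p: selective_integration_gate(x, p, si, params["lam"]))
    elif family == "adaptive_gain":
        if "s_x" in params:
            ag = AdaptiveGainParams(params["s_x"], params["b_x"], params["s_p"], params["b_p"])
        else:
            ag = AdaptiveGainParams.tied(params["s"], params["b"])
        context_apply(lambda x, p: adaptive_gain_transform(x, p, ag, params["lam"]))
    else:
        raise ValueError(f"unknown utility family {family!r}")
    return out


# -- likelihood building blocks --------------------------------------------

def softmax_choice_prob(utilities, params: SoftmaxParams | float) -> np.ndarray:
    """Softmax p(i) = exp(beta U_i) / sum_j exp(beta U_j), computed stably."""
    beta = params.beta if isinstance(params, SoftmaxParams) else float(params)
    u = np.asarray(utilities, dtype=float) * beta
    u = u - u.max(axis=-1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=-1, keepdims=True)


def binomial_loglik(p_model, p_empirical, weights, eps: float = LIKELIHOOD_FLOOR) -> float:
    """Weighted binomial log-likelihood sum w*[pe log pm + (1-pe) log(1-pm)]."""
    pm = np.clip(np.asarray(p_model, dtype=float), eps, 1.0 - eps)
    pe = np.asarray(p_empirical, dtype=float)
    if np.any((pe < 0) | (pe > 1)):
        raise ValueError("empirical proportions must lie in [0, 1]")
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * (pe * np.log(pm) + (1.0 - pe) * np.log1p(-pm))))


def _included(df: pd.DataFrame, dynamics: str) -> pd.DataFrame:
    """Trials entering the likelihood: H or L responses only."""
    m = df["choice"].isin(["H", "L"])
    if dynamics in ("ffi", "dual"):
        m &= np.isfinite(df["rt"].to_numpy(float))
    return df[m]


def prepare_static_data(trials) -> pd.DataFrame:
    """Collapse trials into unique conditions with empirical p(H over L) and counts."""
    df = add_condition_keys(trials_frame(trials))
    inc = _included(df, "static")
    if len(inc) == 0:
        raise ValueError("no H/L-response trials to fit")
    rows = []
    for key, g in inc.groupby(["condition", "cond_key"], sort=False):
        first = g.iloc[0]
        rows.append(
            {
                "condition": key[0],
                "hx": first["hx"], "hp": first["hp"],
                "lx": first["lx"], "lp": first["lp"],
                "dx": first["dx"], "dp": first["dp"],
                "p_emp": float((g["choice"] == "H").mean()),
                "weight": len(g),
            }
        )
    return pd.DataFrame(rows)


def static_loglik(trials, spec: ModelSpec, params: dict,
                  _cond: pd.DataFrame | None = None) -> float:
    """Binomial log-likelihood of per-condition choice proportions."""
    cond = _cond if _cond is not None else prepare_static_data(trials)
    u = compute_utilities(cond, spec.family, params, spec.options)
    pm = softmax_choice_prob(u, params["beta"])[:, 0]
    return binomial_loglik(pm, cond["p_emp"].to_numpy(), cond["weight"].to_numpy())


def joint_loglik(trials, spec: ModelSpec, params: dict) -> float:
    """Joint choice/RT log-likelihood summed over included trials.

    Per-trial likelihoods are floored at ``LIKELIHOOD_FLOOR`` before taking
    logs so RTs faster than the fitted non-decision time stay finite.
    """
    if spec.dynamics == "static":
        return static_loglik(trials, spec, params)
    df = _included(trials_frame(trials), spec.dynamics)
    if len(df) == 0:
        raise ValueError("no included trials for the joint likelihood")
    terms = trial_likelihoods(df, spec, params)
    return float(np.sum(np.log(np.maximum(terms, LIKELIHOOD_FLOOR))))


def trial_likelihoods(df: pd.DataFrame, spec: ModelSpec, params: dict) -> np.ndarray:
    """Vector of per-trial likelihood densities for dynamic models."""
    chosen = (df["choice"] == "L").to_numpy(int)  # H -> 0, L -> 1
    T = df["rt"].to_numpy(float) - params["tnd"]
    if spec.dynamics == "ffi":
        u = compute_utilities(df, spec.family, params, spec.options)
        p = FFIParams(k=params["k"], theta=params["theta"], c=params.get("c", 1.0),
                      I0=params.get("I0", 0.0), tnd=params["tnd"])
        mu = _race.drift_rates(u, p)
        return _race.ffi_likelihood_terms(np.maximum(T, 0.0), mu, chosen, p.theta) * (T > 0)
    if spec.dynamics == "dual":
        p = DualRouteParams(k=params["k"], theta=params["theta"], fMI=params.get("fMI", 0.0),
                            I0=params.get("I0", 0.0), tnd=params["tnd"])
        out = np.zeros(len(df))
        tern = (df["condition"] == "ternary").to_numpy()
        for mask, with_d in ((~tern, False), (tern, True)):
            if not mask.any():
                continue
            u = compute_utilities(df.loc[mask], "ev", params, include_d=with_d)
            out[mask] = _race.dual_likelihood_terms(
                np.maximum(T[mask], 0.0), u, chosen[mask], p
            ) * (T[mask] > 0)
        return out
    raise ValueError(f"unknown dynamics {spec.dynamics!r}")


# -- fitting ---------------------------------------------------------------

@dataclass
class FitResult:
    """Best-of-multi-start maximum-likelihood fit."""

    model: str
    params: dict
    loglik: float
    n_obs: int
    starts: list
    seed: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "seed": int(self.seed),
        }


@dataclass
class CVResult:
    """K-fold cross-validation: held-out log-likelihood per fold and mean."""

    model: str
    fold_logliks: list
    mean_loglik: float
    fold_assignment: np.ndarray
    seed: int


def _objective(trials, spec: ModelSpec):
    if spec.dynamics == "static":
        cond = prepare_static_data(trials)

        def f(x):
            return -static_loglik(None, spec, spec.params_from_vector(x), _cond=cond)
    else:
        df = _included(trials_frame(trials), spec.dynamics).copy()
        if len(df) == 0:
            raise ValueError("no included trials to fit")

        def f(x):
            params = spec.params_from_vector(x)
            terms = trial_likelihoods(df, spec, params)
            return -float(np.sum(np.log(np.maximum(terms, LIKELIHOOD_FLOOR))))

    return f


def fit_model(trials, spec: ModelSpec, nstarts: int = 10, seed: int = 0) -> FitResult:
    """Maximum-likelihood fit with Latin-hypercube multi-start (deterministic).

    Each start runs bounded L-BFGS-B with tight tolerances; the best
    converged start is returned together with per-start diagnostics.
    """
    if nstarts < 1:
        raise ValueError("nstarts must be >= 1")
    bounds = spec.resolve_bounds(trials)
    neg = _objective(trials, spec)
    n_obs = len(_included(trials_frame(trials), spec.dynamics))
    d = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if d > 0:
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        starts = lo + sampler.random(nstarts) * (hi - lo)
        # keep starts strictly interior
        starts = np.clip(starts, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo))
    else:
        starts = np.zeros((1, 0))
    per_start = []
    best = None
    for x0 in starts:
        try:
            res = optimize.minimize(
                neg, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-10, "gtol": 1e-8, "maxfun": 5000, "maxiter": 5000},
            )
            per_start.append({"x0": x0.tolist(), "x": res.x.tolist(),
                              "loglik": -float(res.fun), "success": bool(res.success)})
            if best is None or -res.fun > best[1]:
                best = (res.x, -float(res.fun), bool(res.success))
        except Exception as exc:  # keep other starts alive
            per_start.append({"x0": x0.tolist(), "error": str(exc)})
    if best is None:
        raise RuntimeError(f"all {nstarts} starts failed: {per_start}")
    params = spec.params_from_vector(best[0])
    if spec.family in ("si", "si_binary") and "w2" in params and "w3" in params:
        params["w2"], params["w3"] = (
            min(params["w2"], params["w3"]),
            max(params["w2"], params["w3"]),
        )
    return FitResult(spec.name, params, best[1], n_obs, per_start, seed, best[2])


def _stratified_folds(df: pd.DataFrame, kfolds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels, stratified by condition type when both are present."""
    fold = np.empty(len(df), dtype=int)
    pos = {c: np.flatnonzero((df["condition"] == c).to_numpy()) for c in df["condition"].unique()}
    for idxs in pos.values():
        perm = rng.permutation(idxs)
        fold[perm] = np.arange(len(perm)) % kfolds
    return fold


def crossvalidate(trials, spec: ModelSpec, kfolds: int = 5, seed: int = 0,
                  nstarts: int = 10) -> CVResult:
    """K-fold cross-validation; mean held-out log-likelihood across folds.

    Folds partition the trials (stratified by binary/ternary condition);
    models are refit on each training set and evaluated by summed
    log-likelihood on the held-out fold.
    """
    df = trials_frame(trials).reset_index(drop=True)
    if kfolds < 2 or len(df) < kfolds:
        raise ValueError("need kfolds >= 2 and at least kfolds trials")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(df, kfolds, rng)
    fold_lls = []
    for f in range(kfolds):
        train = df[fold != f]
        test = df[fold == f]
        if len(_included(test, spec.dynamics)) == 0:
            raise ValueError(f"fold {f} has no includable trials")
        fit = fit_model(train, spec, nstarts=nstarts, seed=seed + 1000 * (f + 1))
        if spec.dynamics == "static":
            fold_lls.append(static_loglik(test, spec, fit.params))
        else:
            fold_lls.append(joint_loglik(test, spec, fit.params))
    return CVResult(spec.name, fold_lls, float(np.mean(fold_lls)), fold, seed)


def bic(ll: float, nparams: int, nobs: int) -> float:
    """Bayesian information criterion: nparams*ln(nobs) - 2*ll."""
    if nobs < 1:
        raise ValueError("nobs must be >= 1")
    return nparams * np.log(nobs) - 2.0 * ll
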