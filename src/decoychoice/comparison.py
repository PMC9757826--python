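"""Random-effects Bayesian model selection and recovery harnesses.

``rfx_bms`` implements the standard variational scheme for group-level model
comparison: subjects are treated as random effects drawn from a population
distribution over models with Dirichlet-distributed frequencies.  The
variational posterior over frequencies yields posterior model frequencies,
exceedance probabilities (estimated by Dirichlet sampling), and the Bayes
omnibus risk (BOR) — the posterior probability that all models are equally
frequent — used to form protected exceedance probabilities
pxp = xp*(1 - BOR) + BOR/K.

``model_recovery`` and ``parameter_recovery`` close the loop: simulate each
model with fitted/known parameters, refit all candidates, and summarise how
reliably the generating model (or its parameters) is identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .fitting import ModelSpec, bic, fit_model, joint_loglik

__all__ = [
    "BMSResult",
    "ConfusionMatrix",
    "rfx_bms",
    "model_recovery",
    "parameter_recovery",
]


@dataclass
class BMSResult:
    """Random-effects model-selection output."""

    alpha: np.ndarray          # Dirichlet posterior parameters
    frequencies: np.ndarray    # posterior model frequencies (simplex)
    xp: np.ndarray             # exceedance probabilities (simplex)
    bor: float                 # Bayes omnibus risk in [0, 1]
    pxp: np.ndarray            # protected exceedance probabilities (simplex)
    models: list | None = None


@dataclass
class ConfusionMatrix:
    """Generating-model (rows) x fitted-model (columns) recovery summary."""

    models: list
    frequencies: np.ndarray  # rows are simplexes of posterior frequencies
    pxp: np.ndarray          # protected exceedance per generating model


def _dirichlet_exceedance(alpha: np.ndarray, nsamples: int, rng: np.random.Generator) -> np.ndarray:
    if np.allclose(alpha, alpha[0]):
        # exchangeable posterior: exceedance is exactly uniform
        return np.full(len(alpha), 1.0 / len(alpha))
    draws = rng.dirichlet(alpha, size=nsamples)
    win = np.argmax(draws, axis=1)
    return np.bincount(win, minlength=len(alpha)) / nsamples


def rfx_bms(
    evidence,
    nsamples: int = 100_000,
    seed: int = 0,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    models: list | None = None,
) -> BMSResult:
    """Variational random-effects model selection over a subjects x models
    log-evidence matrix (cross-validated log-likelihoods or -BIC/2).

    Iterates the Dirichlet update alpha_k = alpha0 + sum_n g_nk, where g_nk
    is subject n's posterior over models; exceedance probabilities come from
    sampling the converged Dirichlet, and protection applies the Bayes
    omnibus risk correction toward chance 1/K.
    """
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(lme)):
        bad = np.argwhere(~np.isfinite(lme))[0]
        raise ValueError(f"non-finite evidence at subject {bad[0]}, model {bad[1]}")
    n, K = lme.shape
    alpha = np.full(K, float(alpha0))
    g = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        elog_r = digamma(alpha) - digamma(alpha.sum())
        logu = lme + elog_r
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    freq = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    xp = _dirichlet_exceedance(alpha, nsamples, rng)

    # Bayes omnibus risk: compare the variational free energy of the
    # random-effects model (H1) with the equal-frequency null (H0).
    elog_r = digamma(alpha) - digamma(alpha.sum())
    a0 = np.full(K, float(alpha0))
    elj = (
        gammaln(a0.sum()) - gammaln(a0).sum() + ((a0 - 1.0) * elog_r).sum()
        + np.sum(g * (lme + elog_r))
    )
    sqf = gammaln(alpha).sum() - gammaln(alpha.sum()) - ((alpha - 1.0) * elog_r).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        sqm = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    f1 = elj + sqf + sqm
    f0 = float(np.sum(logsumexp(lme, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = xp * (1.0 - bor) + bor / K
    return BMSResult(alpha, freq, xp, bor, pxp, models)


def model_recovery(
    specs: list,
    fitted: list,
    trialset,
    seed: int = 0,
    nstarts: int = 5,
    evidence: str = "bic",
    bms_seed: int = 0,
    deadline: float | None = None,
) -> ConfusionMatrix:
    """Simulate each model with fitted parameters, refit all, and compare.

    ``specs``: candidate ModelSpecs; ``fitted``: per-subject dicts mapping
    spec.name -> parameter dict (the generating parameters); ``trialset``:
    the trial design every agent is run on.  Evidence for the random-effects
    comparison is -BIC/2 ('bic') or the raw maximised log-likelihood ('ll').
    Deterministic under ``seed``.
    """
    from .synth import AgentSpec, simulate_agent  # deferred: synth imports fitting

    K = len(specs)
    names = [s.name for s in specs]
    freq = np.zeros((K, K))
    pxp = np.zeros((K, K))
    rng = np.random.default_rng(seed)
    for gi, gen_spec in enumerate(specs):
        rows = []
        for subj, params_by_model in enumerate(fitted):
            agent = AgentSpec(gen_spec, params_by_model[gen_spec.name],
                              deadline=deadline)
            sim = simulate_agent(trialset, agent, seed=int(rng.integers(2**31 - 1)))
            if len(sim.df[sim.df["choice"].isin(["H", "L"])]) == 0:
                raise RuntimeError(f"simulation of {gen_spec.name} yielded no valid trials")
            row = []
            for fit_spec in specs:
                res = fit_model(sim, fit_spec, nstarts=nstarts,
                                seed=int(rng.integers(2**31 - 1)))
                if evidence == "bic":
                    row.append(-0.5 * bic(res.loglik, fit_spec.n_free, res.n_obs))
                else:
                    row.append(res.loglik)
            rows.append(row)
        res = rfx_bms(np.asarray(rows), seed=bms_seed + gi, models=names)
        freq[gi] = res.frequencies
        pxp[gi] = res.pxp
    return ConfusionMatrix(names, freq, pxp)


def parameter_recovery(
    spec: ModelSpec,
    true_params: list,
    trialset,
    seed: int = 0,
    nstarts: int = 5,
    deadline: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-refit parameter recovery for one model.

    ``true_params``: list of parameter dicts (>= 2 to compute correlations;
    the spec's recovery studies use >= 10).  Returns (table, summary): the
    table holds true and recovered values per free parameter and agent, the
    summary per-parameter Pearson correlation, bias, and RMSE.
    """
    from .synth import AgentSpec, simulate_agent

    rng = np.random.default_rng(seed)
    records = []
    for i, tp in enumerate(true_params):
        agent = AgentSpec(spec, tp, deadline=deadline)
        sim = simulate_agent(trialset, agent, seed=int(rng.integers(2**31 - 1)))
        res = fit_model(sim, spec, nstarts=nstarts, seed=int(rng.integers(2**31 - 1)))
        for p in spec.param_names:
            records.append(
                {"agent": i, "param": p, "true": float(tp[p]),
                 "recovered": float(res.params[p]), "loglik": res.loglik}
            )
    table = pd.DataFrame(records)
    rows = []
    for p, g in table.groupby("param"):
        err = g["recovered"] - g["true"]
        corr = np.nan
        if g["true"].nunique() > 1 and g["recovered"].nunique() > 1:
            corr = float(np.corrcoef(g["true"], g["recovered"])[0, 1])
        rows.append({"param": p, "corr": corr, "bias": float(err.mean()),
                     "rmse": float(np.sqrt((err**2).mean()))})
    return table, pd.DataFrame(rows)
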