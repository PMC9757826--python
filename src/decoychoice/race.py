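"""Analytic choice/RT likelihoods for feedforward-inhibition race models.

Each alternative i drives an independent diffusion accumulator
``dx_i = (k*I_i + I0) dt + xi*sqrt(dt)`` with unit noise variance, zero
starting point, and an absorbing bound theta; the first accumulator to reach
the bound determines the choice and the decision time.  The evidence input
``I_i`` is the alternative's utility minus a scaled mean of its competitors'
utilities (feedforward inhibition, strength c: c=0 is a pure race, c=1 a
drift-diffusion model).  Single-accumulator first-passage times are inverse
Gaussian, so the joint choice/RT likelihood has a closed form: the chosen
accumulator's first-passage density times the survival of every competitor.

A dual-route variant races two parallel processes per alternative — one on
mutually inhibited raw utilities, one on divisively normalised utilities —
and responds with whichever accumulator absorbs first.

A vectorised Euler--Maruyama simulator (optionally with a Brownian-bridge
crossing correction, which removes the leading-order discretisation bias)
serves as a stochastic oracle and as the generative engine for agents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr

from .utility import divisive_normalize

__all__ = [
    "FFIParams",
    "DualRouteParams",
    "SimSettings",
    "drift_rates",
    "dual_route_drifts",
    "fpt_density",
    "fpt_cdf",
    "fpt_survival",
    "choice_rt_likelihood",
    "dual_route_likelihood",
    "choice_probability",
    "mean_rt",
    "simulate_race",
    "simulate_paths",
    "ffi_likelihood_terms",
    "dual_likelihood_terms",
]

LIKELIHOOD_FLOOR = 1e-10  # trial likelihoods are floored before logging


@dataclass(frozen=True)
class FFIParams:
    """Feedforward-inhibition race parameters (sigma = 1, x0 = 0 fixed).

    k: drift sensitivity (>0); I0: baseline drift; c: inhibition strength
    in [0, 1]; theta: decision bound (>0); tnd: non-decision time (s).
    """

    k: float
    theta: float
    c: float = 1.0
    I0: float = 0.0
    tnd: float = 0.0

    def __post_init__(self):
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("k and theta must be > 0")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if self.tnd < 0:
            raise ValueError("tnd must be >= 0")


@dataclass(frozen=True)
class DualRouteParams:
    """Dual-route (mutual inhibition + divisive normalisation) parameters.

    fMI: mutual-inhibition strength; k, I0, theta, tnd as in FFIParams;
    sigma fixed at 1 for both routes.
    """

    k: float
    theta: float
    fMI: float = 0.0
    I0: float = 0.0
    tnd: float = 0.0

    def __post_init__(self):
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("k and theta must be > 0")
        if self.tnd < 0:
            raise ValueError("tnd must be >= 0")


@dataclass(frozen=True)
class SimSettings:
    """Numerical settings for integration grids and path simulation."""

    dt: float = 0.001
    tmax: float = 100.0
    npaths: int = 10_000
    seed: int = 0
    bridge: bool = True

    def __post_init__(self):
        if self.dt <= 0 or self.tmax <= self.dt:
            raise ValueError("require dt > 0 and tmax > dt")
        if self.npaths < 1:
            raise ValueError("npaths must be >= 1")


DEFAULT_GRID = SimSettings()


# -- drifts ----------------------------------------------------------------

def drift_rates(utilities, params: FFIParams) -> np.ndarray:
    """FFI drift mu_i = k*U_i - c*k*mean_{j != i}(U_j) + I0.

    Accepts a 1-D utility vector or an (n_trials, n_alternatives) matrix.
    """
    u = np.asarray(utilities, dtype=float)
    n = u.shape[-1]
    if n < 2:
        raise ValueError("need at least two alternatives")
    others_mean = (u.sum(axis=-1, keepdims=True) - u) / (n - 1)
    return params.k * u - params.c * params.k * others_mean + params.I0


def dual_route_drifts(utilities, params: DualRouteParams):
    """Drifts of the vanilla-MI and the divisively normalised routes.

    Both routes use I_i = U_i - fMI * mean_i(U_i) (mean over *all*
    alternatives including i), the DN route on U/sum(U); mu = k*I + I0.
    """
    u = np.asarray(utilities, dtype=float)
    if u.shape[-1] < 2:
        raise ValueError("need at least two alternatives")
    u_dn = divisive_normalize(u)

    def mu(uu):
        inhib = params.fMI * uu.mean(axis=-1, keepdims=True)
        return params.k * (uu - inhib) + params.I0

    return mu(u), mu(u_dn)


# -- inverse-Gaussian first-passage time -----------------------------------

def fpt_density(t, mu, theta):
    """First-passage density of a unit-variance diffusion from 0 to bound theta.

    p(t) = theta / sqrt(2 pi t^3) * exp(-(theta - mu t)^2 / (2 t)); 0 for t <= 0.
    """
    t = np.asarray(t, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = theta / np.sqrt(2.0 * np.pi * t**3) * np.exp(-((theta - mu * t) ** 2) / (2.0 * t))
    dens = np.where(t > 0, dens, 0.0)
    return dens if dens.ndim else float(dens)


def fpt_cdf(T, mu, theta):
    """P(first passage <= T): Phi((mu T - theta)/sqrt(T)) + e^{2 theta mu} Phi(-(mu T + theta)/sqrt(T)).

    The second term is evaluated in log space (scaled complementary error
    function) so that large theta*mu cannot overflow.
    """
    T = np.asarray(T, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrt_t = np.sqrt(T)
        a = ndtr(np.where(T > 0, (mu * T - theta) / sqrt_t, -np.inf))
        logb = np.where(
            T > 0, 2.0 * theta * mu + log_ndtr(-(mu * T + theta) / np.where(T > 0, sqrt_t, 1.0)), -np.inf
        )
    cdf = a + np.exp(logb)
    cdf = np.clip(np.where(T > 0, cdf, 0.0), 0.0, 1.0)
    return cdf if cdf.ndim else float(cdf)


def fpt_survival(T, mu, theta):
    """P(first passage > T) = 1 - fpt_cdf, clipped to [0, 1]."""
    s = 1.0 - fpt_cdf(T, mu, theta)
    s = np.clip(s, 0.0, 1.0)
    return s if np.ndim(s) else float(s)


# -- trialwise likelihoods -------------------------------------------------

def ffi_likelihood_terms(T, mu, chosen, theta) -> np.ndarray:
    """Vectorised L(i, T) for the FFI race.

    T: (n,) decision times (RT - tnd; non-positive values yield 0);
    mu: (n, n_acc) drifts; chosen: (n,) accumulator indices.
    """
    T = np.asarray(T, dtype=float)
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    chosen = np.asarray(chosen, dtype=int)
    n = len(T)
    idx = np.arange(n)
    g = fpt_density(T, mu[idx, chosen], theta)
    G = fpt_survival(T[:, None], mu, theta)
    G = np.array(G, dtype=float)
    G[idx, chosen] = 1.0
    return g * G.prod(axis=1)


def choice_rt_likelihood(i: int, rt: float, utilities, params: FFIParams) -> float:
    """Density of choosing accumulator ``i`` at observed ``rt`` (seconds).

    Composition of the chosen accumulator's first-passage density at
    T = rt - tnd with all competitors' survival; 0 (with a warning) when
    rt <= tnd, which downstream log-likelihoods floor at LIKELIHOOD_FLOOR.
    """
    T = rt - params.tnd
    if T <= 0:
        warnings.warn(f"rt={rt} <= tnd={params.tnd}: zero likelihood (floored downstream)")
        return 0.0
    mu = drift_rates(utilities, params)
    return float(ffi_likelihood_terms(np.array([T]), mu[None, :], np.array([i]), params.theta)[0])


def dual_likelihood_terms(T, utilities, chosen, params: DualRouteParams) -> np.ndarray:
    """Vectorised dual-route L(i, T) = L_DN(i, T) + L_MI(i, T).

    Each route term is the route accumulator's density times the survival of
    every other accumulator in *both* routes (a 2*n_alt-way race).
    """
    T = np.asarray(T, dtype=float)
    u = np.atleast_2d(np.asarray(utilities, dtype=float))
    chosen = np.asarray(chosen, dtype=int)
    mu_v, mu_dn = dual_route_drifts(u, params)
    idx = np.arange(len(T))
    th = params.theta
    G_v = np.array(fpt_survival(T[:, None], mu_v, th), dtype=float)
    G_dn = np.array(fpt_survival(T[:, None], mu_dn, th), dtype=float)
    g_v = fpt_density(T, mu_v[idx, chosen], th)
    g_dn = fpt_density(T, mu_dn[idx, chosen], th)
    # DN route absorbs first: exclude the chosen DN accumulator's survival
    Gd = G_dn.copy()
    Gd[idx, chosen] = 1.0
    l_dn = g_dn * Gd.prod(axis=1) * G_v.prod(axis=1)
    Gv = G_v.copy()
    Gv[idx, chosen] = 1.0
    l_v = g_v * Gv.prod(axis=1) * G_dn.prod(axis=1)
    return l_dn + l_v


def dual_route_likelihood(i: int, rt: float, utilities, params: DualRouteParams) -> float:
    """Dual-route density of choice ``i`` at observed ``rt`` (seconds)."""
    T = rt - params.tnd
    if T <= 0:
        warnings.warn(f"rt={rt} <= tnd={params.tnd}: zero likelihood (floored downstream)")
        return 0.0
    u = np.asarray(utilities, dtype=float)
    return float(dual_likelihood_terms(np.array([T]), u[None, :], np.array([i]), params)[0])


# -- predicted choice probabilities and RTs --------------------------------

def _likelihood_on_grid(utilities, params, settings: SimSettings):
    """Return (t grid, L(i, t) columns per alternative)."""
    t = np.arange(settings.dt, settings.tmax + settings.dt / 2, settings.dt)
    u = np.asarray(utilities, dtype=float)
    n_alt = u.shape[-1]
    cols = np.empty((len(t), n_alt))
    if isinstance(params, DualRouteParams):
        for i in range(n_alt):
            cols[:, i] = dual_likelihood_terms(t, np.tile(u, (len(t), 1)), np.full(len(t), i), params)
    else:
        mu = drift_rates(u, params)
        th = params.theta
        G = np.array(fpt_survival(t[:, None], mu[None, :], th), dtype=float)
        g = fpt_density(t[:, None], mu[None, :], th)
        for i in range(n_alt):
            Gi = G.copy()
            Gi[:, i] = 1.0
            cols[:, i] = g[:, i] * Gi.prod(axis=1)
    return t, cols


def choice_probability(
    utilities, params, settings: SimSettings | None = None, mass_tol: float = 1e-4
) -> np.ndarray:
    """p(choice = i) = integral of L(i, t) dt (trapezoid rule).

    Warns if the probability mass not absorbed by ``tmax`` exceeds
    ``mass_tol``.  Works for FFI and dual-route parameter sets.
    """
    settings = settings or DEFAULT_GRID
    t, cols = _likelihood_on_grid(utilities, params, settings)
    p = np.trapezoid(cols, t, axis=0)
    residual = 1.0 - p.sum()
    if residual > mass_tol:
        warnings.warn(
            f"probability mass {residual:.2e} beyond tmax={settings.tmax}; extend the horizon"
        )
    return p


def mean_rt(utilities, params, i: int, settings: SimSettings | None = None) -> float:
    """Conditional mean RT for choice ``i``: E[t | i] + tnd."""
    settings = settings or DEFAULT_GRID
    t, cols = _likelihood_on_grid(utilities, params, settings)
    li = cols[:, i]
    mass = np.trapezoid(li, t)
    if mass <= 0:
        raise ValueError(f"choice {i} has no probability mass on the grid")
    return float(np.trapezoid(t * li, t) / mass + params.tnd)


# -- stochastic simulation oracle ------------------------------------------

def simulate_paths(
    mu: np.ndarray,
    theta: float,
    dt: float,
    tmax: float,
    rng: np.random.Generator,
    bridge: bool = True,
):
    """Euler--Maruyama first-passage simulation of independent accumulators.

    ``mu`` has shape (n_paths, n_acc); each row is one race.  Returns
    (winner, t_dec): winner = accumulator index, -1 if censored at tmax;
    t_dec = decision time (NaN if censored), recorded at the midpoint of the
    absorbing step (the crossing occurred somewhere inside it).  With
    ``bridge`` the crossing probability between successive steps,
    exp(-2 (theta-x)(theta-x')/dt), is sampled so crossings inside a step
    are not missed.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    n, n_acc = mu.shape
    winner = np.full(n, -1, dtype=int)
    t_dec = np.full(n, np.nan)
    alive = np.arange(n)
    x = np.zeros((n, n_acc))
    sqdt = np.sqrt(dt)
    nsteps = int(np.ceil(tmax / dt))
    for step in range(1, nsteps + 1):
        na = len(alive)
        if na == 0:
            break
        xa = x[alive]
        x_new = xa + mu[alive] * dt + sqdt * rng.standard_normal((na, n_acc))
        crossed = x_new >= theta
        if bridge:
            below = ~crossed
            with np.errstate(over="ignore"):
                p_cross = np.exp(-2.0 * (theta - xa) * (theta - x_new) / dt)
            hit = below & (rng.random((na, n_acc)) < p_cross) & (xa < theta)
            crossed |= hit
        any_cross = crossed.any(axis=1)
        if any_cross.any():
            rows = alive[any_cross]
            sub = crossed[any_cross]
            # break simultaneous crossings uniformly at random
            keys = np.where(sub, 1.0 + rng.random(sub.shape), 0.0)
            winner[rows] = np.argmax(keys, axis=1)
            t_dec[rows] = (step - 0.5) * dt
        x[alive] = x_new
        alive = alive[~any_cross]
    return winner, t_dec


def simulate_race(utilities, params, settings: SimSettings):
    """Simulate the race for one utility vector; reproducible under the seed.

    Returns (choices, rts): choices are alternative indices (-1 when a path
    is not absorbed by tmax, reported separately as censored), rts include
    the non-decision time (NaN for censored paths).
    """
    rng = np.random.default_rng(settings.seed)
    u = np.asarray(utilities, dtype=float)
    if isinstance(params, DualRouteParams):
        mu_v, mu_dn = dual_route_drifts(u, params)
        mu_all = np.concatenate([mu_dn, mu_v])
        groups = np.concatenate([np.arange(len(u)), np.arange(len(u))])
    else:
        mu_all = drift_rates(u, params)
        groups = np.arange(len(u))
    mu_tiled = np.tile(mu_all, (settings.npaths, 1))
    winner, t_dec = simulate_paths(
        mu_tiled, params.theta, settings.dt, settings.tmax, rng, bridge=settings.bridge
    )
    choices = np.where(winner >= 0, groups[np.clip(winner, 0, None)], -1)
    rts = t_dec + params.tnd
    return choices, rts
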