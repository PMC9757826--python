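"""Static utility functions for two-attribute risky prospects.

Covers context-independent valuation (expected value, additive utility,
expected utility and prospect-theory style non-linear attribute distortions)
and context-dependent transforms (selective integration, adaptive gain,
divisive normalisation).  All functions accept scalars or arrays; the
context transforms operate on per-trial matrices of shape (n_trials,
n_alternatives) with alternatives compared within each attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistortionParams",
    "SIParams",
    "AdaptiveGainParams",
    "expected_value",
    "additive_utility",
    "distort_probability",
    "distort_magnitude",
    "selective_integration_gate",
    "si_gate_attribute",
    "adaptive_gain_transform",
    "adaptive_gain_attribute",
    "divisive_normalize",
    "UTILITY_FAMILIES",
]


@dataclass(frozen=True)
class DistortionParams:
    """Non-linear attribute distortions.

    eta: log-odds slope (>0); p0: log-odds fixed point (0<p0<1);
    gamma: magnitude power (>0); tau: probability-weighting curvature (>0).
    """

    eta: float = 1.0
    p0: float = 0.5
    gamma: float = 1.0
    tau: float = 1.0

    def __post_init__(self):
        if self.eta <= 0 or self.gamma <= 0 or self.tau <= 0:
            raise ValueError("distortion parameters eta, gamma, tau must be > 0")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be strictly inside (0, 1)")


@dataclass(frozen=True)
class SIParams:
    """Selective-integration gating weights, 0 <= w2 <= w3 <= 1 (w1 = 0)."""

    w2: float
    w3: float

    def __post_init__(self):
        if not (0.0 <= self.w2 <= self.w3 <= 1.0):
            raise ValueError(f"require 0 <= w2 <= w3 <= 1, got ({self.w2}, {self.w3})")


@dataclass(frozen=True)
class AdaptiveGainParams:
    """Sigmoidal transduction parameters per attribute (slope s > 0, bias b)."""

    s_x: float
    b_x: float
    s_p: float
    b_p: float

    def __post_init__(self):
        if self.s_x <= 0 or self.s_p <= 0:
            raise ValueError("adaptive-gain slopes must be strictly positive")

    @classmethod
    def tied(cls, s: float, b: float) -> "AdaptiveGainParams":
        """Single (s, b) shared between magnitude and probability."""
        return cls(s, b, s, b)


def expected_value(x, p):
    """EV = X * P."""
    return np.asarray(x, dtype=float) * np.asarray(p, dtype=float)


def additive_utility(x, p, lam: float, convention: str = "weighted-mean"):
    """Additive utility of a prospect.

    'weighted-mean' returns lam*X + (1-lam)*P (the modelling convention);
    'attribute-sum' returns X + P, a rank-equivalent form that differs by a
    factor of 2 at lam = 0.5 and is kept for worked unweighted examples.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if convention == "weighted-mean":
        return lam * x + (1.0 - lam) * p
    if convention == "attribute-sum":
        return x + p
    raise ValueError(f"unknown convention {convention!r}")


def _logit(p):
    return np.log(p) - np.log1p(-p)


def distort_probability(p, mode: str = "log-odds", params: DistortionParams | None = None):
    """Subjective probability distortion.

    'log-odds' solves logit(Pd) = eta*logit(P) + (1-eta)*logit(P0); the
    endpoints P in {0, 1} are mapped to themselves (limit behaviour) with a
    warning.  'kt' is the one-parameter inverse-S weighting
    Pd = P^tau / (P^tau + (1-P)^tau)^(1/tau).
    """
    params = params or DistortionParams()
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if mode == "log-odds":
        interior = (p > 0) & (p < 1)
        if not np.all(interior):
            warnings.warn("log-odds distortion at P in {0,1}: mapped to themselves")
        out = np.array(p, dtype=float, copy=True)
        pi = p[interior]
        lo = params.eta * _logit(pi) + (1.0 - params.eta) * _logit(params.p0)
        out[interior] = 1.0 / (1.0 + np.exp(-lo))
        return out if out.ndim else float(out)
    if mode == "kt":
        t = params.tau
        num = p**t
        den = (p**t + (1.0 - p) ** t) ** (1.0 / t)
        out = num / den
        return out if np.ndim(out) else float(out)
    raise ValueError(f"unknown distortion mode {mode!r}")


def distort_magnitude(x, gamma: float):
    """Power-law magnitude distortion Xd = X**gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("magnitudes must be non-negative")
    out = x**gamma
    return out if out.ndim else float(out)


def si_gate_attribute(values: np.ndarray, w2: float, w3: float) -> np.ndarray:
    """Rank-dependent gating of one attribute across alternatives.

    ``values`` has shape (n_trials, n_alternatives).  Within each row the
    highest value is unchanged, the intermediate is multiplied by (1 - w2)
    and the lowest by (1 - w3).  Ties: values sharing the row maximum stay
    unchanged; values sharing the row minimum (without being maximal) are
    suppressed by w3; a full tie leaves the row unchanged.  With two
    alternatives the single losing value is suppressed by w2 (only one
    losing rank exists).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n_alt = v.shape[1]
    mx = v.max(axis=1, keepdims=True)
    mn = v.min(axis=1, keepdims=True)
    is_max = v == mx
    if n_alt == 2:
        factor = np.where(is_max, 1.0, 1.0 - w2)
    else:
        is_min = (v == mn) & ~is_max
        is_mid = ~is_max & ~is_min
        factor = 1.0 * is_max + (1.0 - w3) * is_min + (1.0 - w2) * is_mid
    out = v * factor
    return out if np.asarray(values).ndim == 2 else out[0]


def selective_integration_gate(x, p, params: SIParams, lam: float) -> np.ndarray:
    """Selective integration: gate each attribute by rank, then form AU.

    ``x`` and ``p`` are (n_trials, n_alternatives) attribute matrices (or 1-D
    vectors over alternatives).  Returns per-alternative utilities
    AU = lam*X' + (1-lam)*P' after within-attribute rank gating.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    xg = si_gate_attribute(x, params.w2, params.w3)
    pg = si_gate_attribute(p, params.w2, params.w3)
    return lam * xg + (1.0 - lam) * pg


def adaptive_gain_attribute(values: np.ndarray, s: float, b: float) -> np.ndarray:
    """Centre one attribute by its context mean, then sigmoidally transduce.

    v_bar = v - mean(context); out = 1 / (1 + exp((b - v_bar) / s)).
    """
    if s <= 0:
        raise ValueError("slope s must be > 0")
    v = np.atleast_2d(np.asarray(values, dtype=float))
    centred = v - v.mean(axis=1, keepdims=True)
    out = 1.0 / (1.0 + np.exp((b - centred) / s))
    return out if np.asarray(values).ndim == 2 else out[0]


def adaptive_gain_transform(x, p, params: AdaptiveGainParams, lam: float) -> np.ndarray:
    """Adaptive-gain utilities: per-attribute context centring + sigmoid, then AU."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    xg = adaptive_gain_attribute(x, params.s_x, params.b_x)
    pg = adaptive_gain_attribute(p, params.s_p, params.b_p)
    return lam * xg + (1.0 - lam) * pg


def divisive_normalize(utilities) -> np.ndarray:
    """Divide each utility by the sum across the alternatives present.

    Accepts a 1-D vector over alternatives or an (n_trials, n_alternatives)
    matrix (normalised row-wise).  All inputs must be >= 0 with positive sum.
    """
    u = np.asarray(utilities, dtype=float)
    if np.any(u < 0):
        raise ValueError("utilities must be non-negative for divisive normalisation")
    if u.ndim == 1:
        s = u.sum()
        if s <= 0:
            raise ValueError("zero utility sum")
        return u / s
    s = u.sum(axis=1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("zero utility sum in at least one row")
    return u / s


#: registry of utility model family names usable from configs and the CLI
UTILITY_FAMILIES = ("ev", "au", "eu", "pt", "si", "adaptive_gain", "dn")
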