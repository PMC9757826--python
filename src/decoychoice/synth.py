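"""Design-faithful synthetic choice sets and simulated agents.

The generator emulates the structure of the task's trial design: 150
ternary and 150 binary trials per subject, H/L labels ordered by expected
value, a many-to-one ternary->binary matching (the same (H, L) pair recurs
across ternary conditions that differ only in the distractor, and binary
trials repeat some pairs), and a pseudo-random distractor assignment that
resamples until DV - HV is decorrelated from the difficulty index HV - LV.
A configurable variant instead *induces* a covariation between DV - HV and
the additive-utility difference, reproducing the confound diagnosed by the
notional-distractor analyses; another removes it from both quantities.

Agents simulate behaviour from any registered model: static agents draw
softmax choices (no RT), dynamic agents draw (choice, RT) from the race
simulator with deadline censoring recorded as non-responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import race as _race
from .fitting import ModelSpec, compute_utilities, softmax_choice_prob
from .race import DualRouteParams, FFIParams
from .trials import DEFAULT_DEADLINE, TrialTable

__all__ = [
    "GeneratorConfig",
    "AgentSpec",
    "generate_choice_sets",
    "simulate_agent",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Trial-design generator settings.

    The defaults reproduce the deposited design's structural facts: 150
    ternary trials over 149 unique (H, L, D) conditions built on 95 unique
    (H, L) pairs, and 150 binary trials covering every pair at least once.
    ``decorrelation_threshold`` caps |Pearson r| between DV - HV and
    HV - LV across unique ternary conditions (the published threshold is
    unstated; 0.1 is this package's default).  ``au_covariation`` switches
    the generator into the confounded regime: DV - HV is driven toward a
    positive correlation (at least that value) with the component of the
    additive-utility difference (weight ``lam``) orthogonal to HV - LV —
    the component that surfaces as a notional distractor slope in the
    binary GLM; ``decorrelate_au`` instead also caps its magnitude.
    """

    n_ternary: int = 150
    n_binary: int = 150
    n_hl_pairs: int = 95
    n_unique_ternary: int = 149
    x_range: tuple = (0.1, 0.9)
    p_range: tuple = (0.1, 0.9)
    decorrelation_threshold: float = 0.1
    au_covariation: float | None = None
    decorrelate_au: bool = False
    lam: float = 0.5
    max_iter: int = 5000
    seed: int = 0
    subject: str = "s1"

    def __post_init__(self):
        if not 0.0 < self.decorrelation_threshold <= 1.0:
            raise ValueError("decorrelation threshold must lie in (0, 1]")
        if self.n_unique_ternary < self.n_hl_pairs:
            raise ValueError("need at least as many ternary conditions as (H, L) pairs")
        if self.n_ternary < self.n_unique_ternary or self.n_binary < self.n_hl_pairs:
            raise ValueError("trial counts cannot be below the unique-condition counts")


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _sample_pairs(cfg: GeneratorConfig, rng: np.random.Generator):
    xs = rng.uniform(*cfg.x_range, size=(cfg.n_hl_pairs, 2))
    ps = rng.uniform(*cfg.p_range, size=(cfg.n_hl_pairs, 2))
    ev = xs * ps
    swap = ev[:, 0] < ev[:, 1]
    xs[swap] = xs[swap][:, ::-1]
    ps[swap] = ps[swap][:, ::-1]
    return xs, ps  # column 0 = H, column 1 = L


def _assign_distractors(cfg: GeneratorConfig, rng, hv_lv, dau, hv):
    """Sample per-condition D attributes satisfying the configured covariation
    constraints; returns (dx, dp) arrays over unique ternary conditions."""
    thr = cfg.decorrelation_threshold
    n = len(hv_lv)
    best_r = np.inf
    for _ in range(cfg.max_iter):
        dx = rng.uniform(*cfg.x_range, size=n)
        dp = rng.uniform(*cfg.p_range, size=n)
        dx, dp = _optimise_assignment(cfg, rng, dx, dp, hv_lv, dau, hv)
        dvhv = dx * dp - hv
        r1 = _corr(dvhv, hv_lv)
        r2 = _corr(dvhv, dau)
        ok = abs(r1) <= thr
        if cfg.decorrelate_au:
            ok &= abs(r2) <= thr
        if cfg.au_covariation is not None:
            ok &= r2 >= cfg.au_covariation
        if ok:
            return dx, dp
        best_r = min(best_r, abs(r1))
    raise RuntimeError(
        f"decorrelation threshold {thr} unattainable within {cfg.max_iter} "
        f"iterations (best |r| = {best_r:.3f})"
    )


def _optimise_assignment(cfg, rng, dx, dp, hv_lv, dau, hv, n_swaps: int = 4000):
    """Greedy pairwise swaps of D assignments toward the covariation target.

    Swapping which condition receives which D preserves the sampled D
    marginal while steering corr(DV - HV, dAU) and corr(DV - HV, HV - LV).
    """
    thr = cfg.decorrelation_threshold
    target = cfg.au_covariation

    def penalty(dx_, dp_):
        dvhv = dx_ * dp_ - hv
        r1, r2 = _corr(dvhv, hv_lv), _corr(dvhv, dau)
        pen = max(0.0, abs(r1) - thr)
        if cfg.decorrelate_au:
            pen += max(0.0, abs(r2) - thr)
        if target is not None:
            pen += max(0.0, target - r2)
        return pen

    cur = penalty(dx, dp)
    n = len(dx)
    for _ in range(n_swaps):
        if cur == 0.0:
            break
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        dx[[i, j]] = dx[[j, i]]
        dp[[i, j]] = dp[[j, i]]
        new = penalty(dx, dp)
        if new <= cur:
            cur = new
        else:
            dx[[i, j]] = dx[[j, i]]
            dp[[i, j]] = dp[[j, i]]
    return dx, dp


def generate_choice_sets(config: GeneratorConfig | None = None) -> TrialTable:
    """Generate one subject's trial design; deterministic under the seed.

    Ternary conditions reuse (H, L) pairs with different distractors; binary
    trials cover every pair at least once with a many-to-one multiplicity
    pattern, so the baseline map has weights > 1 for some conditions.
    Choices are 'none' (the design carries no behaviour until an agent is
    simulated on it).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    xs, ps = _sample_pairs(cfg, rng)

    # unique ternary conditions: every pair once, extras drawn at random
    extra = rng.integers(0, cfg.n_hl_pairs, size=cfg.n_unique_ternary - cfg.n_hl_pairs)
    cond_pair = np.concatenate([np.arange(cfg.n_hl_pairs), extra])
    hx, hp = xs[cond_pair, 0], ps[cond_pair, 0]
    lx, lp = xs[cond_pair, 1], ps[cond_pair, 1]
    hv, lv = hx * hp, lx * lp
    dau = cfg.lam * (hx - lx) + (1 - cfg.lam) * (hp - lp)
    # the AU component orthogonal to the difficulty index is what shows up
    # as a notional distractor slope once HV - LV is a regressor
    hv_lv = hv - lv
    slope = np.dot(dau - dau.mean(), hv_lv - hv_lv.mean()) / np.var(hv_lv) / len(hv_lv)
    dau_res = dau - slope * hv_lv
    dx, dp = _assign_distractors(cfg, rng, hv_lv, dau_res, hv)

    # ternary trials: every unique condition once, extras duplicated
    dup = rng.integers(0, cfg.n_unique_ternary, size=cfg.n_ternary - cfg.n_unique_ternary)
    tern_cond = np.concatenate([np.arange(cfg.n_unique_ternary), dup])
    # binary trials: every pair once, extras at random (multi-matched baselines)
    extra_b = rng.integers(0, cfg.n_hl_pairs, size=cfg.n_binary - cfg.n_hl_pairs)
    bin_pair = np.concatenate([np.arange(cfg.n_hl_pairs), extra_b])

    rows = []
    for c in tern_cond:
        rows.append(("ternary", hx[c], hp[c], lx[c], lp[c], dx[c], dp[c]))
    for pi in bin_pair:
        rows.append(("binary", xs[pi, 0], ps[pi, 0], xs[pi, 1], ps[pi, 1], np.nan, np.nan))
    order = rng.permutation(len(rows))
    df = pd.DataFrame(
        [rows[i] for i in order],
        columns=["condition", "hx", "hp", "lx", "lp", "dx", "dp"],
    )
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(0, "subject", cfg.subject)
    df["choice"] = "none"
    df["rt"] = np.nan
    return TrialTable(df)


# -- simulated agents -------------------------------------------------------

@dataclass
class AgentSpec:
    """A generative agent: a model spec with true parameters.

    ``deadline`` censors slow dynamic responses (recorded as non-responses);
    None uses the trial table's deadline.  ``dt``/``bridge`` control the
    race simulator's step and crossing correction.
    """

    spec: ModelSpec
    params: dict = field(default_factory=dict)
    deadline: float | None = None
    dt: float = 0.001
    bridge: bool = True


def simulate_agent(trials, agent: AgentSpec, seed: int = 0) -> TrialTable:
    """Simulate one agent on a trial design; reproducible under the seed.

    Static agents draw choices from softmax probabilities over the two
    targets (context transforms still see the distractor on ternary rows);
    no RT is produced.  Dynamic agents draw (choice, RT) from the race
    simulator; the unavailable D can only be 'chosen' by dual-route agents,
    which race all modelled accumulators.
    """
    table = trials if isinstance(trials, TrialTable) else TrialTable(trials)
    df = table.df.copy()
    deadline = agent.deadline if agent.deadline is not None else table.deadline
    spec, params = agent.spec, agent.params
    rng = np.random.default_rng(seed)

    if spec.dynamics == "static":
        u = compute_utilities(df, spec.family, params, spec.options)
        p_h = softmax_choice_prob(u, params["beta"])[:, 0]
        draw = rng.random(len(df))
        df["choice"] = np.where(draw < p_h, "H", "L")
        df["rt"] = np.nan
        return TrialTable(df, deadline=table.deadline, validate=False)

    tnd = params.get("tnd", 0.0)
    tmax = max(deadline - tnd, 2.0 * agent.dt)
    choices = np.full(len(df), "none", dtype=object)
    rts = np.full(len(df), np.nan)
    tern = (df["condition"] == "ternary").to_numpy()
    if spec.dynamics == "ffi":
        p = FFIParams(k=params["k"], theta=params["theta"], c=params.get("c", 1.0),
                      I0=params.get("I0", 0.0), tnd=tnd)
        u = compute_utilities(df, spec.family, params, spec.options)
        mu = _race.drift_rates(u, p)
        winner, t_dec = _race.simulate_paths(mu, p.theta, agent.dt, tmax, rng,
                                             bridge=agent.bridge)
        labels = np.array(["H", "L"])
        ok = winner >= 0
        choices[ok] = labels[winner[ok]]
        rts[ok] = t_dec[ok] + tnd
    elif spec.dynamics == "dual":
        p = DualRouteParams(k=params["k"], theta=params["theta"], fMI=params.get("fMI", 0.0),
                            I0=params.get("I0", 0.0), tnd=tnd)
        for mask, with_d in ((~tern, False), (tern, True)):
            if not mask.any():
                continue
            u = compute_utilities(df.loc[mask], "ev", params, include_d=with_d)
            mu_v, mu_dn = _race.dual_route_drifts(u, p)
            mu_all = np.concatenate([mu_dn, mu_v], axis=1)
            winner, t_dec = _race.simulate_paths(mu_all, p.theta, agent.dt, tmax, rng,
                                                 bridge=agent.bridge)
            n_alt = u.shape[1]
            labels = np.array(["H", "L", "D"][:n_alt] * 2)
            ok = winner >= 0
            idx = np.flatnonzero(mask)
            choices[idx[ok]] = labels[winner[ok]]
            rts[idx[ok]] = t_dec[ok] + tnd
    else:
        raise ValueError(f"agent dynamics {spec.dynamics!r} not simulatable")
    over = np.isfinite(rts) & (rts > deadline)
    choices[over] = "none"
    rts[over] = np.nan
    df["choice"] = choices
    df["rt"] = rts
    return TrialTable(df, deadline=deadline, validate=False)


# -- fixtures ---------------------------------------------------------------

FIXTURE_NAMES = ("intro_pairs", "decoy_geometry", "recovery")
_RECOVERY_SEED = 314159  # recorded seed: fixture regenerates bit-identically


def _read_fixture_csv(name: str) -> pd.DataFrame:
    with resources.files("decoychoice.fixtures").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def make_fixture(name: str):
    """Return (TrialTable, annotations) for a registered test scenario.

    'intro_pairs': the two worked binary prospect pairs, (1, 0.9) vs
    (1, 0.8) and (0.5, 0.5) vs (0.5, 0.3), whose EV differences are both
    0.1 while their attribute-sum AU differences are 0.1 and 0.2.
    'decoy_geometry': 12 ternary conditions (plus matched binary rows)
    covering all four proximity x dominance decoy cells, annotated with
    their ground-truth categories.  'recovery': a 300-trial generated
    design under a recorded seed.
    """
    if name == "intro_pairs":
        df = _read_fixture_csv("intro_pairs")
        ann = {
            "ev_diff": [0.1, 0.1],
            "au_sum_diff": [0.1, 0.2],
        }
        return TrialTable(df), ann
    if name == "decoy_geometry":
        raw = _read_fixture_csv("decoy_geometry")
        ann = raw[raw["condition"] == "ternary"][["proximity", "dominance"]].reset_index(drop=True)
        df = raw.drop(columns=["proximity", "dominance"])
        return TrialTable(df), {"categories": ann, "lam": 0.5}
    if name == "recovery":
        cfg = GeneratorConfig(seed=_RECOVERY_SEED)
        return generate_choice_sets(cfg), {"seed": _RECOVERY_SEED, "config": cfg}
    raise KeyError(f"unknown fixture scenario {name!r}; known: {FIXTURE_NAMES}")
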