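"""Statistical analyses of relative choice accuracy and decoy effects.

Implements the study-style analysis chain: weighted logistic GLMs of
relative accuracy with z-scored regressors (ternary trials, matched binary
baselines with *notional* distractor values, or both combined with a
condition dummy), group-level one-sample t-tests with Holm correction,
permutation-based correction of the condition-unspecific ternary-vs-binary
bias, sliding quantile-window binned accuracy maps, and the 2x2
(proximity x dominance) repeated-measures decoy-effect analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .trials import (
    ChoiceSet,
    Prospect,
    TrialTable,
    classify_decoy,
    match_binary_baselines,
)

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "BinnedMap",
    "DecoyTable",
    "build_design_matrix",
    "fit_weighted_logit",
    "group_level_tests",
    "across_subject_correlation",
    "permutation_bias_correction",
    "binned_map",
    "decoy_effect_table",
    "bias_corrected_contrasts",
    "condition_accuracy_table",
]


# -- design matrices and weighted logistic GLM ------------------------------

@dataclass
class DesignMatrix:
    """Named regressors, response proportions, and observation weights."""

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    n_dropped_conditions: int = 0


@dataclass
class GLMResult:
    """Per-subject weighted logistic fit."""

    params: pd.Series
    bse: pd.Series
    converged: bool
    dropped: list = field(default_factory=list)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        return v - np.mean(v)
    return (v - np.mean(v)) / sd


def condition_accuracy_table(trials, tol: float = 1e-9) -> pd.DataFrame:
    """Per unique ternary condition: ternary accuracy, matched-binary baseline.

    Columns: the condition's attributes, ternary p(H over L) with its H/L
    trial count, baseline p(H over L) across matched binary trials with the
    matched-trial observation weight, and a matched flag.
    """
    table = trials if isinstance(trials, TrialTable) else TrialTable(trials, validate=False)
    bm = match_binary_baselines(table, tol=tol)
    df = table.df
    rows = []
    for key, entry in bm.entries.items():
        hx, hp, lx, lp, dx, dp = key
        tern = df[
            (df["condition"] == "ternary")
            & np.isclose(df["hx"], hx) & np.isclose(df["hp"], hp)
            & np.isclose(df["lx"], lx) & np.isclose(df["lp"], lp)
            & np.isclose(df["dx"], dx) & np.isclose(df["dp"], dp)
        ]
        t_hl = tern[tern["choice"].isin(["H", "L"])]
        b_rows = df.loc[entry.binary_rows]
        b_hl = b_rows[b_rows["choice"].isin(["H", "L"])]
        rows.append(
            {
                "hx": hx, "hp": hp, "lx": lx, "lp": lp, "dx": dx, "dp": dp,
                "t_acc": (t_hl["choice"] == "H").mean() if len(t_hl) else np.nan,
                "t_n": len(t_hl),
                "b_acc": (b_hl["choice"] == "H").mean() if len(b_hl) else np.nan,
                "b_n": len(b_hl),
                "weight": entry.weight,
                "matched": entry.matched,
            }
        )
    return pd.DataFrame(rows)


def build_design_matrix(
    trials,
    basis: str = "ev",
    lam: float | None = None,
    distractor_variable: str = "relative",
    include_sum: bool = False,
    rows: str = "both",
    tol: float = 1e-9,
) -> DesignMatrix:
    """Design matrix for the relative-accuracy GLM of one subject.

    The response is p(H over L) per unique ternary condition — in ternary
    trials and/or in the matched binary baseline, where the distractor value
    is *notional* (inherited from the matched ternary condition).  ``basis``
    is 'ev' (value = X*P) or 'au' (weighted-mean additive utility; requires
    ``lam``).  ``distractor_variable`` is 'relative' (D - H) or 'absolute'
    (D).  ``rows``: 'ternary', 'binary', or 'both' (adds the condition dummy
    C and each effect x C).  Every component regressor is z-scored before
    interactions are formed (interaction = product of z-scored columns).
    """
    acc = condition_accuracy_table(trials, tol=tol)
    matched = acc[acc["matched"] & acc["t_n"].gt(0) & np.isfinite(acc["t_acc"])]
    n_dropped = len(acc) - len(matched)
    if n_dropped:
        warnings.warn(f"{n_dropped} ternary conditions without usable match excluded")
    if basis == "ev":
        vh = matched["hx"] * matched["hp"]
        vl = matched["lx"] * matched["lp"]
        vd = matched["dx"] * matched["dp"]
    elif basis == "au":
        if lam is None:
            raise ValueError("AU basis requires lam (from a prior utility fit)")
        vh = lam * matched["hx"] + (1 - lam) * matched["hp"]
        vl = lam * matched["lx"] + (1 - lam) * matched["lp"]
        vd = lam * matched["dx"] + (1 - lam) * matched["dp"]
    else:
        raise ValueError(f"unknown basis {basis!r}")
    vdiff = (vh - vl).to_numpy(float)
    dvar = (vd - vh).to_numpy(float) if distractor_variable == "relative" else vd.to_numpy(float)
    vsum = (vh + vl).to_numpy(float)

    blocks = []
    if rows in ("ternary", "both"):
        blocks.append(("T", matched["t_acc"].to_numpy(float), matched["t_n"].to_numpy(float)))
    if rows in ("binary", "both"):
        blocks.append(("B", matched["b_acc"].to_numpy(float), matched["b_n"].to_numpy(float)))
    if not blocks:
        raise ValueError(f"unknown rows selection {rows!r}")

    reps = len(blocks)
    zdiff = _zscore(np.tile(vdiff, reps))
    zdvar = _zscore(np.tile(dvar, reps))
    cols = {"vdiff": zdiff, "dvar": zdvar, "vdiff_x_dvar": zdiff * zdvar}
    if include_sum:
        cols["vsum"] = _zscore(np.tile(vsum, reps))
    y = np.concatenate([b[1] for b in blocks])
    w = np.concatenate([b[2] for b in blocks])
    if rows == "both":
        c = np.concatenate([np.ones(len(matched)) if b[0] == "T" else np.zeros(len(matched))
                            for b in blocks])
        for name in list(cols):
            cols[f"{name}_x_C"] = cols[name] * c
        cols["C"] = c
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    ok = np.isfinite(y) & (w > 0)
    return DesignMatrix(X[ok].reset_index(drop=True), y[ok], w[ok], n_dropped)


def fit_weighted_logit(design: DesignMatrix) -> GLMResult:
    """Weighted binomial logit via IRLS (statsmodels GLM, var_weights).

    Proportions with integer weights are equivalent to expanded Bernoulli
    data.  Zero-variance (degenerate) columns are dropped with a warning;
    complete separation is flagged rather than raised.
    """
    X = design.X.copy()
    dropped = []
    for col in X.columns:
        if col != "const" and np.std(X[col].to_numpy()) < 1e-12:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropping rank-deficient columns: {dropped}")
        X = X.drop(columns=dropped)
    model = sm.GLM(design.y, X, family=sm.families.Binomial(), var_weights=design.weights)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        converged = bool(res.converged)
        params, bse = res.params, res.bse
    except PerfectSeparationError:
        warnings.warn("complete separation in weighted logit; coefficients unreliable")
        res = model.fit(maxiter=25, tol=1e-4)
        converged = False
        params, bse = res.params, res.bse
    return GLMResult(pd.Series(params, index=X.columns), pd.Series(bse, index=X.columns),
                     converged, dropped)


# -- group-level inference --------------------------------------------------

def group_level_tests(coefs: pd.DataFrame, correction: str = "holm") -> pd.DataFrame:
    """One-sample t-tests of per-subject coefficients against zero.

    ``coefs``: subjects x terms.  Returns per-term mean, t, df, raw p, and
    (optionally Holm-) adjusted p.  Zero across-subject variance yields an
    undefined (NaN) t reported as such.
    """
    if len(coefs) < 2:
        raise ValueError("need >= 2 subjects")
    rows = []
    for term in coefs.columns:
        v = coefs[term].to_numpy(float)
        v = v[np.isfinite(v)]
        n = len(v)
        sd = v.std(ddof=1)
        if sd == 0:
            t_val = 0.0 if v.mean() == 0 else np.nan
            p = 1.0 if v.mean() == 0 else np.nan
        else:
            t_val, p = stats.ttest_1samp(v, 0.0)
        rows.append({"term": term, "mean": v.mean(), "t": t_val, "df": n - 1, "p": p})
    out = pd.DataFrame(rows).set_index("term")
    if correction == "holm":
        finite = np.isfinite(out["p"].to_numpy())
        adj = np.full(len(out), np.nan)
        if finite.any():
            adj[finite] = multipletests(out["p"].to_numpy()[finite], method="holm")[1]
        out["p_holm"] = adj
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return out


def across_subject_correlation(x, y, method: str = "spearman"):
    """Across-subject correlation between two per-subject effect vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


# -- condition-unspecific bias ----------------------------------------------

def permutation_bias_correction(
    ternary_acc: pd.Series,
    binary_acc: pd.Series,
    nperm: int = 5000,
    seed: int = 0,
    weights: pd.Series | None = None,
):
    """Condition-unspecific ternary-vs-binary bias by permutation.

    Shuffles the mapping between ternary conditions and their matched binary
    baselines (uniformly, within subject); the bias is the mean permuted
    T - B contrast, and the corrected per-condition contrast is the true
    T - B minus that single subject-level constant.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    t = ternary_acc.to_numpy(float)
    b = binary_acc.reindex(ternary_acc.index).to_numpy(float)
    if len(t) < 2:
        raise ValueError("need >= 2 conditions to shuffle")
    w = np.ones(len(t)) if weights is None else weights.reindex(ternary_acc.index).to_numpy(float)
    rng = np.random.default_rng(seed)
    contrasts = np.empty(nperm)
    for i in range(nperm):
        perm = rng.permutation(len(b))
        contrasts[i] = np.average(t - b[perm], weights=w)
    bias = float(contrasts.mean())
    corrected = pd.Series(t - b - bias, index=ternary_acc.index)
    return bias, corrected


# -- binned maps -------------------------------------------------------------

@dataclass
class BinnedMap:
    """Sliding quantile-window average of an outcome over two coordinates."""

    values: np.ndarray      # (n, n); axis 0 indexes x1 windows, axis 1 x2
    x1_centers: np.ndarray  # coordinate value at each window's centre quantile
    x2_centers: np.ndarray
    window_quantile: float
    step_quantile: float


def binned_map(
    x1, x2, y, window_quantile: float = 0.30, step_quantile: float = 0.01
) -> BinnedMap:
    """Average ``y`` in a sliding square quantile window over (x1, x2).

    The window edge spans ``window_quantile`` of each coordinate's empirical
    distribution and slides in steps of ``step_quantile``; the defaults (30%
    window, 1% step) give floor((1 - 0.30)/0.01) + 1 = 71 positions per
    axis.  Quantiles use linear interpolation; empty cells are NaN.
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    y = np.asarray(y, float)
    for ax, v in (("x1", x1), ("x2", x2)):
        if len(np.unique(v)) < 2:
            raise ValueError(f"{ax} needs >= 2 distinct values")
    n = int(math.floor((1.0 - window_quantile) / step_quantile + 1e-9)) + 1
    starts = np.array([i * step_quantile for i in range(n)])

    def windows(v):
        lo = np.quantile(v, starts)
        hi = np.quantile(v, np.minimum(starts + window_quantile, 1.0))
        centers = np.quantile(v, np.minimum(starts + window_quantile / 2.0, 1.0))
        masks = [(v >= lo[i]) & (v <= hi[i]) for i in range(n)]
        return masks, centers

    m1, c1 = windows(x1)
    m2, c2 = windows(x2)
    grid = np.full((n, n), np.nan)
    finite = np.isfinite(y)
    for i in range(n):
        sel1 = m1[i] & finite
        for j in range(n):
            sel = sel1 & m2[j]
            if sel.any():
                grid[i, j] = y[sel].mean()
    return BinnedMap(grid, c1, c2, window_quantile, step_quantile)


# -- decoy-effect analysis ---------------------------------------------------

@dataclass
class DecoyTable:
    """2x2 decoy-effect summary: proximity (H/L) x dominance (inferior/superior)."""

    cells: pd.DataFrame       # subjects x 4 cell-mean columns
    anova: pd.DataFrame       # main effects and interaction (F, df, p, partial eta^2)
    cell_tests: pd.DataFrame  # cellwise one-sample t-tests, Holm-corrected
    n_excluded_subjects: int = 0


_CELLS = [("H", "inferior"), ("H", "superior"), ("L", "inferior"), ("L", "superior")]


def _rm_contrast(cells: pd.DataFrame, weights: dict) -> dict:
    scores = sum(w * cells[c] for c, w in weights.items())
    n = len(scores)
    mean = scores.mean()
    sd = scores.std(ddof=1)
    if sd == 0:
        t = 0.0 if mean == 0 else np.inf
    else:
        t = mean / (sd / math.sqrt(n))
    F = t * t
    df2 = n - 1
    p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
    eta = F / (F + df2) if np.isfinite(F) else 1.0
    return {"F": float(F), "df1": 1, "df2": df2, "p": p, "partial_eta_sq": float(eta)}


def decoy_effect_table(data: pd.DataFrame, correction: str = "holm") -> DecoyTable:
    """2x2 repeated-measures decoy-effect analysis.

    ``data`` holds one row per (subject, ternary condition) with columns
    ``subject``, ``proximity`` ('H'/'L'/'tie'), ``dominance``
    ('inferior'/'superior'/'neither'), and ``value`` (bias-corrected T - B
    accuracy).  Tie/neither categories are excluded; subjects missing any of
    the four cells are excluded from the ANOVA (with a warning).  Returns
    per-subject cell means, the 2x2 rmANOVA (closed-form within-subject
    contrasts), and Holm-corrected cellwise t-tests against zero.
    """
    d = data[data["proximity"].isin(["H", "L"])
             & data["dominance"].isin(["inferior", "superior"])]
    cell_means = (
        d.groupby(["subject", "proximity", "dominance"])["value"].mean().unstack(["proximity", "dominance"])
    )
    cell_means = cell_means.reindex(columns=pd.MultiIndex.from_tuples(_CELLS))
    complete = cell_means.dropna()
    n_excl = len(cell_means) - len(complete)
    if n_excl:
        warnings.warn(f"{n_excl} subjects with empty decoy cells excluded from the ANOVA")
    if len(complete) < 2:
        raise ValueError("need >= 2 complete subjects for the 2x2 analysis")
    q = 0.25
    anova = pd.DataFrame(
        {
            "proximity": _rm_contrast(
                complete, {("H", "inferior"): q, ("H", "superior"): q,
                           ("L", "inferior"): -q, ("L", "superior"): -q}),
            "dominance": _rm_contrast(
                complete, {("H", "inferior"): q, ("L", "inferior"): q,
                           ("H", "superior"): -q, ("L", "superior"): -q}),
            "interaction": _rm_contrast(
                complete, {("H", "inferior"): 1, ("H", "superior"): -1,
                           ("L", "inferior"): -1, ("L", "superior"): 1}),
        }
    ).T
    rows = []
    for cell in _CELLS:
        v = complete[cell].to_numpy(float)
        t_val, p = stats.ttest_1samp(v, 0.0) if v.std(ddof=1) > 0 else (0.0, 1.0)
        rows.append({"cell": f"{cell[0]}_{cell[1]}", "mean": v.mean(), "t": t_val,
                     "df": len(v) - 1, "p": p})
    tests = pd.DataFrame(rows).set_index("cell")
    if correction == "holm":
        tests["p_holm"] = multipletests(tests["p"].to_numpy(), method="holm")[1]
    return DecoyTable(cell_means, anova, tests, n_excl)


def bias_corrected_contrasts(
    trials, lam: float = 0.5, nperm: int = 5000, seed: int = 0, tol: float = 1e-9
) -> pd.DataFrame:
    """Per-condition bias-corrected T - B contrasts with decoy categories.

    Convenience pipeline for one subject: matched-baseline accuracies,
    permutation bias correction, and Euclidean/AU decoy classification at
    magnitude weight ``lam``.  Returns one row per matched ternary condition.
    """
    acc = condition_accuracy_table(trials, tol=tol)
    ok = acc["matched"] & np.isfinite(acc["t_acc"]) & np.isfinite(acc["b_acc"])
    acc = acc[ok].reset_index(drop=True)
    bias, corrected = permutation_bias_correction(
        acc["t_acc"], acc["b_acc"], nperm=nperm, seed=seed
    )
    cats = []
    for _, r in acc.iterrows():
        cs = ChoiceSet.from_prospects(
            Prospect(r["hx"], r["hp"]), Prospect(r["lx"], r["lp"]), Prospect(r["dx"], r["dp"])
        )
        cats.append(classify_decoy(cs, lam))
    out = acc.copy()
    out["value"] = corrected.to_numpy()
    out["bias"] = bias
    out["proximity"] = [c.proximity for c in cats]
    out["dominance"] = [c.dominance for c in cats]
    return out
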