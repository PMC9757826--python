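"""Trial-level data model for the two-attribute risky-choice task.

Options are risky prospects defined by a reward magnitude ``X`` and a reward
probability ``P`` (both stored on normalised [0, 1] scales).  On each trial a
subject chooses between two available targets, H and L (labelled by expected
value, EV = X*P, so that EV(H) >= EV(L)); ternary trials additionally display
an unavailable distractor D.  This module provides validated loading of trial
tables, the many-to-one ternary->binary baseline matching, relative-accuracy
computation, and geometric/utility-based classification of distractors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Prospect",
    "ChoiceSet",
    "TrialTable",
    "BaselineEntry",
    "BaselineMap",
    "DecoyCategory",
    "SchemaError",
    "ValidationError",
    "load_trials",
    "match_binary_baselines",
    "relative_accuracy",
    "classify_decoy",
    "classify_decoys",
]

DEFAULT_DEADLINE = 1.5  # seconds; speeded-choice limit of the task
MATCH_DECIMALS = 9      # default absolute matching tolerance is 1e-9

REQUIRED_COLUMNS = ("subject", "trial", "condition", "hx", "hp", "lx", "lp", "choice", "rt")
ATTR_COLUMNS = ("hx", "hp", "lx", "lp", "dx", "dp")
VALID_CHOICES = ("H", "L", "D", "none")


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """A row violates the trial-table invariants."""


@dataclass(frozen=True)
class Prospect:
    """A risky prospect: reward magnitude ``x`` and probability ``p``."""

    x: float
    p: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.p)):
            raise ValidationError(f"non-finite prospect ({self.x}, {self.p})")
        if self.x < 0:
            raise ValidationError(f"negative reward magnitude {self.x}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"probability {self.p} outside [0, 1]")

    @property
    def ev(self) -> float:
        return self.x * self.p


@dataclass(frozen=True)
class ChoiceSet:
    """Targets H and L (EV(H) >= EV(L)) plus an optional distractor D."""

    h: Prospect
    l: Prospect
    d: Prospect | None = None

    def __post_init__(self) -> None:
        if self.h.ev < self.l.ev:
            raise ValidationError("ChoiceSet labels must satisfy EV(H) >= EV(L)")

    @classmethod
    def from_prospects(cls, a: Prospect, b: Prospect, d: Prospect | None = None) -> "ChoiceSet":
        """Build a choice set, assigning H/L labels by EV ordering."""
        if a.ev >= b.ev:
            return cls(a, b, d)
        return cls(b, a, d)

    @property
    def is_ternary(self) -> bool:
        return self.d is not None


@dataclass(frozen=True)
class DecoyCategory:
    """Distractor classification: geometric proximity and AU dominance.

    ``proximity`` is 'H', 'L' or 'tie' by Euclidean distance in the (X, P)
    plane; ``dominance`` is 'superior' if AU(D) exceeds both targets' AU,
    'inferior' if it falls below both, else 'neither'.
    """

    proximity: str
    dominance: str


@dataclass
class BaselineEntry:
    """Binary trials matched to one ternary condition; weight = match count."""

    key: tuple
    binary_rows: list = field(default_factory=list)

    @property
    def weight(self) -> int:
        return len(self.binary_rows)

    @property
    def matched(self) -> bool:
        return self.weight > 0


@dataclass
class BaselineMap:
    """Mapping from unique ternary (H, L, D) conditions to matched binary trials."""

    entries: dict

    @property
    def unmatched(self) -> list:
        return [k for k, e in self.entries.items() if not e.matched]

    @property
    def weights(self) -> dict:
        return {k: e.weight for k, e in self.entries.items()}

    def total_pairs(self) -> int:
        return sum(e.weight for e in self.entries.values())


class TrialTable:
    """Validated table of choice trials.

    Wraps a :class:`pandas.DataFrame` with columns ``subject, trial, condition
    (binary|ternary), hx, hp, lx, lp, dx, dp, choice (H|L|D|none), rt``.
    Attribute values are on normalised [0, 1] scales; RTs are in seconds and
    bounded by the response ``deadline`` (non-responses carry NaN RT and are
    kept in the table but excluded from likelihoods and accuracies).
    """

    def __init__(self, df: pd.DataFrame, deadline: float = DEFAULT_DEADLINE, validate: bool = True):
        self.deadline = float(deadline)
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        for c in ("dx", "dp"):
            if c not in df.columns:
                df[c] = np.nan
        bad_cond = ~df["condition"].isin(["binary", "ternary"])
        if bad_cond.any():
            raise ValidationError(f"unknown condition at rows {list(df.index[bad_cond])}")
        for c in ("hp", "lp", "dp"):
            vals = df[c].to_numpy(dtype=float)
            bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
            if bad.any():
                rows = list(df.index[bad])
                raise ValidationError(f"probability column {c!r} outside [0, 1] at rows {rows}")
        for c in ("hx", "lx", "dx"):
            vals = df[c].to_numpy(dtype=float)
            bad = np.isfinite(vals) & (vals < 0)
            if bad.any():
                raise ValidationError(f"negative magnitude in {c!r} at rows {list(df.index[bad])}")
        tern = df["condition"] == "ternary"
        lacking = tern & (df["dx"].isna() | df["dp"].isna())
        if lacking.any():
            raise ValidationError(
                f"ternary rows lacking distractor attributes: {list(df.index[lacking])}"
            )
        bad_choice = ~df["choice"].isin(VALID_CHOICES)
        if bad_choice.any():
            raise ValidationError(f"invalid choice at rows {list(df.index[bad_choice])}")
        d_in_binary = (~tern) & (df["choice"] == "D")
        if d_in_binary.any():
            raise ValidationError(f"D choice on binary rows {list(df.index[d_in_binary])}")
        responded = df["choice"] != "none"
        rt = df["rt"].to_numpy(dtype=float)
        bad_rt = responded & (~np.isfinite(rt) | (rt <= 0) | (rt > self.deadline))
        # static (choice-only) data carry NaN RTs on responded rows; allow that
        bad_rt &= np.isfinite(rt)
        if bad_rt.any():
            raise ValidationError(
                f"RT outside (0, deadline={self.deadline}] at rows {list(df.index[bad_rt])}"
            )
        self._assign_labels_by_ev()

    def _assign_labels_by_ev(self) -> None:
        """Swap H/L columns (and recode choices) wherever EV(H) < EV(L)."""
        df = self.df
        hv = df["hx"].to_numpy(float) * df["hp"].to_numpy(float)
        lv = df["lx"].to_numpy(float) * df["lp"].to_numpy(float)
        swap = hv < lv
        if swap.any():
            idx = df.index[swap]
            for a, b in (("hx", "lx"), ("hp", "lp")):
                tmp = df.loc[idx, a].copy()
                df.loc[idx, a] = df.loc[idx, b]
                df.loc[idx, b] = tmp
            ch = df.loc[idx, "choice"]
            df.loc[idx, "choice"] = ch.map({"H": "L", "L": "H"}).fillna(ch)

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def binary(self) -> pd.DataFrame:
        return self.df[self.df["condition"] == "binary"]

    @property
    def ternary(self) -> pd.DataFrame:
        return self.df[self.df["condition"] == "ternary"]

    @property
    def responded(self) -> pd.DataFrame:
        return self.df[self.df["choice"] != "none"]

    def copy(self) -> "TrialTable":
        return TrialTable(self.df.copy(), deadline=self.deadline, validate=False)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _build_schema(schema: dict | None) -> dict:
    schema = dict(schema or {})
    colmap = {c: schema.get("columns", {}).get(c, c) for c in REQUIRED_COLUMNS + ("dx", "dp")}
    schema["_colmap"] = colmap
    return schema


def _rescale(values: np.ndarray, bounds) -> np.ndarray:
    lo, hi = float(bounds[0]), float(bounds[1])
    if hi <= lo:
        raise SchemaError(f"degenerate rescale bounds {bounds}")
    return (values - lo) / (hi - lo)


def load_trials(path, schema: dict | None = None, deadline: float = DEFAULT_DEADLINE) -> TrialTable:
    """Read a trials CSV and return a validated :class:`TrialTable`.

    ``schema`` may declare ``columns`` (mapping of canonical to file column
    names) and ``x_scale``/``p_scale`` ``(min, max)`` pairs used to rescale raw
    attribute units onto [0, 1].  H/L labels are reassigned by EV ordering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = _build_schema(schema)
    raw = pd.read_csv(path)
    colmap = schema["_colmap"]
    missing = [v for k, v in colmap.items() if k in REQUIRED_COLUMNS and v not in raw.columns]
    if missing:
        raise SchemaError(f"file {path} missing columns {missing}")
    df = pd.DataFrame({k: raw[v] if v in raw.columns else np.nan for k, v in colmap.items()})
    if "x_scale" in schema:
        for c in ("hx", "lx", "dx"):
            df[c] = _rescale(df[c].to_numpy(dtype=float), schema["x_scale"])
    if "p_scale" in schema:
        for c in ("hp", "lp", "dp"):
            df[c] = _rescale(df[c].to_numpy(dtype=float), schema["p_scale"])
    df["choice"] = df["choice"].fillna("none")
    return TrialTable(df, deadline=deadline)


# -- condition keys --------------------------------------------------------

def _round_key(*vals, decimals: int = MATCH_DECIMALS) -> tuple:
    return tuple(np.round(np.asarray(vals, dtype=float), decimals))


def pair_key(row, decimals: int = MATCH_DECIMALS) -> tuple:
    """Matching key for the (H, L) attribute quadruple."""
    return _round_key(row["hx"], row["hp"], row["lx"], row["lp"], decimals=decimals)


def condition_key(row, decimals: int = MATCH_DECIMALS) -> tuple:
    """Unique condition key: (H, L) pair, plus D attributes when ternary."""
    if row["condition"] == "ternary":
        return _round_key(
            row["hx"], row["hp"], row["lx"], row["lp"], row["dx"], row["dp"], decimals=decimals
        )
    return pair_key(row, decimals=decimals)


def add_condition_keys(df: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Return a copy with ``pair_key`` and ``cond_key`` tuple columns."""
    decimals = max(0, int(round(-math.log10(tol))))
    out = df.copy()
    out["pair_key"] = [pair_key(r, decimals) for _, r in df.iterrows()]
    out["cond_key"] = [condition_key(r, decimals) for _, r in df.iterrows()]
    return out


# -- operations ------------------------------------------------------------

def match_binary_baselines(trials: TrialTable, tol: float = 1e-9) -> BaselineMap:
    """Map every unique ternary condition to the binary trials sharing its (H, L).

    The design reuses (H, L) pairs across ternary conditions that differ only
    in D, so the mapping is many-to-one; the number of matched binary trials
    per condition is the entry's observation weight.  Ternary conditions with
    no match are kept and flagged (weight 0), never silently dropped.
    """
    df = add_condition_keys(trials.df, tol=tol)
    binary = df[df["condition"] == "binary"]
    ternary = df[df["condition"] == "ternary"]
    if len(binary) == 0:
        raise ValidationError("no binary trials: baseline map would be empty")
    by_pair: dict = {}
    for idx, row in binary.iterrows():
        by_pair.setdefault(row["pair_key"], []).append(idx)
    entries: dict = {}
    for idx, row in ternary.iterrows():
        key = row["cond_key"]
        if key not in entries:
            entries[key] = BaselineEntry(key, list(by_pair.get(row["pair_key"], [])))
    return BaselineMap(entries)


def relative_accuracy(
    trials, groupby=("condition",), warn_empty: bool = True
) -> pd.DataFrame:
    """Per-group proportion of H choices among H-or-L choices.

    D choices and non-responses are excluded from numerator and denominator.
    Groups with no H/L choice are reported with NaN accuracy (never 0).
    """
    df = trials.df if isinstance(trials, TrialTable) else trials
    groupby = list(groupby)
    rows = []
    for key, g in df.groupby(groupby, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        hl = g[g["choice"].isin(["H", "L"])]
        n = len(hl)
        if n == 0:
            if warn_empty:
                warnings.warn(f"group {key} has no H/L choices; accuracy undefined")
            acc = np.nan
        else:
            acc = float((hl["choice"] == "H").sum()) / n
        rows.append(dict(zip(groupby, key), p_h=acc, n_hl=n))
    return pd.DataFrame(rows)


def classify_decoy(cs: ChoiceSet, lam: float, tol: float = 0.0) -> DecoyCategory:
    """Classify a distractor by proximity (Euclidean, attribute plane) and AU dominance.

    ``lam`` is the magnitude weight of the weighted-mean additive utility
    AU = lam*X + (1-lam)*P.  Equidistant decoys get proximity 'tie'.
    """
    if cs.d is None:
        raise ValidationError("classify_decoy requires a ternary choice set")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    d = cs.d
    dist_h = math.hypot(d.x - cs.h.x, d.p - cs.h.p)
    dist_l = math.hypot(d.x - cs.l.x, d.p - cs.l.p)
    if abs(dist_h - dist_l) <= tol:
        proximity = "tie"
    else:
        proximity = "H" if dist_h < dist_l else "L"

    def au(p: Prospect) -> float:
        return lam * p.x + (1.0 - lam) * p.p

    au_d, au_h, au_l = au(d), au(cs.h), au(cs.l)
    if au_d > max(au_h, au_l):
        dominance = "superior"
    elif au_d < min(au_h, au_l):
        dominance = "inferior"
    else:
        dominance = "neither"
    return DecoyCategory(proximity, dominance)


def classify_decoys(df: pd.DataFrame, lam: float, tol: float = 0.0) -> pd.DataFrame:
    """Vectorised convenience: DecoyCategory per ternary row of ``df``."""
    tern = df[df["condition"] == "ternary"]
    out = []
    for idx, row in tern.iterrows():
        cs = ChoiceSet.from_prospects(
            Prospect(row["hx"], row["hp"]),
            Prospect(row["lx"], row["lp"]),
            Prospect(row["dx"], row["dp"]),
        )
        cat = classify_decoy(cs, lam, tol=tol)
        out.append({"index": idx, "proximity": cat.proximity, "dominance": cat.dominance})
    return pd.DataFrame(out).set_index("index")
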