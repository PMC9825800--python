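"""Post-stratification weights aligning the sample to population margins.

Snowball-sampled surveys over-represent some country/gender/age cells;
weights correct each question's answered subsample toward user-supplied
population shares over country x gender x age class.  Cells with
population mass but no sampled respondents are collapsed up a fixed
ladder (drop age, then gender, then country) so the weighted margins stay
a proper distribution; every collapse is flagged for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import SPORT_CATEGORIES

__all__ = [
    "PopulationMargins",
    "PostStratificationWeighter",
    "compute_weights",
    "rake_weights",
    "weighted_category_distribution",
]

_CELL = ["country", "gender", "age_class"]


@dataclass(frozen=True)
class PopulationMargins:
    """Target joint distribution over (country, gender, age_class).

    ``cells`` is a DataFrame with columns country, gender, age_class,
    share; shares are non-negative and sum to one.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_CELL + ["share"]) - set(self.cells.columns)
        if missing:
            raise ValueError(f"margins missing columns: {sorted(missing)}")
        s = self.cells["share"]
        if (s < 0).any():
            raise ValueError("population shares must be non-negative")
        if abs(float(s.sum()) - 1.0) > 1e-9:
            raise ValueError(f"population shares must sum to 1, got {s.sum()!r}")

    def joint(self) -> pd.Series:
        return self.cells.set_index(_CELL)["share"]

    def marginal(self, dim: str) -> pd.Series:
        return self.cells.groupby(dim)["share"].sum()

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "PopulationMargins":
        """Build margins from a count table (columns country, gender,
        age_class, count)."""
        df = counts.copy()
        df["share"] = df["count"] / df["count"].sum()
        return cls(df[_CELL + ["share"]])

    @classmethod
    def from_csv(cls, path) -> "PopulationMargins":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _answered_mask(df: pd.DataFrame, question: Optional[str]) -> pd.Series:
    if question is None:
        return pd.Series(True, index=df.index)
    col = f"{question}_answer"
    if col not in df.columns:
        raise KeyError(f"no column {col!r} in respondent table")
    return df[col].isin(["yes", "no"])


def compute_weights(
    respondents: pd.DataFrame,
    question: Optional[str],
    margins: PopulationMargins,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full-cell post-stratification weights for one question's responders.

    Restricted to respondents with a "yes"/"no" answer to ``question``
    (``None`` keeps everyone), each (country, gender, age_class) cell gets
    weight population-share / sample-share.  A (country, gender) group in
    which population and sample support disagree on some age cell is
    collapsed to the (country, gender) level; the same rule applied again
    collapses to country level.  Respondents whose demographic category
    carries no population mass at any ladder level keep weight 1 and are
    flagged ``unmatched``.  Weights are normalised to average 1.

    Returns a DataFrame aligned to the answered respondents with columns
    ``id``, ``weight`` and ``cell_level`` in {"full", "country_gender",
    "country", "unmatched"}.
    """
    sub = respondents[_answered_mask(respondents, question)]
    if sub.empty:
        raise ValueError(f"no respondents answered question {question!r}")
    n = len(sub)
    pop = margins.joint()
    pop_cg = pop.groupby(level=[0, 1]).sum()
    pop_c = pop.groupby(level=0).sum()

    samp = sub.groupby(_CELL).size()
    samp_cg = sub.groupby(["country", "gender"]).size()
    samp_c = sub.groupby("country").size()

    # a (country, gender) group collapses if population and sample disagree
    # on the support of some age cell; a country collapses likewise over its
    # gender groups
    def _mismatch(pop_s: pd.Series, samp_s: pd.Series, parents, both: bool) -> set:
        bad = set()
        keys = set(pop_s[pop_s > 0].index) | set(samp_s.index)
        for key in keys:
            parent = key[:-1] if isinstance(key, tuple) else ()
            if parent not in parents:
                continue
            p = float(pop_s.get(key, 0.0))
            s = int(samp_s.get(key, 0))
            if (p > 0 and s == 0) or (both and p == 0 and s > 0):
                bad.add(parent)
        return bad

    cg_pairs = set(samp_cg.index)
    collapse_cg = _mismatch(pop, samp, cg_pairs, both=True)
    countries = set(samp_c.index)
    # only unreachable population mass forces a country collapse; a sampled
    # gender with no population margin stays unmatched (unit weight, flagged)
    collapse_c = _mismatch(pop_cg, samp_cg, {(c,) for c in countries}, both=False)
    collapse_c = {c for (c,) in collapse_c}
    # a collapsed pair inside an otherwise fine country still forces the pair
    # only; but a pair with no sample at all forces the whole country (handled
    # by the mismatch at country level above)

    weights = np.empty(n, dtype=float)
    levels = np.empty(n, dtype=object)
    cells = list(zip(sub["country"], sub["gender"], sub["age_class"]))
    for i, (c, g, a) in enumerate(cells):
        if c in collapse_c:
            p = float(pop_c.get(c, 0.0))
            if p > 0:
                weights[i] = p / (int(samp_c[c]) / n)
                levels[i] = "country"
                continue
        elif (c, g) in collapse_cg:
            p = float(pop_cg.get((c, g), 0.0))
            if p > 0:
                weights[i] = p / (int(samp_cg[(c, g)]) / n)
                levels[i] = "country_gender"
                continue
        else:
            p = float(pop.get((c, g, a), 0.0))
            if p > 0:
                weights[i] = p / (int(samp[(c, g, a)]) / n)
                levels[i] = "full"
                continue
        weights[i] = 1.0
        levels[i] = "unmatched"
    if normalize:
        weights = weights / weights.mean()
    out = pd.DataFrame(
        {
            "id": sub["id"].to_numpy() if "id" in sub.columns else sub.index.to_numpy(),
            "weight": weights,
            "cell_level": levels,
        },
        index=sub.index,
    )
    return out


def rake_weights(
    respondents: pd.DataFrame,
    question: Optional[str],
    margins: PopulationMargins,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Iterative proportional fitting on the three one-way marginals.

    Alternative to full-cell post-stratification when the joint table is
    sparse; matches the country, gender and age marginals but not the
    joint.  Categories without population mass keep weight 1 (flagged).
    """
    sub = respondents[_answered_mask(respondents, question)]
    if sub.empty:
        raise ValueError(f"no respondents answered question {question!r}")
    n = len(sub)
    w = np.ones(n)
    matched = np.ones(n, dtype=bool)
    targets = {}
    for dim in _CELL:
        marg = margins.marginal(dim)
        vals = sub[dim].to_numpy()
        matched &= np.isin(vals, marg[marg > 0].index)
        targets[dim] = (vals, marg)
    for _ in range(max_iter):
        delta = 0.0
        for dim in _CELL:
            vals, marg = targets[dim]
            cur = pd.Series(w[matched]).groupby(vals[matched]).sum() / w[matched].sum()
            for cat, target in marg.items():
                if target <= 0:
                    continue
                m = matched & (vals == cat)
                if not m.any():
                    continue
                factor = float(target) / float(cur.get(cat, np.nan))
                delta = max(delta, abs(factor - 1.0))
                w[m] *= factor
        if delta < tol:
            break
    w[~matched] = 1.0
    w = w / w.mean()
    return pd.DataFrame(
        {
            "id": sub["id"].to_numpy() if "id" in sub.columns else sub.index.to_numpy(),
            "weight": w,
            "cell_level": np.where(matched, "raked", "unmatched"),
        },
        index=sub.index,
    )


def weighted_category_distribution(records: pd.DataFrame, weights=None) -> pd.Series:
    """Weighted percentage of records per sport category (sums to 100).

    ``records`` needs a ``category`` column; ``weights`` may be an array
    aligned with the records, the name of a weight column, or ``None``
    (falls back to a ``weight`` column if present, else unit weights).
    """
    if weights is None:
        w = records["weight"].to_numpy(float) if "weight" in records.columns else np.ones(len(records))
    elif isinstance(weights, str):
        w = records[weights].to_numpy(float)
    else:
        w = np.asarray(weights, dtype=float)
    totals = pd.Series(w).groupby(records["category"].to_numpy()).sum()
    shares = totals.reindex(SPORT_CATEGORIES, fill_value=0.0)
    return 100.0 * shares / shares.sum()


class PostStratificationWeighter(BaseEstimator, TransformerMixin):
    """Transformer producing per-respondent post-stratification weights.

    Parameters
    ----------
    margins : PopulationMargins
        Target population distribution over country x gender x age class.
    question : str or None
        Restrict to respondents who answered this question (item
        nonresponse makes weights question-specific).
    method : {"poststratify", "rake"}
        Full-cell post-stratification with the collapse ladder, or
        iterative proportional fitting on the three marginals.
    """

    def __init__(
        self,
        margins: PopulationMargins = None,
        question: Optional[str] = None,
        method: str = "poststratify",
    ):
        self.margins = margins
        self.question = question
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        if self.margins is None:
            raise ValueError("margins must be provided")
        if self.method not in ("poststratify", "rake"):
            raise ValueError(f"unknown method {self.method!r}")
        fn = compute_weights if self.method == "poststratify" else rake_weights
        self.weight_table_ = fn(X, self.question, self.margins)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return ``X`` restricted to answered respondents with a
        ``weight`` column attached."""
        out = X.loc[self.weight_table_.index].copy()
        out["weight"] = self.weight_table_["weight"]
        return out
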