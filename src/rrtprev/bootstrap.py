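"""Nonparametric bootstrap inference for RRT share estimates.

Boundary truncation (negative moment solutions replaced by zero-pinned
boundary MLEs) makes the sampling distribution of the shares heavily
skewed, with a point mass at 0 for rare traits.  Normal-theory intervals
are therefore inappropriate; respondents are resampled with replacement,
stratified by randomisation subsample, and percentile intervals are taken
from the replicate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import RRTDesign, STUDY_DESIGN
from .estimator import (
    EstimateTriple,
    ml_estimate,
    ml_estimate_batch,
    weighted_counts,
    ResponseCounts,
)

__all__ = [
    "BootstrapResult",
    "DifferenceTest",
    "bootstrap_estimates",
    "bootstrap_shares",
    "difference_test",
    "percentile_ci",
]

PARAM_NAMES = ("theta_yes", "theta_no", "theta_inc")


def percentile_ci(replicates, level: float) -> tuple[float, float]:
    """Percentile interval: empirical quantiles at (1-level)/2 and 1-(1-level)/2.

    Quantiles use the inclusive linear-interpolation definition.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    reps = np.asarray(replicates, dtype=float)
    if reps.size == 0:
        raise ValueError("no replicates")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _extract_arrays(records: pd.DataFrame, question: str, weight_col: Optional[str]):
    ans_col = f"{question}_answer"
    if weight_col is None:
        for cand in (f"weight_{question}", "weight"):
            if cand in records.columns:
                weight_col = cand
                break
    answered = records[records[ans_col].isin(["yes", "no"])]
    yes = (answered[ans_col] == "yes").to_numpy(dtype=float)
    sub = answered["subsample"].to_numpy()
    w = (
        answered[weight_col].to_numpy(dtype=float)
        if weight_col is not None
        else np.ones(len(answered))
    )
    return yes, sub, w


def _resample_counts(yes, sub, w, B: int, rng: np.random.Generator):
    """Stratified respondent resampling; returns (y1, n1, y2, n2) of shape (B,)."""
    out = []
    for g in (1, 2):
        m = sub == g
        if not m.any():
            raise ValueError(f"no answered records in subsample {g}")
        wg = w[m]
        yg = wg * yes[m]
        draws = rng.integers(0, len(wg), size=(B, len(wg)))
        out.append(yg[draws].sum(axis=1))
        out.append(wg[draws].sum(axis=1))
    y1, n1, y2, n2 = out[0], out[1], out[2], out[3]
    return y1, n1, y2, n2


def bootstrap_shares(
    yes: np.ndarray,
    sub: np.ndarray,
    w: np.ndarray,
    design: RRTDesign,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate share triples, shape (B, 3). Array-level fast path."""
    y1, n1, y2, n2 = _resample_counts(yes, sub, w, B, rng)
    res = ml_estimate_batch(y1, n1, y2, n2, design)
    return np.column_stack([res[p] for p in PARAM_NAMES])


@dataclass
class BootstrapResult:
    """Point estimate, replicate triples and percentile intervals."""

    point: EstimateTriple
    replicates: np.ndarray  # (B, 3): theta_yes, theta_no, theta_inc
    ci: dict[str, tuple[float, float]]
    level: float
    B: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.replicates) != self.B:
            raise ValueError("replicate count does not match B")
        for lo, hi in self.ci.values():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid interval ({lo}, {hi})")

    def replicate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.replicates, columns=list(PARAM_NAMES))

    def to_dict(self) -> dict:
        return {
            "estimate": {
                "yes": self.point.theta_yes,
                "no": self.point.theta_no,
                "inc": self.point.theta_inc,
            },
            "boundary_case": list(self.point.boundary_case or []),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "level": self.level,
            "B": self.B,
            "seed": self.seed,
        }


def bootstrap_estimates(
    records: pd.DataFrame,
    question: str,
    design: RRTDesign = STUDY_DESIGN,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    weight_col: Optional[str] = None,
) -> BootstrapResult:
    """Bootstrap the share estimate for one question.

    Respondents are resampled with replacement within each randomisation
    subsample (preserving n1 and n2); weights travel with their respondent
    and are treated as known constants.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    yes, sub, w = _extract_arrays(records, question, weight_col)
    point = ml_estimate(_counts_from_arrays(yes, sub, w), design)
    rng = np.random.default_rng(seed)
    reps = bootstrap_shares(yes, sub, w, design, B, rng)
    ci = {p: percentile_ci(reps[:, i], level) for i, p in enumerate(PARAM_NAMES)}
    return BootstrapResult(point=point, replicates=reps, ci=ci, level=level, B=B, seed=seed)


def _counts_from_arrays(yes, sub, w) -> ResponseCounts:
    vals = {}
    for g in (1, 2):
        m = sub == g
        if not m.any():
            raise ValueError(f"no answered records in subsample {g}")
        vals[f"n{g}"] = float(w[m].sum())
        vals[f"y{g}"] = float((w[m] * yes[m]).sum())
    return ResponseCounts(**vals)


@dataclass
class DifferenceTest:
    """Bootstrap contrast between a group and a reference population.

    The decision is driven by the honest-yes difference, but all three
    share differences are exposed: honest-no differences can be induced by
    INC differences alone, so they must be inspected jointly before being
    attributed to behaviour.
    """

    estimate_group: EstimateTriple
    estimate_reference: EstimateTriple
    diff: dict[str, float]
    ci_diff: dict[str, tuple[float, float]]
    alpha: float
    significant: bool
    B: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "estimate_group": {p: getattr(self.estimate_group, p) for p in PARAM_NAMES},
            "estimate_reference": {
                p: getattr(self.estimate_reference, p) for p in PARAM_NAMES
            },
            "diff": dict(self.diff),
            "ci_diff": {k: list(v) for k, v in self.ci_diff.items()},
            "alpha": self.alpha,
            "significant": self.significant,
            "B": self.B,
            "seed": self.seed,
        }


def difference_test(
    group: pd.DataFrame,
    reference: pd.DataFrame,
    question: str,
    design: RRTDesign = STUDY_DESIGN,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    weight_col: Optional[str] = None,
) -> DifferenceTest:
    """Bootstrap test of a share difference between two record sets.

    Both sets are resampled independently (stratified by subsample); the
    difference is significant at level ``alpha`` iff the (1 - alpha)
    percentile interval of the honest-yes difference excludes zero.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if B < 1:
        raise ValueError("B must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng_g, rng_r = (np.random.default_rng(s) for s in ss.spawn(2))
    yes_g, sub_g, w_g = _extract_arrays(group, question, weight_col)
    yes_r, sub_r, w_r = _extract_arrays(reference, question, weight_col)
    est_g = ml_estimate(_counts_from_arrays(yes_g, sub_g, w_g), design)
    est_r = ml_estimate(_counts_from_arrays(yes_r, sub_r, w_r), design)
    reps_g = bootstrap_shares(yes_g, sub_g, w_g, design, B, rng_g)
    reps_r = bootstrap_shares(yes_r, sub_r, w_r, design, B, rng_r)
    diff_reps = reps_g - reps_r
    diff = {
        p: float(getattr(est_g, p) - getattr(est_r, p)) for p in PARAM_NAMES
    }
    ci_diff = {
        p: tuple(
            float(q)
            for q in np.quantile(
                diff_reps[:, i], [alpha / 2.0, 1.0 - alpha / 2.0], method="linear"
            )
        )
        for i, p in enumerate(PARAM_NAMES)
    }
    lo, hi = ci_diff["theta_yes"]
    significant = bool(lo > 0.0 or hi < 0.0)
    return DifferenceTest(
        estimate_group=est_g,
        estimate_reference=est_r,
        diff=diff,
        ci_diff=ci_diff,
        alpha=alpha,
        significant=significant,
        B=B,
        seed=seed,
    )
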