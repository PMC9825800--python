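"""Maximum-likelihood estimation of the three RRT population shares.

Under the forced-response design with directed detection of non-compliant
"no" answers, the population splits into three latent classes per question:

* honest-yes (``theta_yes``): compliant respondents who carry the sensitive
  trait — they answer "yes" unless the random digit forces a "no";
* honest-no (``theta_no``): compliant non-carriers — they answer "yes" only
  when forced to;
* INC (``theta_inc``): instruction-non-compliant respondents who answer
  "no" regardless of the assigned question.

The observed yes-probability in subsample *g* is therefore

    lambda_g = theta_yes * (1 - p_g_no) + theta_no * p_g_yes

and two subsamples with different (p_yes, p_no) identify all three shares.
The unconstrained solution of the resulting 2x2 linear system is the MLE
whenever it lies in the probability simplex; otherwise the MLE sits on the
simplex boundary and is found by maximising the binomial likelihood with
one or two shares pinned to zero, keeping the case with the highest
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .design import RRTDesign, STUDY_DESIGN, validate_design

__all__ = [
    "ResponseCounts",
    "EstimateTriple",
    "expected_yes_rate",
    "moment_solve",
    "log_likelihood",
    "ml_estimate",
    "ml_estimate_batch",
    "prevalence_bounds",
    "weighted_counts",
    "RRTPrevalenceEstimator",
]

#: log-likelihood differences below this are treated as ties
LL_TIE_TOL = 1e-9
_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class ResponseCounts:
    """Sufficient statistics: (possibly weighted) totals and yes-counts.

    ``n1``/``n2`` are the respondent totals (or weight sums) in the two
    subsamples, ``y1``/``y2`` the corresponding "yes" totals.
    """

    n1: float
    y1: float
    n2: float
    y2: float

    def __post_init__(self) -> None:
        for g, (n, y) in ((1, (self.n1, self.y1)), (2, (self.n2, self.y2))):
            if n <= 0:
                raise ValueError(f"subsample {g}: total count must be positive, got {n}")
            if not 0 <= y <= n:
                raise ValueError(f"subsample {g}: yes-count {y} outside [0, {n}]")

    @property
    def yes_rates(self) -> tuple[float, float]:
        return self.y1 / self.n1, self.y2 / self.n2


@dataclass(frozen=True)
class EstimateTriple:
    """Estimated population shares on the probability simplex.

    ``boundary_case`` names the shares pinned to zero by the constrained
    maximisation (``None`` for an interior solution).  ``unique`` is False
    when distinct boundary solutions tied in likelihood; the reported one
    then has the largest ``theta_inc`` among the maximisers.
    """

    theta_yes: float
    theta_no: float
    theta_inc: float
    boundary_case: Optional[tuple[str, ...]] = None
    log_likelihood: float = float("nan")
    unique: bool = True

    def __post_init__(self) -> None:
        shares = (self.theta_yes, self.theta_no, self.theta_inc)
        if any(s < -_SIMPLEX_TOL or s > 1 + _SIMPLEX_TOL for s in shares):
            raise ValueError(f"shares outside [0, 1]: {shares}")
        if abs(sum(shares) - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"shares must sum to 1, got {sum(shares)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_yes, self.theta_no, self.theta_inc])


def _coef(design: RRTDesign) -> tuple[float, float, float, float]:
    """Linear coefficients of (theta_yes, theta_no) in the two yes-rates."""
    return (
        1.0 - design.p1_no,
        design.p1_yes,
        1.0 - design.p2_no,
        design.p2_yes,
    )


def expected_yes_rate(triple, design: RRTDesign, subsample: int) -> float:
    """Forward model: probability of an observed "yes" in a subsample."""
    if isinstance(triple, EstimateTriple):
        ty, tn = triple.theta_yes, triple.theta_no
    else:
        ty, tn = triple[0], triple[1]
    return ty * (1.0 - design.p_no(subsample)) + tn * design.p_yes(subsample)


def moment_solve(counts: ResponseCounts, design: RRTDesign) -> tuple[float, float, float]:
    """Solve the 2x2 linear system matching the observed yes-rates exactly.

    Returns the unconstrained ``(theta_yes, theta_no, theta_inc)``; the
    values may fall outside [0, 1], which signals a boundary MLE.
    """
    validate_design(design)
    a1, b1, a2, b2 = _coef(design)
    det = a1 * b2 - a2 * b1
    if abs(det) < 1e-12:
        raise ValueError("singular design: the two subsamples do not identify the shares")
    lam1, lam2 = counts.yes_rates
    ty = (b2 * lam1 - b1 * lam2) / det
    tn = (a1 * lam2 - a2 * lam1) / det
    return ty, tn, 1.0 - ty - tn


def _ll_kernel(y, n, lam):
    """Binomial log-likelihood kernel, elementwise; -inf on impossible outcomes.

    The binomial coefficient is omitted: counts may be weighted (pseudo-
    likelihood) and only likelihood differences at fixed data matter.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_y = np.where(y > 0, y * np.log(lam), 0.0)
        term_n = np.where(n - y > 0, (n - y) * np.log1p(-lam), 0.0)
    return term_y + term_n


def log_likelihood(counts: ResponseCounts, design: RRTDesign, triple) -> float:
    """Log-likelihood of the observed counts under a share triple."""
    total = 0.0
    for g, (n, y) in ((1, (counts.n1, counts.y1)), (2, (counts.n2, counts.y2))):
        lam = expected_yes_rate(triple, design, g)
        total += float(_ll_kernel(y, n, np.clip(lam, 0.0, 1.0)))
    return total


def _maximize_affine_1d(c1, d1, c2, d2, y1, n1, y2, n2, iters: int = 90):
    """Maximise the concave 1-D log-likelihood with lambda_g = c_g + d_g * t.

    Bisection on the (monotone decreasing) derivative over t in [0, 1];
    endpoints are re-checked exactly.  All arguments broadcast.
    """
    y1, n1, y2, n2 = (np.asarray(a, dtype=float) for a in (y1, n1, y2, n2))
    lo = np.zeros(np.broadcast(y1, y2).shape)
    hi = np.ones_like(lo)
    tiny = 1e-300
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        l1 = np.clip(c1 + d1 * mid, tiny, 1.0 - 1e-16)
        l2 = np.clip(c2 + d2 * mid, tiny, 1.0 - 1e-16)
        grad = d1 * (y1 / l1 - (n1 - y1) / (1.0 - l1)) + d2 * (
            y2 / l2 - (n2 - y2) / (1.0 - l2)
        )
        lo = np.where(grad > 0, mid, lo)
        hi = np.where(grad > 0, hi, mid)
    t = 0.5 * (lo + hi)
    cand = np.stack([t, np.zeros_like(t), np.ones_like(t)])
    ll = _ll_kernel(y1, n1, np.clip(c1 + d1 * cand, 0.0, 1.0)) + _ll_kernel(
        y2, n2, np.clip(c2 + d2 * cand, 0.0, 1.0)
    )
    best = np.argmax(ll, axis=0)
    idx = np.indices(t.shape)
    return cand[(best, *idx)], ll[(best, *idx)]


def ml_estimate_batch(y1, n1, y2, n2, design: RRTDesign) -> dict[str, np.ndarray]:
    """Vectorised constrained MLE over arrays of count configurations.

    Returns arrays ``theta_yes``, ``theta_no``, ``theta_inc``,
    ``log_likelihood``, ``interior`` (bool) and ``unique`` (bool), all of
    the broadcast shape of the inputs.  This is the fast path used by the
    bootstrap; :func:`ml_estimate` is the scalar wrapper.
    """
    validate_design(design)
    a1, b1, a2, b2 = _coef(design)
    det = a1 * b2 - a2 * b1
    if abs(det) < 1e-12:
        raise ValueError("singular design: the two subsamples do not identify the shares")
    y1, n1, y2, n2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (y1, n1, y2, n2))
    )
    shape = y1.shape
    y1, n1, y2, n2 = (np.atleast_1d(a).ravel() for a in (y1, n1, y2, n2))
    lam1, lam2 = y1 / n1, y2 / n2
    ty = (b2 * lam1 - b1 * lam2) / det
    tn = (a1 * lam2 - a2 * lam1) / det
    ti = 1.0 - ty - tn
    interior = (ty >= -_SIMPLEX_TOL) & (tn >= -_SIMPLEX_TOL) & (ti >= -_SIMPLEX_TOL)

    ll = _ll_kernel(y1, n1, lam1) + _ll_kernel(y2, n2, lam2)
    ty = np.clip(ty, 0.0, 1.0)
    tn = np.clip(tn, 0.0, 1.0)
    ti = np.clip(ti, 0.0, 1.0)
    unique = np.ones(ty.shape, dtype=bool)

    if not interior.all():
        m = ~interior
        yy1, nn1, yy2, nn2 = y1[m], n1[m], y2[m], n2[m]
        # theta_yes = 0: lambda_g = p_g_yes * t,        triple (0, t, 1-t)
        tA, llA = _maximize_affine_1d(0.0, b1, 0.0, b2, yy1, nn1, yy2, nn2)
        # theta_no = 0:  lambda_g = (1 - p_g_no) * t,   triple (t, 0, 1-t)
        tB, llB = _maximize_affine_1d(0.0, a1, 0.0, a2, yy1, nn1, yy2, nn2)
        # theta_inc = 0: lambda_g = p_g_yes + (1-p_g_no-p_g_yes) * t, (t, 1-t, 0)
        tC, llC = _maximize_affine_1d(b1, a1 - b1, b2, a2 - b2, yy1, nn1, yy2, nn2)

        lls = np.stack([llA, llB, llC])
        incs = np.stack([1.0 - tA, 1.0 - tB, np.zeros_like(tC)])
        tys = np.stack([np.zeros_like(tA), tB, tC])
        tns = np.stack([tA, np.zeros_like(tB), 1.0 - tC])
        best_ll = lls.max(axis=0)
        tied = lls >= best_ll - LL_TIE_TOL
        # among likelihood maximisers, report the largest theta_inc
        # (conservative about non-compliance) and flag non-uniqueness when
        # materially different triples tie
        inc_masked = np.where(tied, incs, -np.inf)
        pick = np.argmax(inc_masked, axis=0)
        idx = np.indices(pick.shape)
        sel = (pick, *idx)
        spread = np.ptp(np.where(tied, tys, tys[sel]), axis=0) + np.ptp(
            np.where(tied, tns, tns[sel]), axis=0
        )
        ty[m], tn[m] = tys[sel], tns[sel]
        ti[m] = 1.0 - ty[m] - tn[m]
        ll[m] = best_ll
        unique[m] = spread <= 1e-9

    return {
        "theta_yes": ty.reshape(shape),
        "theta_no": tn.reshape(shape),
        "theta_inc": ti.reshape(shape),
        "log_likelihood": ll.reshape(shape),
        "interior": interior.reshape(shape),
        "unique": unique.reshape(shape),
    }


def ml_estimate(counts: ResponseCounts, design: RRTDesign = STUDY_DESIGN) -> EstimateTriple:
    """Constrained MLE of (honest-yes, honest-no, INC) from two-subsample counts.

    The moment solution is returned when it lies in the simplex (it matches
    both observed rates exactly, hence is the unconstrained MLE).  Otherwise
    every boundary case — each share pinned to zero, including the simplex
    vertices — is maximised and the highest-likelihood case is reported,
    with ties broken toward the largest INC share.
    """
    res = ml_estimate_batch(counts.y1, counts.n1, counts.y2, counts.n2, design)
    ty = float(res["theta_yes"])
    tn = float(res["theta_no"])
    ti = float(res["theta_inc"])
    if bool(res["interior"]):
        case = None
    else:
        names = ("theta_yes", "theta_no", "theta_inc")
        case = tuple(nm for nm, v in zip(names, (ty, tn, ti)) if v <= _SIMPLEX_TOL)
    return EstimateTriple(
        theta_yes=ty,
        theta_no=tn,
        theta_inc=ti,
        boundary_case=case,
        log_likelihood=float(res["log_likelihood"]),
        unique=bool(res["unique"]),
    )


def prevalence_bounds(triple: EstimateTriple) -> tuple[float, float]:
    """Bounds on the true prevalence: INC "no" answers may conceal the trait.

    The honest-yes share is a lower bound; every INC respondent might be a
    concealed carrier, so honest-yes + INC is the upper bound.
    """
    return triple.theta_yes, triple.theta_yes + triple.theta_inc


def weighted_counts(
    records: pd.DataFrame,
    question: str,
    weight_col: Optional[str] = None,
) -> ResponseCounts:
    """Reduce respondent-level answers to (weighted) two-subsample counts.

    ``records`` needs a ``subsample`` column and a ``{question}_answer``
    column with values "yes"/"no" (anything else counts as item nonresponse
    and is excluded).  Weights come from ``weight_col`` if given, else from
    ``weight_{question}`` or ``weight`` when present, else 1.
    """
    ans_col = f"{question}_answer"
    if ans_col not in records.columns:
        raise KeyError(f"no column {ans_col!r} in records")
    if weight_col is None:
        for cand in (f"weight_{question}", "weight"):
            if cand in records.columns:
                weight_col = cand
                break
    answered = records[records[ans_col].isin(["yes", "no"])]
    w = (
        answered[weight_col].to_numpy(dtype=float)
        if weight_col is not None
        else np.ones(len(answered))
    )
    yes = (answered[ans_col] == "yes").to_numpy()
    sub = answered["subsample"].to_numpy()
    out = {}
    for g in (1, 2):
        m = sub == g
        if not m.any():
            raise ValueError(f"no answered records in subsample {g} for question {question!r}")
        out[f"n{g}"] = float(w[m].sum())
        out[f"y{g}"] = float(w[m & yes].sum())
    return ResponseCounts(**out)


class RRTPrevalenceEstimator(BaseEstimator):
    """Scikit-learn style interface to the constrained RRT share estimator.

    Parameters
    ----------
    design : RRTDesign, default=STUDY_DESIGN
        The two-subsample forced-response design.

    Attributes
    ----------
    theta_yes_, theta_no_, theta_inc_ : float
        Estimated honest-yes, honest-no and INC shares.
    estimate_ : EstimateTriple
        The full estimate including boundary information.
    counts_ : ResponseCounts
        The sufficient statistics the fit reduced the data to.
    bounds_ : tuple of float
        Prevalence bounds (theta_yes, theta_yes + theta_inc).

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[1, 1]] * 150 + [[1, 0]] * 850 + [[2, 1]] * 250 + [[2, 0]] * 750)
    >>> RRTPrevalenceEstimator().fit(X).theta_yes_
    0.125
    """

    def __init__(self, design: RRTDesign = STUDY_DESIGN):
        self.design = design

    def fit(self, X, y=None, sample_weight=None):
        """Fit from respondent-level data.

        ``X`` is either a DataFrame with columns ``subsample`` and
        ``answer`` ("yes"/"no" or 1/0), or an (n, 2) array of
        ``(subsample, answer)`` rows with answers coded 1/0.
        """
        if isinstance(X, pd.DataFrame):
            sub = X["subsample"].to_numpy()
            ans = X["answer"].to_numpy()
            if ans.dtype == object or ans.dtype.kind in "US":
                ans = (ans == "yes").astype(float)
        else:
            X = np.asarray(X)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("X must be an (n, 2) array of (subsample, answer)")
            sub, ans = X[:, 0], X[:, 1].astype(float)
        w = np.ones(len(sub)) if sample_weight is None else np.asarray(sample_weight, float)
        vals = {}
        for g in (1, 2):
            m = sub == g
            if not m.any():
                raise ValueError(f"no records in subsample {g}")
            vals[f"n{g}"] = float(w[m].sum())
            vals[f"y{g}"] = float((w[m] * ans[m]).sum())
        return self.fit_counts(ResponseCounts(**vals))

    def fit_counts(self, counts: ResponseCounts):
        """Fit directly from two-subsample sufficient statistics."""
        est = ml_estimate(counts, self.design)
        self.counts_ = counts
        self.estimate_ = est
        self.theta_yes_ = est.theta_yes
        self.theta_no_ = est.theta_no
        self.theta_inc_ = est.theta_inc
        self.boundary_case_ = est.boundary_case
        self.log_likelihood_ = est.log_likelihood
        self.bounds_ = prevalence_bounds(est)
        return self

    def predict_yes_rate(self, subsample) -> np.ndarray:
        """Expected observed yes-rate per subsample under the fitted shares."""
        check_is_fitted(self, "estimate_")
        sub = np.atleast_1d(np.asarray(subsample))
        return np.array(
            [expected_yes_rate(self.estimate_, self.design, int(g)) for g in sub]
        )
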