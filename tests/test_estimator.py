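import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from rrtprev import (
    EstimateTriple,
    ResponseCounts,
    RRTPrevalenceEstimator,
    STUDY_DESIGN,
    expected_yes_rate,
    log_likelihood,
    ml_estimate,
    moment_solve,
    prevalence_bounds,
    weighted_counts,
)
from conftest import make_records
from oracle import GridOracle


@pytest.mark.parametrize(
    "triple, g, expected",
    [((1, 0, 0), 1, 0.8), ((0, 1, 0), 2, 0.3), ((0, 0, 1), 1, 0.0), ((0, 0, 1), 2, 0.0)],
)
def test_expected_yes_rate_forward_model(triple, g, expected):
    assert expected_yes_rate(triple, STUDY_DESIGN, g) == pytest.approx(expected)


def test_moment_solve_inverts_forward_model():
    # all honest carriers: both subsample rates 0.8
    ty, tn, ti = moment_solve(ResponseCounts(10, 8, 10, 8), STUDY_DESIGN)
    assert (ty, tn, ti) == pytest.approx((1.0, 0.0, 0.0))
    ty, tn, ti = moment_solve(ResponseCounts(100, 15, 100, 25), STUDY_DESIGN)
    assert (ty, tn, ti) == pytest.approx((0.125, 0.5, 0.375))
    # substituting back reproduces the observed rates
    assert expected_yes_rate((ty, tn), STUDY_DESIGN, 1) == pytest.approx(0.15)
    assert expected_yes_rate((ty, tn), STUDY_DESIGN, 2) == pytest.approx(0.25)


def test_moment_solve_can_leave_the_simplex():
    # lambda2 < lambda1 forces a negative honest-no share
    ty, tn, ti = moment_solve(ResponseCounts(10, 3, 10, 1), STUDY_DESIGN)
    assert tn == pytest.approx(-1.0)


def test_log_likelihood_reference_points():
    all_inc = EstimateTriple(0, 0, 1)
    assert log_likelihood(ResponseCounts(10, 0, 10, 0), STUDY_DESIGN, all_inc) == 0.0
    assert log_likelihood(ResponseCounts(10, 10, 10, 0), STUDY_DESIGN, all_inc) == -np.inf
    counts = ResponseCounts(100, 15, 100, 25)
    matched = EstimateTriple(0.125, 0.5, 0.375)
    off = EstimateTriple(0.1, 0.5, 0.4)
    assert log_likelihood(counts, STUDY_DESIGN, matched) > log_likelihood(
        counts, STUDY_DESIGN, off
    )


def test_ml_estimate_interior_matches_moment_solution():
    est = ml_estimate(ResponseCounts(1000, 150, 1000, 250), STUDY_DESIGN)
    assert est.as_array() == pytest.approx([0.125, 0.5, 0.375])
    assert est.boundary_case is None


def test_ml_estimate_boundary_beats_grid_oracle():
    oracle = GridOracle(STUDY_DESIGN)
    est = ml_estimate(ResponseCounts(1000, 300, 1000, 100), STUDY_DESIGN)
    assert est.boundary_case is not None and "theta_no" in est.boundary_case
    *_, ll = oracle.best(300, 1000, 100, 1000)
    assert est.log_likelihood >= ll - 1e-6


def test_ml_estimate_all_no_data_is_all_inc_vertex():
    est = ml_estimate(ResponseCounts(1000, 0, 1000, 0), STUDY_DESIGN)
    assert est.theta_yes == 0.0
    assert est.theta_no + est.theta_inc == pytest.approx(1.0)
    assert est.theta_inc == pytest.approx(1.0)  # tie-break favours INC
    assert est.log_likelihood == pytest.approx(0.0)


@settings(deadline=None, derandomize=True, max_examples=150)
@given(
    n1=st.integers(1, 2000),
    n2=st.integers(1, 2000),
    f1=st.floats(0, 1),
    f2=st.floats(0, 1),
)
def test_ml_estimate_simplex_closure(n1, n2, f1, f2):
    """The constrained MLE always lies on the probability simplex."""
    est = ml_estimate(
        ResponseCounts(n1, int(round(f1 * n1)), n2, int(round(f2 * n2))), STUDY_DESIGN
    )
    arr = est.as_array()
    assert (arr >= -1e-9).all() and (arr <= 1 + 1e-9).all()
    assert arr.sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "ty, ti, expected",
    [(0.10, 0.20, (0.10, 0.30)), (0.44, 0.37, (0.44, 0.81)), (0.0, 0.0, (0.0, 0.0))],
)
def test_prevalence_bounds(ty, ti, expected):
    triple = EstimateTriple(ty, 1 - ty - ti, ti)
    assert prevalence_bounds(triple) == pytest.approx(expected)


def test_weighted_counts_sums_and_exclusions():
    df = pd.DataFrame(
        {
            "subsample": [1, 1, 2, 2, 1],
            "q_answer": ["yes", "no", "yes", "no", None],
            "weight": [2.0, 1.0, 1.0, 1.0, 5.0],
        }
    )
    c = weighted_counts(df, "q")
    assert (c.n1, c.y1) == (3.0, 2.0)  # missing answer excluded from both sums
    assert (c.n2, c.y2) == (2.0, 1.0)
    unweighted = weighted_counts(df.drop(columns="weight"), "q")
    assert (unweighted.n1, unweighted.y1) == (2.0, 1.0)


def test_weighted_counts_requires_both_subsamples():
    df = pd.DataFrame({"subsample": [1, 1], "q_answer": ["yes", "no"]})
    with pytest.raises(ValueError, match="subsample 2"):
        weighted_counts(df, "q")


def test_sklearn_estimator_interface():
    df = make_records(1000, 1000, 150, 250).rename(columns={"q_answer": "answer"})
    est = RRTPrevalenceEstimator().fit(df)
    assert est.theta_yes_ == pytest.approx(0.125)
    assert est.bounds_ == pytest.approx((0.125, 0.5))
    X = np.array([[1, 1]] * 150 + [[1, 0]] * 850 + [[2, 1]] * 250 + [[2, 0]] * 750)
    est2 = clone(est).fit(X)
    assert est2.theta_no_ == pytest.approx(est.theta_no_)
    assert est.predict_yes_rate([1, 2]) == pytest.approx([0.15, 0.25])


def test_counts_validation():
    with pytest.raises(ValueError):
        ResponseCounts(0, 0, 10, 5)
    with pytest.raises(ValueError):
        ResponseCounts(10, 11, 10, 5)
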