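"""Forced-response RRT design: randomisation probabilities and digit rules.

A forced-response randomized response question works off a uniform random
number held only by the respondent.  Depending on the last digit, the
respondent either answers a harmless question with a known answer ("forced
yes" / "forced no") or the sensitive question itself.  Instruction
non-compliance (INC) is detectable when the sample is split into two
subsamples with *different* forced-answer probabilities: the two observed
yes-rates then identify three population shares (honest-yes, honest-no,
INC) instead of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

QuestionKind = Literal["forced_yes", "forced_no", "sensitive"]

_DIGITS = frozenset(range(10))


class DesignError(ValueError):
    """Raised when an RRT design violates its consistency requirements."""


def _default_digit_rules(
    p1_yes: float, p1_no: float, p2_yes: float, p2_no: float
) -> dict[int, dict[str, frozenset[int]]]:
    """Realise the probabilities with consecutive low digits starting at 1.

    Any partition with the right cardinalities is statistically equivalent;
    consecutive digits keep the instruction printable.
    """
    rules = {}
    for g, (py, pn) in ((1, (p1_yes, p1_no)), (2, (p2_yes, p2_no))):
        ky, kn = round(py * 10), round(pn * 10)
        rules[g] = {
            "digits_yes": frozenset(range(1, 1 + ky)),
            "digits_no": frozenset(range(1 + ky, 1 + ky + kn)),
        }
    return rules


@dataclass(frozen=True)
class RRTDesign:
    """Two-subsample forced-response design with digit-to-question rules.

    Parameters
    ----------
    p1_yes, p1_no : float
        Probability of a forced-"yes" / forced-"no" question in subsample 1.
    p2_yes, p2_no : float
        The same for subsample 2.
    digit_rules : mapping, optional
        Per subsample (1, 2), a mapping with keys ``digits_yes`` and
        ``digits_no`` giving the last-digit sets that trigger each forced
        question; the remaining digits route to the sensitive question.
        Defaults to consecutive low digits realising the probabilities.
    """

    p1_yes: float
    p1_no: float
    p2_yes: float
    p2_no: float
    digit_rules: Mapping[int, Mapping[str, frozenset[int]]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.digit_rules is None:
            object.__setattr__(
                self,
                "digit_rules",
                _default_digit_rules(self.p1_yes, self.p1_no, self.p2_yes, self.p2_no),
            )
        validate_design(self)

    def p_yes(self, subsample: int) -> float:
        return {1: self.p1_yes, 2: self.p2_yes}[subsample]

    def p_no(self, subsample: int) -> float:
        return {1: self.p1_no, 2: self.p2_no}[subsample]

    def p_sensitive(self, subsample: int) -> float:
        return 1.0 - self.p_yes(subsample) - self.p_no(subsample)

    def to_dict(self) -> dict:
        return {
            f"subsample_{g}": {
                "p_yes": self.p_yes(g),
                "p_no": self.p_no(g),
                "digits_yes": sorted(self.digit_rules[g]["digits_yes"]),
                "digits_no": sorted(self.digit_rules[g]["digits_no"]),
            }
            for g in (1, 2)
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RRTDesign":
        s1, s2 = d["subsample_1"], d["subsample_2"]
        rules = {
            g: {
                "digits_yes": frozenset(s["digits_yes"]),
                "digits_no": frozenset(s["digits_no"]),
            }
            for g, s in ((1, s1), (2, s2))
        }
        return cls(s1["p_yes"], s1["p_no"], s2["p_yes"], s2["p_no"], rules)


def validate_design(design: RRTDesign) -> RRTDesign:
    """Check a design's internal consistency and return it unchanged.

    Raises
    ------
    DesignError
        If probabilities fall outside [0, 1] or sum to >= 1 within a
        subsample, if the two subsamples share the same probability pair
        (the three shares are then not identifiable), or if the digit sets
        do not realise the probabilities exactly in tenths.
    """
    for g in (1, 2):
        py, pn = design.p_yes(g), design.p_no(g)
        if not (0.0 <= py <= 1.0 and 0.0 <= pn <= 1.0):
            raise DesignError(f"subsample {g}: probabilities must lie in [0, 1]")
        if py + pn >= 1.0:
            raise DesignError(
                f"subsample {g}: p_yes + p_no = {py + pn:g} leaves no room "
                "for the sensitive question (must be < 1)"
            )
    if (design.p1_yes, design.p1_no) == (design.p2_yes, design.p2_no):
        raise DesignError(
            "identical probability pairs in both subsamples: the three "
            "population shares are not identifiable"
        )
    for g in (1, 2):
        rule = design.digit_rules[g]
        dy, dn = frozenset(rule["digits_yes"]), frozenset(rule["digits_no"])
        if not (dy <= _DIGITS and dn <= _DIGITS) or dy & dn:
            raise DesignError(f"subsample {g}: digit sets must be disjoint subsets of 0-9")
        if len(dy) != round(design.p_yes(g) * 10) or len(dn) != round(design.p_no(g) * 10):
            raise DesignError(
                f"subsample {g}: digit set sizes ({len(dy)}, {len(dn)}) do not "
                f"realise (p_yes, p_no) = ({design.p_yes(g)}, {design.p_no(g)}) in tenths"
            )
    return design


def assign_question(last_digit: int, subsample: int, design: RRTDesign) -> QuestionKind:
    """Map a random number's last digit to the question kind it triggers."""
    if last_digit not in _DIGITS:
        raise ValueError(f"last digit must be an integer 0-9, got {last_digit!r}")
    if subsample not in (1, 2):
        raise ValueError(f"subsample must be 1 or 2, got {subsample!r}")
    rule = design.digit_rules[subsample]
    if last_digit in rule["digits_yes"]:
        return "forced_yes"
    if last_digit in rule["digits_no"]:
        return "forced_no"
    return "sensitive"


#: The design used throughout: p1y=0.1, p1n=0.2 / p2y=0.3, p2n=0.2, chosen to
#: maximise the share of honest responders at the cost of INC-estimator variance.
STUDY_DESIGN = RRTDesign(p1_yes=0.1, p1_no=0.2, p2_yes=0.3, p2_no=0.2)
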