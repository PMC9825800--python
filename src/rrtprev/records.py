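"""Respondent-record handling: quality control, sport prioritisation,
doper-vs-doping record selection and sport categorisation.

The canonical respondent table is a wide pandas DataFrame, one row per
respondent, with demographic columns (``id``, ``birth_year``, ``education``,
``country``, ``gender``, ``age_class``, ``subsample``), per-question answer
and response-time columns (``{q}_answer`` with values "yes"/"no"/missing,
``{q}_time_s``) and up to four sports in wide columns
(``sport{k}_name``, ``sport{k}_level``, ``sport{k}_years``).  The sensitive
doping question is asked only for the two highest-priority sports
(``doping_1``, ``doping_2``, with ``doping_{j}_sport`` naming the sport).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPETITION_LEVELS",
    "EDUCATION_LEVELS",
    "RRT_QUESTIONS",
    "SPORT_CATEGORIES",
    "CategoryMap",
    "DEFAULT_CATEGORY_MAP",
    "QCConfig",
    "SportEntry",
    "categorize_sport",
    "doper_records",
    "doping_records",
    "prioritize_sports",
    "quality_filter",
    "select_doper_record",
]

#: competition levels, ordered from lowest to highest priority
COMPETITION_LEVELS = ("none", "local", "regional", "national", "international")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(COMPETITION_LEVELS)}

#: ordered education scale used by the plausibility rules
EDUCATION_LEVELS = (
    "in_school",
    "primary",
    "secondary",
    "vocational",
    "bachelor",
    "master",
    "doctorate",
)

#: RRT questions in questionnaire order; the timing rules key off this order
RRT_QUESTIONS = ("otc", "medication", "doping_1", "doping_2", "image")

SPORT_CATEGORIES = ("Artistic", "Combat", "Games", "CGS", "Other")


@dataclass(frozen=True)
class SportEntry:
    """One sport a respondent reported playing."""

    name: str
    level: str
    years: float
    doping_answer: Optional[str] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.level not in COMPETITION_LEVELS:
            raise ValueError(f"unknown competition level {self.level!r}")
        if self.years < 0:
            raise ValueError("years played must be non-negative")


def prioritize_sports(entries: Sequence[SportEntry]) -> list[SportEntry]:
    """Return the (up to) two sports that carry the doping question.

    Stable sort: competition level first (highest priority), years played
    second; exact ties keep input order.
    """
    if not 1 <= len(entries) <= 4:
        raise ValueError("a respondent reports between 1 and 4 sports")
    ranked = sorted(entries, key=lambda e: (-_LEVEL_RANK[e.level], -e.years))
    return ranked[: min(2, len(ranked))]


def _norm(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


#: starter sport -> category map; real analyses extend it via CSV
DEFAULT_CATEGORY_MAP = {
    "dance": "Artistic",
    "gymnastics": "Artistic",
    "figure skating": "Artistic",
    "judo": "Combat",
    "karate": "Combat",
    "boxing": "Combat",
    "wrestling": "Combat",
    "football": "Games",
    "tennis": "Games",
    "volleyball": "Games",
    "basketball": "Games",
    "handball": "Games",
    "athletics": "CGS",
    "cycling": "CGS",
    "swimming": "CGS",
    "jogging/running": "CGS",
    "running": "CGS",
    "rowing": "CGS",
    "fitness": "Other",
}


@dataclass(frozen=True)
class CategoryMap:
    """Total sport-name -> category mapping with a residual default."""

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MAP))
    default: str = "Other"

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values()} - set(SPORT_CATEGORIES)
        if bad or self.default not in SPORT_CATEGORIES:
            raise ValueError(f"unknown categories: {bad or self.default}")

    def lookup(self, name: str) -> str:
        return self.mapping.get(_norm(name), self.default)

    @classmethod
    def from_csv(cls, path, default: str = "Other") -> "CategoryMap":
        df = pd.read_csv(path)
        return cls({_norm(r.sport): r.category for r in df.itertuples()}, default)


def categorize_sport(name: str, cmap: Optional[CategoryMap] = None) -> str:
    """Case- and whitespace-normalised category lookup, default "Other"."""
    return (cmap or CategoryMap()).lookup(name)


@dataclass(frozen=True)
class QCConfig:
    """Data-quality rules.

    Timing thresholds apply to the response-time columns of questions that
    were actually presented (answer or time recorded): the first RRT
    question must take at least ``min_first_rrt_s`` seconds, and any later
    RRT question answered in ``max_fast_subsequent_s`` seconds or less is
    deemed untrustworthy.  Plausibility pairs age (at ``survey_year``)
    against the reported education level.
    """

    min_first_rrt_s: float = 15.0
    max_fast_subsequent_s: float = 2.0
    missing_time_fails: bool = True
    survey_year: int = 2021
    #: education level -> (min plausible age, max plausible age)
    education_age_rules: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "in_school": (0, 30),
            "primary": (6, 120),
            "secondary": (14, 120),
            "vocational": (16, 120),
            "bachelor": (18, 120),
            "master": (21, 120),
            "doctorate": (24, 120),
        }
    )
    rrt_questions: tuple[str, ...] = RRT_QUESTIONS


def _asked(row: pd.Series, q: str) -> bool:
    ans = row.get(f"{q}_answer")
    t = row.get(f"{q}_time_s")
    return (isinstance(ans, str) and ans in ("yes", "no")) or pd.notna(t)


def quality_filter(
    records: pd.DataFrame, rules: Optional[QCConfig] = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop untrustworthy records; return (kept, audit log).

    Drops records with implausible birth-year/education combinations, a
    first-RRT response time under the minimum, or any subsequent RRT time
    at or below the fast threshold.  Every drop is logged with its
    triggering rule; kept + dropped always partitions the input.
    """
    rules = rules or QCConfig()
    keep = np.ones(len(records), dtype=bool)
    audit: list[dict] = []
    asked_qs = [
        q
        for q in rules.rrt_questions
        if f"{q}_answer" in records.columns or f"{q}_time_s" in records.columns
    ]
    for pos, (_, row) in enumerate(records.iterrows()):
        reasons = []
        edu = row.get("education")
        by = row.get("birth_year")
        if edu in rules.education_age_rules and pd.notna(by):
            lo, hi = rules.education_age_rules[edu]
            age = rules.survey_year - int(by)
            if not lo <= age <= hi:
                reasons.append("implausible_demographics")
        presented = [q for q in asked_qs if _asked(row, q)]
        if presented:
            first, rest = presented[0], presented[1:]
            t0 = row.get(f"{first}_time_s")
            if pd.isna(t0):
                if rules.missing_time_fails:
                    reasons.append("missing_response_time")
            elif t0 < rules.min_first_rrt_s:
                reasons.append("first_rrt_under_15s")
            for q in rest:
                t = row.get(f"{q}_time_s")
                if pd.isna(t):
                    if rules.missing_time_fails:
                        reasons.append("missing_response_time")
                elif t <= rules.max_fast_subsequent_s:
                    reasons.append("subsequent_rrt_2s_or_less")
        if reasons:
            keep[pos] = False
            audit.append({"id": row.get("id"), "rules": reasons})
    return records[keep].copy(), audit


def select_doper_record(answers: Sequence[str], rng: np.random.Generator) -> int:
    """Pick the index of the record representing the respondent as a person.

    With one "yes" and one "no", the "yes" record is taken (a person who
    doped in any sport is a doper); equal answers are broken by a seeded
    uniform draw.  Returns the index into ``answers``.
    """
    answered = [i for i, a in enumerate(answers) if a in ("yes", "no")]
    if not answered:
        raise ValueError("no answered doping records for this individual")
    if len(answered) == 1:
        return answered[0]
    yes_idx = [i for i in answered if answers[i] == "yes"]
    if len(yes_idx) == 1:
        return yes_idx[0]
    return int(rng.choice(answered))


_DEMOG_COLS = ["id", "subsample", "country", "gender", "age_class"]


def doping_records(
    records: pd.DataFrame, cmap: Optional[CategoryMap] = None
) -> pd.DataFrame:
    """Long table of per-sport doping answers ("prevalence of doping").

    One row per answered doping question (up to two per respondent), with
    the sport, its category and the answer under question id ``doping``.
    """
    cmap = cmap or CategoryMap()
    rows = []
    demog = [c for c in _DEMOG_COLS if c in records.columns]
    for j in (1, 2):
        acol, scol = f"doping_{j}_answer", f"doping_{j}_sport"
        if acol not in records.columns:
            continue
        sub = records[records[acol].isin(["yes", "no"])]
        part = sub[demog].copy()
        part["sport"] = sub[scol] if scol in sub.columns else None
        part["doping_answer"] = sub[acol]
        part["slot"] = j
        rows.append(part)
    if not rows:
        return pd.DataFrame(columns=demog + ["sport", "doping_answer", "slot", "category"])
    out = pd.concat(rows, ignore_index=True)
    out["category"] = [cmap.lookup(s) if pd.notna(s) else cmap.default for s in out["sport"]]
    return out


def doper_records(
    records: pd.DataFrame,
    cmap: Optional[CategoryMap] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """One record per individual ("prevalence of dopers"), yes-preferred.

    Respondents with two answered doping records contribute the "yes" one
    if the answers differ, a seeded random one if they agree; respondents
    with no answered doping record are excluded and logged.
    """
    cmap = cmap or CategoryMap()
    rng = np.random.default_rng(seed)
    demog = [c for c in _DEMOG_COLS if c in records.columns]
    rows, excluded = [], []
    for _, row in records.iterrows():
        answers = [row.get(f"doping_{j}_answer") for j in (1, 2)]
        try:
            pick = select_doper_record(answers, rng)
        except ValueError:
            excluded.append({"id": row.get("id"), "reason": "no_answered_doping_record"})
            continue
        j = pick + 1
        rec = {c: row.get(c) for c in demog}
        rec["sport"] = row.get(f"doping_{j}_sport")
        rec["doper_answer"] = answers[pick]
        rec["category"] = (
            cmap.lookup(rec["sport"]) if pd.notna(rec["sport"]) else cmap.default
        )
        rows.append(rec)
    cols = demog + ["sport", "doper_answer", "category"]
    return pd.DataFrame(rows, columns=cols), excluded
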