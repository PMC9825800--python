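"""Synthetic survey generator emulating the deposited-data structure.

Generates respondent tables with the statistical structure the analysis
assumes: two randomisation subsamples, five-digit uniform random numbers,
demographics drawn from configurable country x gender x age margins, up to
four sports with competition level and years played, forced-response
answers produced by the latent-class forward model (honest-yes / honest-no
/ INC per question), response times, and an injectable fraction of
quality-control violators.  Latent labels are kept in a sidecar table so
tests can verify recoveries without the pipeline ever reading them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .design import RRTDesign, STUDY_DESIGN, assign_question
from .records import COMPETITION_LEVELS, DEFAULT_CATEGORY_MAP, SportEntry, prioritize_sports

__all__ = [
    "SimulationConfig",
    "SyntheticSurvey",
    "generate_random_numbers",
    "generate_survey",
    "scenario_presets",
    "simulate_question_answers",
    "study_margins",
]

# Observed survey composition used as the default demographic generator:
# country x gender respondent counts and the age-class marginal.
_COUNTRY_GENDER_COUNTS = {
    # country: (female, male)
    "DK": (651, 1846),
    "UK": (84, 138),
    "ESP": (365, 717),
    "GER": (233, 187),
    "GR/CY": (157, 187),
    "IT": (213, 338),
    "NO": (81, 264),
    "Other": (83, 145),
}
_AGE_COUNTS = {
    "15-24": 2129,
    "25-34": 1226,
    "35-44": 994,
    "45-54": 809,
    "55-64": 405,
    "65-74": 129,
    "75-84": 19,
}
_AGE_BOUNDS = {a: tuple(int(x) for x in a.split("-")) for a in _AGE_COUNTS}

#: distribution of the number of sports played (1-4)
_N_SPORTS_COUNTS = np.array([3404, 1478, 561, 323], dtype=float)

#: competition-level distribution; most recreational athletes do not compete
_LEVEL_PROBS = {"none": 0.60, "local": 0.20, "regional": 0.10, "national": 0.07, "international": 0.03}

_SPORT_POPULARITY = {
    "jogging/running": 20,
    "cycling": 16,
    "swimming": 12,
    "fitness": 12,
    "football": 10,
    "tennis": 4,
    "volleyball": 3,
    "basketball": 3,
    "handball": 2,
    "gymnastics": 3,
    "dance": 4,
    "figure skating": 1,
    "judo": 1,
    "karate": 1,
    "boxing": 1,
    "wrestling": 1,
    "athletics": 4,
    "rowing": 2,
}

_EDU_MIN_AGE = {
    "in_school": 0,
    "secondary": 14,
    "vocational": 16,
    "bachelor": 18,
    "master": 21,
    "doctorate": 24,
}


def study_margins() -> pd.DataFrame:
    """Joint country x gender x age cell counts mirroring the survey's
    composition (product of the country-gender table and the age marginal)."""
    age_total = sum(_AGE_COUNTS.values())
    rows = []
    for country, (f, m) in _COUNTRY_GENDER_COUNTS.items():
        for gender, cnt in (("female", f), ("male", m)):
            for age, acnt in _AGE_COUNTS.items():
                rows.append(
                    {
                        "country": country,
                        "gender": gender,
                        "age_class": age,
                        "count": cnt * acnt / age_total,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic survey.

    ``question_shares`` holds the true (honest-yes, honest-no, INC) triple
    per question; ``doping`` applies per sport record, optionally overridden
    per sport category via ``doping_shares_by_category``.
    """

    n_respondents: int = 5700
    split_fraction: float = 0.5
    design: RRTDesign = STUDY_DESIGN
    question_shares: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "otc": (0.104, 0.696, 0.20),
            "medication": (0.44, 0.19, 0.37),
            "image": (0.03, 0.50, 0.47),
            "doping": (0.016, 0.904, 0.08),
        }
    )
    doping_shares_by_category: Optional[dict[str, tuple[float, float, float]]] = None
    #: probability that a question's INC draw reuses the respondent-level draw
    inc_correlation: float = 0.0
    nonresponse_rate: float = 0.02
    contamination_fast: float = 0.01
    contamination_implausible: float = 0.005
    #: median / log-sd of compliant response times (seconds)
    first_rrt_time: tuple[float, float] = (30.0, 0.5)
    later_rrt_time: tuple[float, float] = (10.0, 0.6)
    seed: int = 0
    target_question: str = "otc"

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise ValueError("need at least two respondents")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")
        for q, t in self.question_shares.items():
            _check_simplex(q, t)
        for q, t in (self.doping_shares_by_category or {}).items():
            _check_simplex(q, t)

    @property
    def target_shares(self) -> tuple[float, float, float]:
        q = self.target_question
        return self.question_shares["doping" if q.startswith("dop") else q]


def _check_simplex(name, triple) -> None:
    if len(triple) != 3 or any(s < 0 or s > 1 for s in triple):
        raise ValueError(f"{name}: shares must lie in [0, 1]")
    if abs(sum(triple) - 1.0) > 1e-9:
        raise ValueError(f"{name}: shares must sum to 1, got {sum(triple)}")


@dataclass
class SyntheticSurvey:
    """Observable respondent table plus latent ground truth (sidecar only)."""

    respondents: pd.DataFrame
    truth: pd.DataFrame


def generate_random_numbers(n: int, seed=0) -> list[str]:
    """n five-digit random numbers, each digit i.i.d. uniform on 0-9."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    digits = rng.integers(0, 10, size=(n, 5))
    return ["".join(map(str, row)) for row in digits]


def simulate_question_answers(
    n1: int,
    n2: int,
    shares: tuple[float, float, float],
    design: RRTDesign = STUDY_DESIGN,
    rng: Optional[np.random.Generator] = None,
):
    """Fast forward-model draw of per-respondent answers for one question.

    Returns ``(yes, subsample)`` arrays of length ``n1 + n2``.  Latent
    class and digit draws are explicit so the marginal yes-probability is
    exactly the model's lambda_g.
    """
    rng = rng or np.random.default_rng()
    _check_simplex("shares", shares)
    ty, tn, ti = shares
    sub = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    cls = rng.choice(3, size=n1 + n2, p=[ty, tn, ti])  # 0 hy, 1 hn, 2 inc
    digit = rng.integers(0, 10, size=n1 + n2)
    yes = np.zeros(n1 + n2, dtype=float)
    for g in (1, 2):
        rule = design.digit_rules[g]
        in_g = sub == g
        forced_yes = np.isin(digit, list(rule["digits_yes"]))
        forced_no = np.isin(digit, list(rule["digits_no"]))
        sensitive = ~forced_yes & ~forced_no
        yes[in_g] = np.where(
            cls[in_g] == 2,
            0.0,
            np.where(
                forced_yes[in_g],
                1.0,
                np.where(forced_no[in_g], 0.0, (cls[in_g] == 0) & sensitive[in_g]),
            ),
        )
    return yes, sub


def _draw_class(rng, n, shares, shared_u=None, rho=0.0):
    ty, tn, ti = shares
    u = rng.random(n)
    if shared_u is not None and rho > 0:
        use_shared = rng.random(n) < rho
        u = np.where(use_shared, shared_u, u)
    # INC first (so the correlation knob acts on the INC margin), then the
    # trait among compliant respondents
    inc = u < ti
    carrier = rng.random(n) < (ty / (ty + tn) if ty + tn > 0 else 0.0)
    cls = np.where(inc, 2, np.where(carrier, 0, 1))
    return cls


def _answer_from_class(cls, digit, sub, design):
    out = np.empty(len(cls), dtype=object)
    for i in range(len(cls)):
        if cls[i] == 2:
            out[i] = "no"
            continue
        kind = assign_question(int(digit[i]), int(sub[i]), design)
        if kind == "forced_yes":
            out[i] = "yes"
        elif kind == "forced_no":
            out[i] = "no"
        else:
            out[i] = "yes" if cls[i] == 0 else "no"
    return out


def generate_survey(config: SimulationConfig) -> SyntheticSurvey:
    """Draw a full synthetic survey under the forward model.

    Respondents get demographics from the configured margins, 1-4 sports
    with levels and years, a randomisation subsample, per-question random
    numbers and answers, response times, and (at configured rates)
    injected quality-control violations with ground-truth flags.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    margins = study_margins()
    cell_p = margins["count"] / margins["count"].sum()
    cell_idx = rng.choice(len(margins), size=n, p=cell_p.to_numpy())
    country = margins["country"].to_numpy()[cell_idx]
    gender = margins["gender"].to_numpy()[cell_idx]
    age_class = margins["age_class"].to_numpy()[cell_idx]
    age = np.array(
        [rng.integers(_AGE_BOUNDS[a][0], _AGE_BOUNDS[a][1] + 1) for a in age_class]
    )
    birth_year = 2021 - age
    education = np.array(
        [
            rng.choice([e for e, mn in _EDU_MIN_AGE.items() if mn <= a and not (e == "in_school" and a > 30)])
            for a in age
        ]
    )
    subsample = np.where(rng.random(n) < config.split_fraction, 1, 2)

    sports_names = list(_SPORT_POPULARITY)
    pop = np.array(list(_SPORT_POPULARITY.values()), dtype=float)
    pop /= pop.sum()
    n_sports = rng.choice([1, 2, 3, 4], size=n, p=_N_SPORTS_COUNTS / _N_SPORTS_COUNTS.sum())
    levels = list(_LEVEL_PROBS)
    level_p = np.array(list(_LEVEL_PROBS.values()))

    rows: list[dict] = []
    truth_rows: list[dict] = []
    shared_u = rng.random(n)
    rho = config.inc_correlation

    questions = ["otc", "medication", "image"]
    q_shares = {q: config.question_shares[q] for q in questions}

    for i in range(n):
        rid = i + 1
        rec: dict = {
            "id": rid,
            "birth_year": int(birth_year[i]),
            "education": education[i],
            "country": country[i],
            "gender": gender[i],
            "age_class": age_class[i],
            "subsample": int(subsample[i]),
        }
        k = int(n_sports[i])
        chosen = rng.choice(len(sports_names), size=k, replace=False, p=pop)
        entries = []
        for j, s in enumerate(chosen, start=1):
            name = sports_names[s]
            lvl = levels[int(rng.choice(len(levels), p=level_p))]
            yrs = float(np.round(rng.gamma(2.0, 4.0), 1))
            rec[f"sport{j}_name"] = name
            rec[f"sport{j}_level"] = lvl
            rec[f"sport{j}_years"] = yrs
            entries.append(SportEntry(name=name, level=lvl, years=yrs))
        for j in range(k + 1, 5):
            rec[f"sport{j}_name"] = None
            rec[f"sport{j}_level"] = None
            rec[f"sport{j}_years"] = None
        top2 = prioritize_sports(entries)

        asked = [(q, q_shares[q], None) for q in ("otc", "medication")]
        for j, entry in enumerate(top2, start=1):
            cat = DEFAULT_CATEGORY_MAP.get(entry.name, "Other")
            shares = (config.doping_shares_by_category or {}).get(
                cat, config.question_shares["doping"]
            )
            asked.append((f"doping_{j}", shares, entry.name))
        asked.append(("image", q_shares["image"], None))
        if len(top2) < 2:
            rec["doping_2_answer"] = None
            rec["doping_2_time_s"] = None
            rec["doping_2_sport"] = None
            rec["doping_2_random"] = None

        for pos, (q, shares, sport) in enumerate(asked):
            digits = rng.integers(0, 10, size=5)
            rec[f"{q}_random"] = "".join(map(str, digits))
            cls = _draw_class(rng, 1, shares, shared_u[i : i + 1], rho)[0]
            ans = _answer_from_class([cls], [digits[-1]], [subsample[i]], config.design)[0]
            med, sd = config.first_rrt_time if pos == 0 else config.later_rrt_time
            t = float(np.round(np.exp(np.log(med) + sd * rng.standard_normal()), 1))
            if pos == 0:
                t = max(t, 15.1)
            else:
                t = max(t, 2.2)
            if rng.random() < config.nonresponse_rate:
                ans = None
            rec[f"{q}_answer"] = ans
            rec[f"{q}_time_s"] = t
            if sport is not None:
                rec[f"{q}_sport"] = sport
            truth_rows.append(
                {
                    "id": rid,
                    "question": q,
                    "latent_class": ("honest_yes", "honest_no", "inc")[cls],
                    "qc_violation": "",
                }
            )
        rows.append(rec)

    df = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)

    # inject QC violators: hasty answers and implausible demographics
    n_fast = int(round(config.contamination_fast * n))
    n_impl = int(round(config.contamination_implausible * n))
    viol = rng.choice(n, size=min(n, n_fast + n_impl), replace=False)
    fast_ids, impl_ids = viol[:n_fast], viol[n_fast : n_fast + n_impl]
    for i in fast_ids:
        if rng.random() < 0.5:
            df.loc[i, "otc_time_s"] = float(np.round(rng.uniform(1.0, 14.9), 1))
        else:
            df.loc[i, "medication_time_s"] = float(np.round(rng.uniform(0.2, 2.0), 1))
        truth.loc[truth["id"] == df.loc[i, "id"], "qc_violation"] = "fast_timing"
    for i in impl_ids:
        df.loc[i, "birth_year"] = 2021 - 17
        df.loc[i, "education"] = "doctorate"
        truth.loc[truth["id"] == df.loc[i, "id"], "qc_violation"] = "implausible_demographics"

    return SyntheticSurvey(respondents=df, truth=truth)


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named configurations whose true shares equal the study's estimated
    regimes, for end-to-end recovery tests.

    Where only (honest-yes, INC) are reported, honest-no is the simplex
    complement; for Games the INC share is not reported separately and is
    set between the overall (8%) and male (12%) doping-question rates.
    """
    base = SimulationConfig()

    def cfg(target, q, triple, **kw):
        qs = dict(base.question_shares)
        qs["doping" if q.startswith("dop") else q] = triple
        return replace(base, question_shares=qs, target_question=target, **kw)

    return {
        "otc": cfg("otc", "otc", (0.104, 0.696, 0.20)),
        "medication_other": cfg("medication", "medication", (0.44, 0.19, 0.37)),
        "dopers_overall": cfg("doping", "doping", (0.004, 0.916, 0.08)),
        "dopers_male": cfg("doping", "doping", (0.031, 0.849, 0.12)),
        "doping_games": cfg("doping", "doping", (0.069, 0.831, 0.10)),
        "doping_overall": cfg("doping", "doping", (0.016, 0.904, 0.08)),
    }
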