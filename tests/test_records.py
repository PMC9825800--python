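import numpy as np
import pandas as pd
import pytest

from rrtprev.records import (
    CategoryMap,
    QCConfig,
    SportEntry,
    categorize_sport,
    doper_records,
    doping_records,
    prioritize_sports,
    quality_filter,
    select_doper_record,
)


def _base_record(**over):
    rec = {
        "id": 1,
        "birth_year": 1990,
        "education": "master",
        "otc_answer": "yes",
        "otc_time_s": 30.0,
        "medication_answer": "no",
        "medication_time_s": 10.0,
    }
    rec.update(over)
    return rec


@pytest.mark.parametrize(
    "over, kept, rule",
    [
        ({"otc_time_s": 14.9}, False, "first_rrt_under_15s"),
        ({"otc_time_s": 15.0}, True, None),
        ({"medication_time_s": 2.0}, False, "subsequent_rrt_2s_or_less"),
        ({"medication_time_s": 2.1}, True, None),
        ({"birth_year": 1929, "education": "in_school"}, False, "implausible_demographics"),
        ({"birth_year": 2004, "education": "doctorate"}, False, "implausible_demographics"),
        ({"birth_year": 1990, "education": "doctorate"}, True, None),
    ],
)
def test_quality_filter_boundaries(over, kept, rule):
    df = pd.DataFrame([_base_record(**over)])
    out, audit = quality_filter(df, QCConfig())
    assert (len(out) == 1) is kept
    if not kept:
        assert rule in audit[0]["rules"]


def test_quality_filter_missing_time_policy():
    df = pd.DataFrame([_base_record(medication_time_s=None)])
    out, _ = quality_filter(df, QCConfig(missing_time_fails=True))
    assert len(out) == 0
    out, _ = quality_filter(df, QCConfig(missing_time_fails=False))
    assert len(out) == 1


def test_quality_filter_skips_questions_not_presented():
    rec = _base_record()
    rec["doping_1_answer"] = None
    rec["doping_1_time_s"] = None  # question never asked: no timing rule applies
    out, audit = quality_filter(pd.DataFrame([rec]))
    assert len(out) == 1 and audit == []


def test_quality_filter_bookkeeping_and_order_independence():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(40):
        rows.append(
            _base_record(
                id=i,
                otc_time_s=float(rng.uniform(5, 60)),
                medication_time_s=float(rng.uniform(0.5, 20)),
            )
        )
    df = pd.DataFrame(rows)
    kept, audit = quality_filter(df)
    assert len(kept) + len(audit) == len(df)
    perm = df.sample(frac=1.0, random_state=1)
    kept_p, audit_p = quality_filter(perm)
    assert set(kept_p["id"]) == set(kept["id"])
    assert {a["id"] for a in audit_p} == {a["id"] for a in audit}


def test_prioritize_sports_level_then_years():
    a = SportEntry("athletics", "national", 3)
    b = SportEntry("boxing", "local", 10)
    c = SportEntry("cycling", "none", 20)
    assert [e.name for e in prioritize_sports([a, b, c])] == ["athletics", "boxing"]
    # second-order tie-break on years
    x = SportEntry("tennis", "local", 2)
    y = SportEntry("judo", "local", 5)
    assert [e.name for e in prioritize_sports([x, y])] == ["judo", "tennis"]
    assert prioritize_sports([c]) == [c]
    with pytest.raises(ValueError):
        prioritize_sports([])


def test_select_doper_record_yes_preferred():
    rng = np.random.default_rng(0)
    assert select_doper_record(["yes", "no"], rng) == 0
    assert select_doper_record(["no", "yes"], rng) == 1
    assert select_doper_record(["no", None], rng) == 0
    with pytest.raises(ValueError):
        select_doper_record([None, None], rng)
    # equal answers: deterministic given the generator state
    picks = [select_doper_record(["yes", "yes"], np.random.default_rng(5)) for _ in range(3)]
    assert len(set(picks)) == 1


def test_yes_preference_never_loses_yes_records():
    """Selection can only keep or raise the yes-count vs random choice."""
    rng = np.random.default_rng(1)
    pairs = [["yes", "no"], ["no", "yes"], ["no", "no"], ["yes", "yes"]] * 25
    picked_yes = sum(p[select_doper_record(p, rng)] == "yes" for p in pairs)
    random_yes = sum(p[rng.integers(0, 2)] == "yes" for p in pairs)
    assert picked_yes >= random_yes
    assert picked_yes == 75  # every mixed or yes/yes pair yields a yes


@pytest.mark.parametrize(
    "name, category",
    [("cycling", "CGS"), ("volleyball", "Games"), ("  Cycling ", "CGS"),
     ("underwater hockey", "Other"), ("judo", "Combat"), ("dance", "Artistic")],
)
def test_categorize_sport(name, category):
    assert categorize_sport(name) == category


def test_doping_and_doper_frames():
    df = pd.DataFrame(
        [
            {
                "id": 1, "subsample": 1, "country": "DK", "gender": "female",
                "age_class": "15-24",
                "doping_1_answer": "yes", "doping_1_sport": "cycling",
                "doping_2_answer": "no", "doping_2_sport": "gymnastics",
            },
            {
                "id": 2, "subsample": 2, "country": "NO", "gender": "male",
                "age_class": "25-34",
                "doping_1_answer": "no", "doping_1_sport": "tennis",
                "doping_2_answer": None, "doping_2_sport": None,
            },
            {
                "id": 3, "subsample": 1, "country": "NO", "gender": "male",
                "age_class": "25-34",
                "doping_1_answer": None, "doping_1_sport": "boxing",
                "doping_2_answer": None, "doping_2_sport": None,
            },
        ]
    )
    long = doping_records(df)
    assert len(long) == 3  # respondent 1 twice, respondent 2 once
    assert set(long["category"]) == {"CGS", "Artistic", "Games"}

    dop, excluded = doper_records(df, seed=0)
    # the cycling "yes" wins over the gymnastics "no" for respondent 1
    assert dop.set_index("id").loc[1, "sport"] == "cycling"
    assert dop.set_index("id").loc[1, "doper_answer"] == "yes"
    assert len(dop) == 2
    assert excluded == [{"id": 3, "reason": "no_answered_doping_record"}]


def test_category_map_csv_roundtrip(tmp_path):
    p = tmp_path / "map.csv"
    pd.DataFrame({"sport": ["Quidditch"], "category": ["Games"]}).to_csv(p, index=False)
    cmap = CategoryMap.from_csv(p)
    assert cmap.lookup("quidditch") == "Games"
    assert cmap.lookup("curling") == "Other"
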