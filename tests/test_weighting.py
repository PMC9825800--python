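import numpy as np
import pandas as pd
import pytest

from rrtprev.weighting import (
    PopulationMargins,
    PostStratificationWeighter,
    compute_weights,
    rake_weights,
    weighted_category_distribution,
)


def _margins(rows):
    df = pd.DataFrame(rows, columns=["country", "gender", "age_class", "share"])
    return PopulationMargins(df)


def _resp(cells, question="q", answer="yes"):
    df = pd.DataFrame(cells, columns=["country", "gender", "age_class"])
    df.insert(0, "id", range(1, len(df) + 1))
    df[f"{question}_answer"] = answer
    return df


TWO_CELLS = _margins(
    [("DK", "female", "15-24", 0.5), ("DK", "male", "15-24", 0.5)]
)


def test_ratio_weighting_two_cells():
    # sample shares (0.75, 0.25) against population (0.5, 0.5)
    resp = _resp([("DK", "female", "15-24")] * 3 + [("DK", "male", "15-24")])
    wt = compute_weights(resp, "q", TWO_CELLS, normalize=False)
    assert wt["weight"].to_numpy() == pytest.approx([2 / 3, 2 / 3, 2 / 3, 2.0])
    assert (wt["cell_level"] == "full").all()


def test_matched_sample_gets_unit_weights():
    resp = _resp([("DK", "female", "15-24")] * 2 + [("DK", "male", "15-24")] * 2)
    wt = compute_weights(resp, "q", TWO_CELLS)
    assert wt["weight"].to_numpy() == pytest.approx(np.ones(4))


def test_weights_restricted_to_question_responders():
    resp = _resp([("DK", "female", "15-24")] * 2 + [("DK", "male", "15-24")] * 2)
    resp.loc[0, "q_answer"] = None
    wt = compute_weights(resp, "q", TWO_CELLS)
    assert len(wt) == 3
    assert 1 not in wt["id"].to_numpy()


def test_empty_population_cell_collapses_and_conserves_margins():
    margins = _margins(
        [
            ("DK", "female", "15-24", 0.25),
            ("DK", "female", "25-34", 0.25),
            ("DK", "male", "15-24", 0.5),
        ]
    )
    # no sampled female 25-34: (DK, female) collapses to the gender pair
    resp = _resp([("DK", "female", "15-24")] * 4 + [("DK", "male", "15-24")] * 4)
    wt = compute_weights(resp, "q", margins, normalize=False)
    female = wt[resp["gender"] == "female"]
    assert (female["cell_level"] == "country_gender").all()
    # post-collapse weighted shares match the collapsed population margins
    total = wt["weight"].sum()
    assert female["weight"].sum() / total == pytest.approx(0.5)
    male = wt[resp["gender"] == "male"]
    assert (male["cell_level"] == "full").all()
    assert male["weight"].sum() / total == pytest.approx(0.5)


def test_conservation_on_full_cells():
    rng = np.random.default_rng(2)
    countries = ["DK", "NO"]
    genders = ["female", "male"]
    ages = ["15-24", "25-34"]
    cells = [(c, g, a) for c in countries for g in genders for a in ages]
    pop = rng.dirichlet(np.ones(len(cells)))
    margins = _margins([(*cell, p) for cell, p in zip(cells, pop)])
    draws = rng.choice(len(cells), size=400, p=np.full(len(cells), 1 / len(cells)))
    resp = _resp([cells[i] for i in draws])
    wt = compute_weights(resp, "q", margins)
    shares = wt.groupby([resp["country"], resp["gender"], resp["age_class"]])["weight"].sum()
    shares = shares / wt["weight"].sum()
    for cell, p in zip(cells, pop):
        assert shares[cell] == pytest.approx(p, abs=1e-6)


def test_gender_without_population_margin_is_flagged_unit_weight():
    resp = _resp(
        [("DK", "female", "15-24")] * 2
        + [("DK", "male", "15-24")] * 2
        + [("DK", "non-binary", "15-24")]
    )
    wt = compute_weights(resp, "q", TWO_CELLS, normalize=False)
    nb = wt[resp["gender"] == "non-binary"]
    assert (nb["cell_level"] == "unmatched").all()
    assert nb["weight"].to_numpy() == pytest.approx([1.0])


def test_weighted_category_distribution_raw_and_weighted():
    raw = {"Artistic": 1197, "Combat": 234, "Games": 2431, "CGS": 5106, "Other": 361}
    records = pd.DataFrame(
        {"category": np.repeat(list(raw), list(raw.values()))}
    )
    shares = weighted_category_distribution(records)
    total = sum(raw.values())
    for cat, n in raw.items():
        assert shares[cat] == pytest.approx(100 * n / total)
    assert shares.sum() == pytest.approx(100.0)

    single = pd.DataFrame({"category": ["Games"] * 5})
    assert weighted_category_distribution(single)["Games"] == pytest.approx(100.0)

    rec = pd.DataFrame({"category": ["Games", "CGS"], "weight": [1.0, 3.0]})
    shares = weighted_category_distribution(rec)
    assert shares["CGS"] == pytest.approx(75.0)


def test_raking_matches_marginals():
    margins = _margins(
        [
            ("DK", "female", "15-24", 0.2),
            ("DK", "male", "25-34", 0.3),
            ("NO", "female", "25-34", 0.3),
            ("NO", "male", "15-24", 0.2),
        ]
    )
    rng = np.random.default_rng(4)
    cells = [("DK", "female", "15-24"), ("DK", "male", "25-34"),
             ("NO", "female", "25-34"), ("NO", "male", "15-24")]
    resp = _resp([cells[i] for i in rng.choice(4, size=300)])
    wt = rake_weights(resp, "q", margins)
    w = wt["weight"].to_numpy()
    for dim, target in (("country", {"DK": 0.5, "NO": 0.5}),
                        ("gender", {"female": 0.5, "male": 0.5})):
        got = pd.Series(w).groupby(resp[dim].to_numpy()).sum() / w.sum()
        for k, v in target.items():
            assert got[k] == pytest.approx(v, abs=1e-8)


def test_transformer_attaches_weights():
    resp = _resp([("DK", "female", "15-24")] * 3 + [("DK", "male", "15-24")])
    tf = PostStratificationWeighter(margins=TWO_CELLS, question="q").fit(resp)
    out = tf.transform(resp)
    assert "weight" in out.columns
    assert len(out) == 4
    with pytest.raises(ValueError, match="method"):
        PostStratificationWeighter(margins=TWO_CELLS, method="bogus").fit(resp)


def test_margins_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        _margins([("DK", "female", "15-24", 0.4)])
    with pytest.raises(ValueError, match="non-negative"):
        _margins([("DK", "female", "15-24", 1.5), ("DK", "male", "15-24", -0.5)])
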