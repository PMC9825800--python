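import numpy as np
import pandas as pd
import pytest

from rrtprev import STUDY_DESIGN
from rrtprev.simulate import SimulationConfig, generate_survey, scenario_presets


@pytest.fixture(scope="session")
def design():
    return STUDY_DESIGN


@pytest.fixture(scope="session")
def small_survey():
    """A 1200-respondent synthetic survey shared across tests."""
    from dataclasses import replace

    cfg = replace(scenario_presets()["doping_overall"], n_respondents=1200, seed=17)
    return generate_survey(cfg)


def make_records(n1, n2, y1, y2, weights=None):
    """Minimal respondent frame with prescribed yes-counts per subsample."""
    sub = [1] * n1 + [2] * n2
    ans = (["yes"] * y1 + ["no"] * (n1 - y1)) + (["yes"] * y2 + ["no"] * (n2 - y2))
    df = pd.DataFrame({"id": range(1, n1 + n2 + 1), "subsample": sub, "q_answer": ans})
    if weights is not None:
        df["weight"] = weights
    return df
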