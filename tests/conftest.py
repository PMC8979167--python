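import pandas as pd
import pytest

import phenoconcord as pc


@pytest.fixture(scope="session")
def lexicon():
    return pc.load_packaged_lexicon()


@pytest.fixture(scope="session")
def hierarchy():
    return pc.load_packaged_hierarchy()


@pytest.fixture(scope="session")
def trait_counts():
    return pc.load_survey1_trait_counts()


def make_survey(survey_id, rows):
    """rows: iterable of (rater, specimen, term)."""
    return pc.SurveyTable(
        survey_id, pd.DataFrame(rows, columns=["rater", "specimen", "term"])
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest but fully exercised simulation shared across tests."""
    return pc.generate(pc.SimConfig(n_raters=6, n_specimens=12, seed=11))


@pytest.fixture(scope="session")
def small_sim_analysis(small_sim):
    s = small_sim
    return pc.run_analysis(s.survey1, s.survey2, s.lexicon, s.hierarchy)
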