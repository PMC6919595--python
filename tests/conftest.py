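import numpy as np
import pandas as pd
import pytest

from careimpact import load_registry, sample_ground_truth
from careimpact.linking import FacilitySurvey, SurveyPair, UtilizationProfile
from careimpact.registry import by_id
from careimpact.synth import generate_facility_survey, generate_household_survey


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def registry_map(registry):
    return by_id(registry)


@pytest.fixture(scope="session")
def truth(registry):
    """One reproducible synthetic country ground truth."""
    rng = np.random.default_rng(20160101)
    return sample_ground_truth("TST", rng, registry=registry)


@pytest.fixture(scope="session")
def spa_pair(truth, registry):
    """A linked SPA facility survey + household survey for `truth`."""
    survey = generate_facility_survey(
        truth, 2000, "SPA", seed=11, survey_year=2014.0, registry=registry
    )
    profile = generate_household_survey(truth, seed=12, survey_year=2014.0)
    return SurveyPair(survey, profile, 2014.0, 2014.0)


def make_facility_frame(rows, components):
    """Hand-build a facility records frame. `rows` are dicts with
    facility_id/stratum/weight plus per-component 0/1 entries; components
    missing from a row default to present."""
    data = []
    for i, row in enumerate(rows):
        rec = {
            "facility_id": row.get("facility_id", f"F{i:03d}"),
            "stratum": row.get("stratum", "hospital"),
            "weight": row.get("weight", 1.0),
        }
        for c in components:
            rec[c] = int(row.get(c, 1))
        data.append(rec)
    return pd.DataFrame(data)


@pytest.fixture()
def uniform_profile():
    return UtilizationProfile(
        country_id="U",
        anc4_plus=0.60,
        hfd=0.66,
        stratum_shares={"hospital": 1.0},
        survey_year=2014.0,
    )
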