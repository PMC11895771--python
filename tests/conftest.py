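import pandas as pd
import pytest

from jemkit import JEM, JEMCell, OccupationCode, ScenarioConfig, load_registry

SYSTEM = "SYNTH-A"


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def exposure_ids(registry):
    return [d.exposure_id for d in registry]


def make_cell(code, gender, exposure_id, prevalence=None, category=None,
              n=None, system=SYSTEM, reliable=True):
    return JEMCell(
        occupation=OccupationCode(code, system), gender=gender,
        exposure_id=exposure_id, prevalence_pct=prevalence,
        category=category, n_respondents=n, reliable=reliable,
    )


@pytest.fixture
def tiny_jem():
    """Five occupations x one exposure x both genders, hand-chosen bands."""
    cells = []
    # (code, prevalence M, prevalence F); note the leading-zero code
    spec = [("0110", 2.0, 4.0), ("2110", 10.0, 20.0), ("5120", 30.0, 55.0),
            ("7210", 60.0, 40.0), ("9310", 80.0, 90.0)]
    for code, pm, pf in spec:
        for gender, p in (("M", pm), ("F", pf)):
            cells.append(make_cell(code, gender, "heavy_lifting",
                                   prevalence=p, n=100))
    return JEM("tiny", SYSTEM, cells)


@pytest.fixture
def small_config():
    return ScenarioConfig(seed=11, n_occupations=20, survey_n_per_cell=60,
                          cohort_n=4000)


@pytest.fixture
def tiny_population():
    """Ten people per occupation and gender of the tiny matrix."""
    rows = []
    for code in ("0110", "2110", "5120", "7210", "9310"):
        for gender in ("M", "F"):
            for i in range(10):
                rows.append({"person_id": f"{code}{gender}{i}",
                             "occupation_code": code, "gender": gender,
                             "age": 40.0})
    return pd.DataFrame(rows)
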