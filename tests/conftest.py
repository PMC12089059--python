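import numpy as np
import pandas as pd
import pytest

import pvsignal as pv


@pytest.fixture(scope="session")
def table2_cohort():
    """Deterministic cohort with the printed general-characteristics counts."""
    return pv.table2_fixture_cohort()


@pytest.fixture()
def toy_raw():
    """A tiny hand-built quarter: 4 cases, one consumer report, one SS-only
    amlodipine mention, assorted name variants."""
    demo = pd.DataFrame(
        {
            "case_id": ["A1", "A2", "A3", "A4"],
            "version_id": [1, 1, 1, 1],
            "event_date": ["20200101", "20200102", "20200103", "20200104"],
            "sex": ["F", "M", "F", "M"],
            "age_value": [70.0, 40.0, np.nan, 55.0],
            "age_unit": ["YR", "YR", "", "YR"],
            "weight_kg": [60.0, 80.0, np.nan, 90.0],
            "country": ["US", "GB", "US", "FR"],
            "reporter_qualification": ["MD", "PH", "CN", "MD"],
        }
    )
    drug = pd.DataFrame(
        {
            "case_id": ["A1", "A2", "A2", "A3", "A4"],
            "drug_seq": [1, 1, 2, 1, 1],
            "verbatim_drug_name": [
                "NORVASC 5MG",
                "DRUG 07",
                "AMLODIPINE BESYLATE",
                "amlodipine",
                "NIMODIPINE",
            ],
            # A2: amlodipine only as secondary suspect
            "role_code": ["PS", "PS", "SS", "PS", "PS"],
        }
    )
    reac = pd.DataFrame(
        {
            "case_id": ["A1", "A1", "A2", "A3", "A4"],
            "preferred_term": [
                "Gingival hypertrophy",
                "Peripheral oedema",
                "Dizziness",
                "Headache",
                "Dizziness",
            ],
        }
    )
    return pv.RawTables(demo=demo, drug=drug, reac=reac)


@pytest.fixture()
def toy_cohort(toy_raw):
    raw = pv.normalize_drug_names(toy_raw, pv.amlodipine_synonyms())
    return pv.build_cohort(raw, "amlodipine", hcp_only=False, ps_only=True)


def random_tables(rng, n, low=1, high=500):
    """All-positive random 2x2 tables as an (n, 4) integer array."""
    return rng.integers(low, high, size=(n, 4))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250101)
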