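import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hearineq.cohort import AgeBandScheme
from hearineq.standardize import StandardPopulation

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fiveyear_scheme():
    return AgeBandScheme.fiveyear_50_85plus()


@pytest.fixture(scope="session")
def esp(fiveyear_scheme):
    return StandardPopulation.esp2013_for_scheme(fiveyear_scheme)


def make_records(rows):
    """Build a microdata frame from partial row dicts with sane defaults."""
    defaults = dict(
        person_id="P0", wave=1, country="SE", age=70.0, gender="man",
        education="medium", srhq=2.0, ha_use=False, weight=1.0,
    )
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, **row}
        rec["person_id"] = rec.get("person_id", f"P{i}")
        out.append(rec)
    df = pd.DataFrame(out)
    df["person_id"] = [f"P{i}" for i in range(len(df))]
    return df


@pytest.fixture
def records_factory():
    return make_records
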