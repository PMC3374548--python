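"""Shared fixtures: packaged tables, tiny handmade datasets, calibrated generators."""

from __future__ import annotations

import pandas as pd
import pytest

from awag import (
    AttributeSchema,
    GeneratorConfig,
    SegmentSpec,
    SurveyDataset,
    load_fixture,
    spec_from_rates,
)


@pytest.fixture(scope="session")
def dms_rows():
    return load_fixture("dms")


@pytest.fixture(scope="session")
def dhcs_rows():
    return load_fixture("dhcs")


@pytest.fixture(scope="session")
def profile_rows():
    return load_fixture("sample_profile")


def make_dataset(triples, service="svc", label="x") -> SurveyDataset:
    """Dataset with one single-category attribute and given stage triples."""
    frame = pd.DataFrame(
        {
            "respondent_id": [f"r{i}" for i in range(len(triples))],
            "weight": 1.0,
            "grp": label,
            f"{service}_aware": [t[0] for t in triples],
            f"{service}_want": [t[1] for t in triples],
            f"{service}_adopt": [t[2] for t in triples],
        }
    )
    schema = AttributeSchema(attributes=(("grp", (label,)),), services=(service,))
    return SurveyDataset(frame=frame, schema=schema, services=(service,))


@pytest.fixture
def four_records():
    """The canonical 4-respondent example: nested stage triples."""
    return make_dataset([(1, 1, 1), (1, 1, 0), (1, 0, 0), (0, 0, 0)])


def two_service_config(n_per_segment=1537, seed=0) -> GeneratorConfig:
    """Male/Female strata calibrated to the reference tables' gender rows,
    with both services drawn for the same respondents (established-service
    profile for dms, new-service profile for dhcs)."""

    def seg(label, a, w, d):
        s = spec_from_rates(a, w, d, n=n_per_segment, label={"gender": label})
        return s

    male_dms = seg("Male", 0.871, 0.777, 0.428)
    female_dms = seg("Female", 0.864, 0.779, 0.463)
    male_dhcs = seg("Male", 0.531, 0.695, 0.055)
    female_dhcs = seg("Female", 0.487, 0.697, 0.043)
    return GeneratorConfig(
        segments=(male_dms, female_dms),
        services={
            "dms": {},
            "dhcs": {"Male": male_dhcs, "Female": female_dhcs},
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def two_service_dataset():
    from awag import generate

    return generate(two_service_config(seed=11))
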