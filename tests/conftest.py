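import pandas as pd
import pytest

from econsult import (
    ActivityTimings,
    CategoryMix,
    CostParameters,
    EConsultCategory,
    NoteUseModel,
    derive_per_type_resources,
    expected_resource,
)

# Per-category staff minutes from the published time table, used as an
# independent enumeration oracle against the compositional derivation.
PUBLISHED_PER_TYPE = {
    EConsultCategory.ADMIN_OTHER_DETAILS: (4.50, 0.50),
    EConsultCategory.ADMIN_FIT_NOTE: (6.00, 4.00),
    EConsultCategory.GP_NO_ACTION: (4.50, 3.75),
    EConsultCategory.GP_PRESCRIPTION: (6.00, 4.75),
    EConsultCategory.OTHER_APPOINTMENT: (6.00, 4.25),
    EConsultCategory.GP_PHONE_BACK: (6.00, 3.75 + 5.0),
    EConsultCategory.GP_APPOINTMENT: (6.00, 3.75 + 10.0),
}


def oracle_expected(mix: CategoryMix) -> tuple[float, float]:
    """Enumeration oracle: weighted sums straight off the published table."""
    admin = sum(mix[c] * PUBLISHED_PER_TYPE[c][0] for c in EConsultCategory)
    gp = sum(mix[c] * PUBLISHED_PER_TYPE[c][1] for c in EConsultCategory)
    return admin, gp


@pytest.fixture
def timings():
    return ActivityTimings()


@pytest.fixture
def mix():
    return CategoryMix()


@pytest.fixture
def costs():
    return CostParameters()


@pytest.fixture
def expected_default(timings, mix):
    return expected_resource(derive_per_type_resources(timings, NoteUseModel()), mix)


@pytest.fixture
def tiny_log():
    """Hand-built event log: 10 visits, 3 submissions, known demographics."""
    rows = []
    for i in range(10):
        rows.append(("P1", f"2017-05-{i + 1:02d}", "site_visit", "unknown", "unknown", "unknown"))
    rows += [
        ("P1", "2017-05-02", "submission", "specific_condition", "female", "25-34"),
        ("P1", "2017-05-03", "submission", "administrative_help", "female", "45-54"),
        ("P1", "2017-05-07", "submission", "general_advice_new", "male", "65+"),
    ]
    return pd.DataFrame(
        rows, columns=["practice_id", "date", "kind", "category", "sex", "age_band"]
    )
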