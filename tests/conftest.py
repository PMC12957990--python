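import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wsas_audit import ItemId, RatingRecord, RatingsTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

@pytest.fixture
def six_respondents() -> RatingsTable:
    """Home + work ratings for the six-respondent worked example."""
    from wsas_audit.examples import six_respondents_table

    return six_respondents_table()


def make_complete_table(ratings: np.ndarray, seed_label: str = "test") -> RatingsTable:
    """Build a complete table from an (n, 5, 2) integer array."""
    n = ratings.shape[0]
    records = []
    for i in range(n):
        for j, item in enumerate(ItemId):
            records.append(
                RatingRecord(f"p{i + 1}", item, int(ratings[i, j, 0]), int(ratings[i, j, 1]))
            )
    return RatingsTable.from_records(records, provenance=seed_label)


@pytest.fixture
def random_complete_table() -> RatingsTable:
    rng = np.random.default_rng(42)
    return make_complete_table(rng.integers(0, 9, size=(12, 5, 2)))
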