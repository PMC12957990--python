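"""Built-in worked example: six hypothetical respondents.

Home and work ratings illustrating the patterns the audit detects: impaired
high with bothered low, both equal, and impaired low with bothered high.
Hypothetical data - they do not represent any specific individuals.
"""

from __future__ import annotations

from .model import ItemId, RatingRecord, RatingsTable

#: (impaired, bothered) pairs per respondent.
SIX_RESPONDENTS_HOME = [(6, 8), (8, 8), (4, 6), (3, 6), (6, 3), (5, 8)]
SIX_RESPONDENTS_WORK = [(5, 5), (2, 8), (4, 6), (4, 8), (2, 5), (5, 4)]


def six_respondents_table() -> RatingsTable:
    """Ratings table for the six-respondent worked example (home + work)."""
    records = [
        RatingRecord(f"p{i + 1}", ItemId.HOME, a, b)
        for i, (a, b) in enumerate(SIX_RESPONDENTS_HOME)
    ] + [
        RatingRecord(f"p{i + 1}", ItemId.WORK, a, b)
        for i, (a, b) in enumerate(SIX_RESPONDENTS_WORK)
    ]
    return RatingsTable.from_records(records, provenance="example:six_respondents")
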