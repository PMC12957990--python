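"""Domain types for paired impairment/botheredness ratings.

The instrument is a modified Work and Social Adjustment Scale (WSAS): five
life areas, each rated twice on an integer 0-8 scale -- once for how impaired
the respondent is in that area, and once for how bothered they are about that
level of impairment.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RATING_MIN = 0
RATING_MAX = 8


class ItemId(enum.Enum):
    """The five WSAS life areas, in canonical report order."""

    HOME = "home"
    PRIVATE_LEISURE = "private_leisure"
    RELATIONSHIPS = "relationships"
    SOCIAL_LEISURE = "social_leisure"
    WORK = "work"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def from_token(cls, token: str) -> "ItemId":
        try:
            return cls(token.strip())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown item label {token!r}; expected one of: {valid}") from None


_DISPLAY_NAMES = {
    ItemId.HOME: "Home",
    ItemId.PRIVATE_LEISURE: "Private Leisure",
    ItemId.RELATIONSHIPS: "Relationships",
    ItemId.SOCIAL_LEISURE: "Social Leisure",
    ItemId.WORK: "Work",
}

#: Label used for the pooled (all items concatenated) analyses.
COMBINED = "combined"

#: Fixed row order of the report tables: Combined first, then the five items.
REPORT_ORDER: tuple[str, ...] = (COMBINED,) + tuple(m.value for m in ItemId)


def check_rating(value, *, what: str = "rating") -> int:
    """Validate a single rating: an integer in [0, 8]."""
    v = value
    if isinstance(v, float):
        if not float(v).is_integer():
            raise ValueError(f"{what} must be an integer, got {value!r}")
        v = int(v)
    if isinstance(v, (int, np.integer)) and not isinstance(v, bool):
        v = int(v)
    else:
        raise ValueError(f"{what} must be an integer, got {value!r}")
    if not RATING_MIN <= v <= RATING_MAX:
        raise ValueError(f"{what} must lie in [{RATING_MIN}, {RATING_MAX}], got {v}")
    return v


@dataclass(frozen=True)
class RatingRecord:
    """One respondent's paired ratings on one item."""

    respondent_id: str
    item: ItemId
    impaired: int
    bothered: int

    def __post_init__(self):
        object.__setattr__(self, "impaired", check_rating(self.impaired, what="impaired"))
        object.__setattr__(self, "bothered", check_rating(self.bothered, what="bothered"))


_COLUMNS = ["respondent_id", "item", "impaired", "bothered"]


@dataclass
class RatingsTable:
    """The paired ordinal dataset: respondent x item x {impaired, bothered}.

    Internally a long-format pandas DataFrame with columns
    ``respondent_id, item, impaired, bothered``.  ``impaired``/``bothered``
    may hold NaN only for tables built directly from a frame (e.g. lenient
    ingestion before validation); tables built from records are complete.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ratings frame missing columns: {missing}")
        self.frame = self.frame[_COLUMNS].reset_index(drop=True)
        self.frame["respondent_id"] = self.frame["respondent_id"].astype(str)
        self.frame["item"] = self.frame["item"].map(
            lambda x: x.value if isinstance(x, ItemId) else str(x)
        )

    @classmethod
    def from_records(cls, records: list[RatingRecord], provenance: str = "") -> "RatingsTable":
        frame = pd.DataFrame(
            [(r.respondent_id, r.item.value, r.impaired, r.bothered) for r in records],
            columns=_COLUMNS,
        )
        return cls(frame, provenance=provenance)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_respondents(self) -> int:
        return self.frame["respondent_id"].nunique()

    def items_present(self) -> list[ItemId]:
        present = set(self.frame["item"])
        return [m for m in ItemId if m.value in present]

    def item_pairs(self, item: ItemId) -> tuple[np.ndarray, np.ndarray]:
        """Paired (impaired, bothered) arrays for one item, complete pairs only."""
        sub = self.frame[self.frame["item"] == item.value].dropna(
            subset=["impaired", "bothered"]
        )
        return (
            sub["impaired"].to_numpy(dtype=float),
            sub["bothered"].to_numpy(dtype=float),
        )

    def records(self) -> list[RatingRecord]:
        return [
            RatingRecord(row.respondent_id, ItemId(row.item), int(row.impaired), int(row.bothered))
            for row in self.frame.dropna(subset=["impaired", "bothered"]).itertuples()
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingsTable):
            return NotImplemented
        a = self.frame.sort_values(["respondent_id", "item"]).reset_index(drop=True)
        b = other.frame.sort_values(["respondent_id", "item"]).reset_index(drop=True)
        return a.astype(object).equals(b.astype(object))


@dataclass(frozen=True)
class ValidationReport:
    """Counts of violation classes in a ratings table.

    ``strict_pass`` is true iff every violation count is zero.
    """

    n_records: int
    n_out_of_range: int
    n_duplicates: int
    n_missing: int

    @property
    def strict_pass(self) -> bool:
        return self.n_out_of_range == 0 and self.n_duplicates == 0 and self.n_missing == 0


def validate(table: RatingsTable) -> ValidationReport:
    """Count out-of-range, duplicate and missing-rating violations.

    Mirrors the study's data-inspection step ("no extreme scores and no
    missing values").  Does not mutate the table.
    """
    frame = table.frame
    if len(frame) == 0:
        warnings.warn("validating an empty ratings table", stacklevel=2)
        return ValidationReport(0, 0, 0, 0)
    n_missing = int(frame[["impaired", "bothered"]].isna().any(axis=1).sum())
    complete = frame.dropna(subset=["impaired", "bothered"])
    vals = complete[["impaired", "bothered"]].to_numpy(dtype=float)
    bad_range = (vals < RATING_MIN) | (vals > RATING_MAX) | (vals != np.floor(vals))
    n_out_of_range = int(bad_range.any(axis=1).sum())
    n_duplicates = int(frame.duplicated(subset=["respondent_id", "item"]).sum())
    return ValidationReport(len(frame), n_out_of_range, n_duplicates, n_missing)
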