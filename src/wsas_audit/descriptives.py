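"""Summary statistics behind the study's data inspection and plots.

Quartiles use linear interpolation between order statistics (the "type 7"
convention shared by numpy and R's default quantile); boxplot hinge
conventions differ across software, so the convention is fixed and named
here.  Skewness is the adjusted Fisher-Pearson sample coefficient; for a
constant vector it is reported as 0 with a warning rather than NaN, so that
degenerate synthetic inputs do not crash the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ItemId, RatingsTable

IMPAIRED = "impaired"
BOTHERED = "bothered"


@dataclass(frozen=True)
class SummaryStats:
    item: ItemId
    rating_kind: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: int
    max: int
    skewness: float
    counts_by_level: tuple[int, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _ratings(table: RatingsTable, item: ItemId, rating_kind: str) -> np.ndarray:
    if rating_kind not in (IMPAIRED, BOTHERED):
        raise ValueError(f"rating_kind must be {IMPAIRED!r} or {BOTHERED!r}")
    x, y = table.item_pairs(item)
    v = x if rating_kind == IMPAIRED else y
    if len(v) == 0:
        raise ValueError(f"no records for item {item.value!r}")
    return v


def summarize(table: RatingsTable, item: ItemId, rating_kind: str) -> SummaryStats:
    """Location, spread, shape and level counts for one item's rating column."""
    v = np.sort(_ratings(table, item, rating_kind))  # order statistics; also
    # makes every downstream float reduction independent of record order
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation (type 7)
    if np.ptp(v) == 0:
        warnings.warn(
            f"constant ratings for {item.value}/{rating_kind}; skewness reported as 0",
            stacklevel=2,
        )
        skew = 0.0
    else:
        skew = float(stats.skew(v, bias=False))
    counts = np.bincount(v.astype(int), minlength=9)
    return SummaryStats(
        item=item,
        rating_kind=rating_kind,
        n=len(v),
        mean=float(v.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=int(v.min()),
        max=int(v.max()),
        skewness=skew,
        counts_by_level=tuple(int(c) for c in counts),
    )


@dataclass(frozen=True)
class MedianComparison:
    item: ItemId
    impaired_median: float
    bothered_median: float

    @property
    def differs(self) -> bool:
        return self.impaired_median != self.bothered_median

    @property
    def higher(self) -> str:
        if self.impaired_median > self.bothered_median:
            return IMPAIRED
        if self.bothered_median > self.impaired_median:
            return BOTHERED
        return "tie"


def compare_medians(table: RatingsTable) -> list[MedianComparison]:
    """Per-item impaired vs bothered medians, mirroring the boxplot reading."""
    out = []
    for item in table.items_present():
        mi = summarize(table, item, IMPAIRED).median
        mb = summarize(table, item, BOTHERED).median
        out.append(MedianComparison(item, mi, mb))
    return out
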