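"""Spearman correlation of impaired vs bothered ratings with a permutation test.

Spearman's rho is the Pearson product-moment correlation of the two rank
vectors, with average ranks assigned to ties (the tie-exact form; the
``6*sum(d^2)/(n(n^2-1))`` shortcut is biased under ties and is not used).
Significance is assessed by shuffling one variable without replacement,
recomputing rho for each shuffle, and counting resampled coefficients at
least as large as the observed one.  Small samples are handled by exhaustive
enumeration of all n! permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .model import COMBINED, ItemId, RatingsTable
from .resampling import (
    P_ADD_ONE,
    P_PLUG_IN,
    TAIL_GREATER,
    TAIL_TWO_SIDED,
    ResampleResult,
    check_n_resamples,
    p_from_counts,
    rng_for,
)

DEFAULT_EXACT_THRESHOLD = 7


@dataclass(frozen=True)
class PairedVectors:
    """Paired impaired (x) and bothered (y) rating vectors for one label."""

    x: np.ndarray
    y: np.ndarray
    label: str

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and equally long")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


class ConstantVectorError(ValueError):
    """Raised when a correlation is requested for a constant vector."""


def _checked_ranks(pv: PairedVectors) -> tuple[np.ndarray, np.ndarray]:
    if pv.n < 2:
        raise ValueError(f"need at least 2 pairs, got {pv.n} (label={pv.label!r})")
    for name, v in (("x (impaired)", pv.x), ("y (bothered)", pv.y)):
        if np.ptp(v) == 0:
            raise ConstantVectorError(
                f"correlation undefined: {name} is constant for label {pv.label!r}"
            )
    return stats.rankdata(pv.x), stats.rankdata(pv.y)


def spearman_rho(pv: PairedVectors) -> float:
    """Tie-aware Spearman rank correlation in [-1, 1]."""
    rx, ry = _checked_ranks(pv)
    return float(np.corrcoef(rx, ry)[0, 1])


def pooled_pairs(table: RatingsTable) -> PairedVectors:
    """Concatenate every item's (impaired, bothered) pairs into one vector pair.

    This is the "combined" analysis: with a complete table of 61 respondents
    and five items it yields 305 pairs.  Pooling order is item order then the
    table's row order, so the same table always gives the same pair order.
    """
    if table.n_records == 0:
        raise ValueError("cannot pool an empty table")
    xs, ys = [], []
    for item in table.items_present():
        x, y = table.item_pairs(item)
        xs.append(x)
        ys.append(y)
    return PairedVectors(np.concatenate(xs), np.concatenate(ys), COMBINED)


def item_pairs(table: RatingsTable, item: ItemId) -> PairedVectors:
    x, y = table.item_pairs(item)
    return PairedVectors(x, y, item.value)


def _doubled_rank_ints(r: np.ndarray) -> np.ndarray:
    # average ranks are multiples of 1/2; doubling makes the permutation
    # counting exact in integer arithmetic
    return np.round(2.0 * r).astype(np.int64)


def _count_extreme(dots: np.ndarray, dot_obs: int, n: int, tail: str) -> int:
    # For fixed rank multisets, rho is an increasing affine function of the
    # rank dot product, so tail comparisons on rho reduce to exact integer
    # comparisons on the (doubled-rank) dot products.
    if tail == TAIL_GREATER:
        return int(np.count_nonzero(dots >= dot_obs))
    if tail == TAIL_TWO_SIDED:
        center = n * (n + 1) * (n + 1)
        return int(np.count_nonzero(np.abs(dots - center) >= abs(dot_obs - center)))
    raise ValueError(f"unknown tail {tail!r}")


def permutation_test_rho(
    pv: PairedVectors,
    n_resamples: int = 10_000,
    seed: int | None = None,
    tail: str = TAIL_GREATER,
    p_convention: str = P_ADD_ONE,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> ResampleResult:
    """Permutation test of Spearman's rho.

    Monte-Carlo mode shuffles y ``n_resamples`` times (x fixed) and counts
    shuffles meeting the tail criterion: resampled rho >= observed for
    ``one_sided_greater`` (the literal "as large or larger" counting rule),
    |resampled| >= |observed| for ``two_sided_absolute``.  When
    ``n <= exact_threshold`` all n! permutations are enumerated instead; the
    result is then exact and the p-value is the plug-in fraction.
    """
    rx, ry = _checked_ranks(pv)
    observed = float(np.corrcoef(rx, ry)[0, 1])
    n = pv.n
    rx2, ry2 = _doubled_rank_ints(rx), _doubled_rank_ints(ry)
    dot_obs = int(rx2 @ ry2)

    if n <= exact_threshold:
        perms = np.array(list(permutations(ry2)), dtype=np.int64)
        dots = perms @ rx2
        b = _count_extreme(dots, dot_obs, n, tail)
        n_perm = math.factorial(n)
        return ResampleResult(
            observed=observed,
            p_value=b / n_perm,
            n_resamples=n_perm,
            n_as_extreme=b,
            tail=tail,
            p_convention=P_PLUG_IN,
            seed=seed,
            exact=True,
            label=pv.label,
            statistic="spearman_rho",
        )

    check_n_resamples(n_resamples)
    rng = rng_for(seed, pv.label, "perm_rho")
    shuffled = rng.permuted(np.tile(ry2, (n_resamples, 1)), axis=1)
    dots = shuffled @ rx2
    b = _count_extreme(dots, dot_obs, n, tail)
    return ResampleResult(
        observed=observed,
        p_value=p_from_counts(b, n_resamples, p_convention),
        n_resamples=n_resamples,
        n_as_extreme=b,
        tail=tail,
        p_convention=p_convention,
        seed=seed,
        exact=False,
        label=pv.label,
        statistic="spearman_rho",
    )


def association_table(
    table: RatingsTable,
    n_resamples: int = 10_000,
    seed: int | None = None,
    tail: str = TAIL_GREATER,
    p_convention: str = P_ADD_ONE,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> list[ResampleResult]:
    """Correlation results in report order: combined first, then each item."""
    vecs = [pooled_pairs(table)] + [item_pairs(table, it) for it in table.items_present()]
    return [
        permutation_test_rho(
            pv,
            n_resamples=n_resamples,
            seed=seed,
            tail=tail,
            p_convention=p_convention,
            exact_threshold=exact_threshold,
        )
        for pv in vecs
    ]
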