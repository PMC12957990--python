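"""Sign-flip resampling test of impaired/bothered interchangeability.

If an impairment rating can substitute for a botheredness rating, the two
members of each pair are exchangeable and the paired differences
``d_i = impaired_i - bothered_i`` are symmetric about zero.  The test draws
random signs in {+1, -1} with replacement, multiplies them into the
difference vector, and compares |resampled mean| against |observed mean|
(a two-sided criterion, ties counted as extreme).  For small n all 2^n sign
assignments are enumerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import COMBINED, ItemId, RatingsTable
from .resampling import (
    P_ADD_ONE,
    P_PLUG_IN,
    TAIL_TWO_SIDED,
    ResampleResult,
    check_n_resamples,
    p_from_counts,
    rng_for,
)

DEFAULT_EXACT_MAX_N = 20


@dataclass(frozen=True)
class DifferenceVector:
    """Per-pair integer differences impaired - bothered, each in [-8, 8]."""

    d: np.ndarray
    label: str

    def __post_init__(self):
        d = np.asarray(self.d)
        if d.ndim != 1 or len(d) < 1:
            raise ValueError("difference vector must be 1-D and non-empty")
        if not np.all(d == np.floor(d)):
            raise ValueError("differences must be integers")
        d = d.astype(np.int64)
        if np.any(np.abs(d) > 8):
            raise ValueError("paired 0-8 ratings cannot differ by more than 8")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.d)


def differences(table: RatingsTable, label: ItemId | str) -> DifferenceVector:
    """Difference vector for one item, or pooled across all items ("combined")."""
    if label == COMBINED or (isinstance(label, str) and label == COMBINED):
        ds = []
        for item in table.items_present():
            x, y = table.item_pairs(item)
            ds.append(x - y)
        if not ds:
            raise ValueError("no records to difference")
        return DifferenceVector(np.concatenate(ds), COMBINED)
    item = label if isinstance(label, ItemId) else ItemId.from_token(str(label))
    x, y = table.item_pairs(item)
    if len(x) == 0:
        raise ValueError(f"no records for item {item.value!r}")
    return DifferenceVector(x - y, item.value)


def signflip_test(
    dv: DifferenceVector,
    n_resamples: int = 10_000,
    seed: int | None = None,
    p_convention: str = P_ADD_ONE,
) -> ResampleResult:
    """Monte-Carlo sign-flip test of the symmetric-differences null.

    Counting is done on integer sums (|sum(s_i d_i)| >= |sum(d_i)|), which is
    equivalent to comparing means and immune to floating-point tie
    misclassification.
    """
    check_n_resamples(n_resamples)
    d = dv.d
    s_obs = int(abs(d.sum()))
    rng = rng_for(seed, dv.label, "signflip")
    signs = rng.integers(0, 2, size=(n_resamples, dv.n), dtype=np.int8) * 2 - 1
    sums = signs.astype(np.int64) @ d
    b = int(np.count_nonzero(np.abs(sums) >= s_obs))
    return ResampleResult(
        observed=float(d.mean()),
        p_value=p_from_counts(b, n_resamples, p_convention),
        n_resamples=n_resamples,
        n_as_extreme=b,
        tail=TAIL_TWO_SIDED,
        p_convention=p_convention,
        seed=seed,
        exact=False,
        label=dv.label,
        statistic="mean_difference",
    )


def signflip_exact(dv: DifferenceVector, max_n: int = DEFAULT_EXACT_MAX_N) -> ResampleResult:
    """Exact twin of the sign-flip test: enumerate all 2^n sign assignments.

    Zero differences simply contribute duplicate assignments; the enumeration
    handles them with no special casing.  All arithmetic is integer-exact.
    """
    n = dv.n
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds exact enumeration limit {max_n}; use the Monte-Carlo signflip_test"
        )
    d = dv.d
    s_obs = int(abs(d.sum()))
    codes = np.arange(2**n, dtype=np.uint32)
    signs = (((codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.int64) * 2) - 1
    sums = signs @ d
    b = int(np.count_nonzero(np.abs(sums) >= s_obs))
    return ResampleResult(
        observed=float(d.mean()),
        p_value=b / 2**n,
        n_resamples=2**n,
        n_as_extreme=b,
        tail=TAIL_TWO_SIDED,
        p_convention=P_PLUG_IN,
        seed=None,
        exact=True,
        label=dv.label,
        statistic="mean_difference",
    )


def interchangeability_table(
    table: RatingsTable,
    n_resamples: int = 10_000,
    seed: int | None = None,
    p_convention: str = P_ADD_ONE,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> list[ResampleResult]:
    """Interchangeability results in report order: combined, then each item.

    Vectors short enough for full enumeration (n <= ``exact_max_n``) are
    tested exactly; longer ones by Monte-Carlo at ``n_resamples`` draws.
    """
    labels: list[ItemId | str] = [COMBINED] + list(table.items_present())
    out = []
    for label in labels:
        dv = differences(table, label)
        if dv.n <= exact_max_n:
            out.append(signflip_exact(dv, max_n=exact_max_n))
        else:
            out.append(
                signflip_test(dv, n_resamples=n_resamples, seed=seed, p_convention=p_convention)
            )
    return out
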