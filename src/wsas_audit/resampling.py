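"""Shared resampling machinery: p-value conventions, result container, seeds."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

TAIL_GREATER = "one_sided_greater"
TAIL_TWO_SIDED = "two_sided_absolute"
P_PLUG_IN = "plug_in"
P_ADD_ONE = "add_one"

MIN_RESAMPLES = 100


@dataclass(frozen=True)
class ResampleResult:
    """An observed statistic with its resampling-based p-value and provenance.

    ``p_convention``: ``plug_in`` reports b/B (the raw proportion of resampled
    statistics at least as extreme as the observed one); ``add_one`` reports
    (b+1)/(B+1), which can never be zero and yields a valid Monte-Carlo test.
    Exact enumerations always use ``plug_in`` (the fraction IS the p-value).
    """

    observed: float
    p_value: float
    n_resamples: int
    n_as_extreme: int
    tail: str
    p_convention: str
    seed: int | None
    exact: bool
    label: str = ""
    statistic: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def p_from_counts(n_as_extreme: int, n_resamples: int, convention: str) -> float:
    if convention == P_PLUG_IN:
        return n_as_extreme / n_resamples
    if convention == P_ADD_ONE:
        return (n_as_extreme + 1) / (n_resamples + 1)
    raise ValueError(f"unknown p-value convention {convention!r}")


def check_n_resamples(n_resamples: int) -> None:
    if n_resamples < MIN_RESAMPLES:
        raise ValueError(
            f"n_resamples must be at least {MIN_RESAMPLES}, got {n_resamples}"
        )


def subseed(master_seed: int, *labels: str) -> np.random.SeedSequence:
    """Deterministic per-task seed stream derived from a master seed.

    The stream key is the CRC-32 of each label, so adding a new labelled task
    never perturbs the streams of existing ones.
    """
    key = tuple(zlib.crc32(lab.encode("utf-8")) for lab in labels)
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def rng_for(master_seed: int | None, *labels: str) -> np.random.Generator:
    """PCG64 generator for a labelled sub-task (fresh entropy if seed is None)."""
    if master_seed is None:
        return np.random.default_rng()
    return np.random.Generator(np.random.PCG64(subseed(master_seed, *labels)))
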