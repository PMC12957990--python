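"""Simulation study: type-I error and power of the two resampling tests.

The study's raw data are unavailable, so the package validates its own
machinery by simulation: under each test's null the rejection rate at level
alpha should equal alpha (within binomial Monte-Carlo error), and power
should rise with effect size.  A final routine re-runs the whole audit on
many study-like synthetic tables and summarizes how often each item's
qualitative conclusion matches the study's pattern (every item except social
leisure rejecting interchangeability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import PairedVectors, permutation_test_rho
from .interchangeability import DifferenceVector, differences, signflip_test
from .model import COMBINED, ItemId
from .resampling import rng_for
from .synthetic import ItemGeneratorSpec, generate, study_like_config
from .association import spearman_rho, item_pairs

TEST_SIGNFLIP = "signflip"
TEST_PERM_RHO = "perm_rho"


@dataclass(frozen=True)
class SimulationDesign:
    n_respondents: int = 61
    n_replicates: int = 2_000
    n_resamples_per_test: int = 2_000
    alpha: float = 0.05
    effect_grid: tuple[float, ...] = ()
    master_seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 100:
            raise ValueError("need at least 100 replicates for a reported rate")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")


@dataclass(frozen=True)
class RatePoint:
    """One rejection rate with its binomial Monte-Carlo standard error."""

    effect: float
    rejection_rate: float
    n_replicates: int

    @property
    def monte_carlo_se(self) -> float:
        r = self.rejection_rate
        return float(np.sqrt(r * (1 - r) / self.n_replicates))


@dataclass(frozen=True)
class CalibrationReport:
    test: str
    alpha: float
    points: tuple[RatePoint, ...]

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "alpha": self.alpha,
            "points": [
                {
                    "effect": p.effect,
                    "rejection_rate": p.rejection_rate,
                    "monte_carlo_se": p.monte_carlo_se,
                    "n_replicates": p.n_replicates,
                }
                for p in self.points
            ],
        }


def _null_spec(shift: float, latent_correlation: float) -> ItemGeneratorSpec:
    return ItemGeneratorSpec(
        item=ItemId.HOME, latent_correlation=latent_correlation, shift=shift
    )


def _single_item_draw(
    spec: ItemGeneratorSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    from .synthetic import _draw_item_pairs

    return _draw_item_pairs(spec, n, rng)


def _rejection_rate(
    design: SimulationDesign, test: str, shift: float, latent_correlation: float
) -> float:
    """Fraction of replicates with p <= alpha for one generator setting."""
    n_reject = 0
    for rep in range(design.n_replicates):
        rng = rng_for(design.master_seed, "calibration", test, f"shift={shift}", f"rep={rep}")
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spec = _null_spec(shift, latent_correlation)
        x, y = _single_item_draw(spec, design.n_respondents, rng)
        if test == TEST_SIGNFLIP:
            dv = DifferenceVector((x - y).astype(np.int64), "sim")
            res = signflip_test(dv, n_resamples=design.n_resamples_per_test, seed=rep_seed)
        elif test == TEST_PERM_RHO:
            if np.ptp(x) == 0 or np.ptp(y) == 0:  # astronomically rare at n >= 10
                continue
            pv = PairedVectors(x, y, "sim")
            res = permutation_test_rho(
                pv, n_resamples=design.n_resamples_per_test, seed=rep_seed
            )
        else:
            raise ValueError(f"unknown test {test!r}")
        if res.p_value <= design.alpha:
            n_reject += 1
    return n_reject / design.n_replicates


def type1_error(design: SimulationDesign, test: str) -> CalibrationReport:
    """Rejection rate under the test's null.

    Sign-flip null: zero latent shift, so impaired and bothered coordinates
    are exchangeable and the differences are symmetric about zero (a paired
    latent correlation of 0.6 is kept to mimic real paired data; it does not
    affect the symmetry).  Permutation-rho null: independent coordinates.
    """
    if test == TEST_SIGNFLIP:
        rate = _rejection_rate(design, test, shift=0.0, latent_correlation=0.6)
    elif test == TEST_PERM_RHO:
        rate = _rejection_rate(design, test, shift=0.0, latent_correlation=0.0)
    else:
        raise ValueError(f"unknown test {test!r}")
    return CalibrationReport(
        test=test,
        alpha=design.alpha,
        points=(RatePoint(0.0, rate, design.n_replicates),),
    )


def power_curve(design: SimulationDesign, test: str) -> CalibrationReport:
    """Rejection rate at each effect size in the design's grid.

    For the sign-flip test the effect is the latent shift; for the
    permutation-rho test it is the latent correlation.
    """
    if not design.effect_grid:
        raise ValueError("power_curve requires a non-empty effect_grid")
    points = []
    for effect in design.effect_grid:
        if test == TEST_SIGNFLIP:
            rate = _rejection_rate(design, test, shift=effect, latent_correlation=0.6)
        elif test == TEST_PERM_RHO:
            rate = _rejection_rate(design, test, shift=0.0, latent_correlation=effect)
        else:
            raise ValueError(f"unknown test {test!r}")
        points.append(RatePoint(effect, rate, design.n_replicates))
    return CalibrationReport(test=test, alpha=design.alpha, points=tuple(points))


@dataclass(frozen=True)
class StudyPatternSummary:
    """Per-label outcome rates over replicated study-like audits."""

    n_replicates: int
    alpha: float
    reject_rate: dict  # label -> fraction of replicates rejecting interchangeability
    strong_assoc_rate: dict  # label -> fraction with permutation p <= 1e-4
    mean_spearman: dict  # label -> mean sample Spearman across replicates
    mean_difference: dict  # label -> mean of mean(impaired - bothered)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
            "reject_rate": dict(self.reject_rate),
            "strong_assoc_rate": dict(self.strong_assoc_rate),
            "mean_spearman": dict(self.mean_spearman),
            "mean_difference": dict(self.mean_difference),
        }


def reproduce_study_pattern(
    master_seed: int = 0,
    n_replicates: int = 500,
    n_respondents: int = 61,
    n_resamples: int = 10_000,
    alpha: float = 0.05,
    run_association: bool = True,
) -> StudyPatternSummary:
    """Audit many study-like synthetic tables and summarize the outcome pattern.

    Reports, per item and for the pooled vectors, the fraction of replicates
    rejecting interchangeability at ``alpha`` and (optionally) the fraction
    where the permutation correlation test yields p <= 1e-4, together with
    the replicate means of the sample Spearman and the mean difference.
    Deterministic in ``master_seed``.
    """
    base = study_like_config(0)
    labels = [COMBINED] + [it.value for it in ItemId]
    reject = {lab: 0 for lab in labels}
    strong = {lab: 0 for lab in labels}
    sp_sum = {lab: 0.0 for lab in labels}
    md_sum = {lab: 0.0 for lab in labels}

    for rep in range(n_replicates):
        rng = rng_for(master_seed, "study_pattern", f"rep={rep}")
        rep_seed = int(rng.integers(0, 2**31 - 1))
        table = generate(base.replace(n_respondents=n_respondents, seed=rep_seed))
        for lab in labels:
            dv = differences(table, lab if lab == COMBINED else ItemId(lab))
            res = signflip_test(dv, n_resamples=n_resamples, seed=rep_seed)
            if res.p_value <= alpha:
                reject[lab] += 1
            md_sum[lab] += float(dv.d.mean())
        from .association import pooled_pairs

        vecs = {COMBINED: pooled_pairs(table)}
        for it in ItemId:
            vecs[it.value] = item_pairs(table, it)
        for lab, pv in vecs.items():
            sp_sum[lab] += spearman_rho(pv)
            if run_association:
                res = permutation_test_rho(pv, n_resamples=n_resamples, seed=rep_seed)
                if res.p_value <= 1e-4:
                    strong[lab] += 1

    return StudyPatternSummary(
        n_replicates=n_replicates,
        alpha=alpha,
        reject_rate={k: v / n_replicates for k, v in reject.items()},
        strong_assoc_rate={k: v / n_replicates for k, v in strong.items()},
        mean_spearman={k: v / n_replicates for k, v in sp_sum.items()},
        mean_difference={k: v / n_replicates for k, v in md_sum.items()},
    )
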