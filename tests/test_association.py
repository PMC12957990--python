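"""Spearman rho and its permutation test, against independent oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from wsas_audit import (
    ItemId,
    PairedVectors,
    item_pairs,
    permutation_test_rho,
    pooled_pairs,
    spearman_rho,
)
from wsas_audit.association import ConstantVectorError
from wsas_audit.resampling import P_PLUG_IN, TAIL_GREATER, TAIL_TWO_SIDED

from conftest import make_complete_table


def brute_force_exact_p(x, y, tail):
    """Independent enumeration oracle: scipy rho over every permutation of y."""
    obs = stats.spearmanr(x, y).statistic
    hits = total = 0
    for perm in permutations(y):
        r = stats.spearmanr(x, perm).statistic
        if tail == TAIL_GREATER:
            hits += r >= obs - 1e-12
        else:
            hits += abs(r) >= abs(obs) - 1e-12
        total += 1
    return hits / total


class TestSpearmanRho:
    def test_identity_and_reversal(self):
        up = np.arange(5.0)
        assert spearman_rho(PairedVectors(up, up, "t")) == pytest.approx(1.0)
        assert spearman_rho(PairedVectors(up, up[::-1], "t")) == pytest.approx(-1.0)

    def test_work_item_hand_ranked_oracle(self, six_respondents):
        pv = item_pairs(six_respondents, ItemId.WORK)
        # hand ranks: x -> (5.5, 1.5, 3.5, 3.5, 1.5, 5.5), y -> (2.5, 5.5, 4, 5.5, 2.5, 1)
        rx = np.array([5.5, 1.5, 3.5, 3.5, 1.5, 5.5])
        ry = np.array([2.5, 5.5, 4.0, 5.5, 2.5, 1.0])
        assert spearman_rho(pv) == pytest.approx(np.corrcoef(rx, ry)[0, 1])
        assert spearman_rho(pv) == pytest.approx(-0.554, abs=5e-4)

    def test_constant_vector_names_offender(self):
        pv = PairedVectors(np.array([3.0, 3.0, 3.0]), np.array([1.0, 2.0, 3.0]), "home")
        with pytest.raises(ConstantVectorError, match="impaired.*home"):
            spearman_rho(pv)

    @given(seed=st.integers(0, 5_000))
    def test_matches_scipy_under_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 9, n).astype(float)
        y = rng.integers(0, 9, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        ours = spearman_rho(PairedVectors(x, y, "t"))
        assert ours == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 9, 20).astype(float)
        y = rng.integers(0, 9, 20).astype(float)
        assert spearman_rho(PairedVectors(x, y, "t")) == pytest.approx(
            spearman_rho(PairedVectors(y, x, "t"))
        )

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 9, 15).astype(float)
        y = rng.integers(0, 9, 15).astype(float)
        perm = rng.permutation(15)
        assert spearman_rho(PairedVectors(x, y, "t")) == pytest.approx(
            spearman_rho(PairedVectors(x[perm], y[perm], "t"))
        )


class TestPermutationTest:
    @pytest.mark.parametrize("tail", [TAIL_GREATER, TAIL_TWO_SIDED])
    def test_exact_mode_matches_brute_force(self, six_respondents, tail):
        pv = item_pairs(six_respondents, ItemId.WORK)
        res = permutation_test_rho(pv, tail=tail)
        assert res.exact and res.n_resamples == math.factorial(6)
        assert res.p_value == pytest.approx(brute_force_exact_p(pv.x, pv.y, tail))

    def test_perfect_distinct_correlation_exact_p(self):
        v = np.arange(1.0, 9.0)
        res = permutation_test_rho(
            PairedVectors(v, v, "t"), tail=TAIL_GREATER, exact_threshold=8
        )
        assert res.exact
        assert res.p_value == pytest.approx(1 / math.factorial(8))
        assert res.n_as_extreme == 1

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 9, 6).astype(float)
        y = rng.integers(0, 9, 6).astype(float)
        pv = PairedVectors(x, y, "t")
        exact = permutation_test_rho(pv).p_value
        mc = permutation_test_rho(
            pv, n_resamples=20_000, seed=5, exact_threshold=0, p_convention=P_PLUG_IN
        )
        assert not mc.exact
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(mc.p_value - exact) <= 3 * se

    def test_mc_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 9, 30).astype(float)
        y = rng.integers(0, 9, 30).astype(float)
        pv = PairedVectors(x, y, "t")
        a = permutation_test_rho(pv, n_resamples=1_000, seed=9)
        b = permutation_test_rho(pv, n_resamples=1_000, seed=9)
        assert a == b

    def test_swap_symmetry_exact_mode(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 9, 6).astype(float)
        y = rng.integers(0, 9, 6).astype(float)
        a = permutation_test_rho(PairedVectors(x, y, "t"))
        b = permutation_test_rho(PairedVectors(y, x, "t"))
        assert a.p_value == b.p_value
        assert a.observed == pytest.approx(b.observed)

    def test_add_one_convention_never_zero(self):
        rng = np.random.default_rng(7)
        x = np.arange(30.0)
        y = x + rng.normal(0, 0.01, 30)
        res = permutation_test_rho(PairedVectors(x, y, "t"), n_resamples=1_000, seed=1)
        assert res.p_value == (res.n_as_extreme + 1) / (res.n_resamples + 1)
        assert res.p_value > 0

    def test_too_few_resamples_rejected(self):
        pv = PairedVectors(np.arange(30.0), np.arange(30.0)[::-1], "t")
        with pytest.raises(ValueError, match="at least 100"):
            permutation_test_rho(pv, n_resamples=50, seed=0)


class TestPooledPairs:
    def test_pooled_length_and_label(self, random_complete_table):
        pv = pooled_pairs(random_complete_table)
        assert pv.n == random_complete_table.n_records == 60
        assert pv.label == "combined"

    def test_pooling_order_stable(self, random_complete_table):
        a = pooled_pairs(random_complete_table)
        b = pooled_pairs(random_complete_table)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_single_record_rejected_downstream(self):
        rng = np.random.default_rng(8)
        table = make_complete_table(rng.integers(0, 9, size=(1, 5, 2)))
        pv = item_pairs(table, ItemId.HOME)
        with pytest.raises(ValueError, match="at least 2"):
            spearman_rho(pv)
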