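"""Copula generator: discretization, calibration, and statistical recovery."""

import numpy as np
import pytest
from scipy import stats

from wsas_audit import (
    DEFAULT_MARGINAL_WEIGHTS,
    GeneratorConfig,
    ItemGeneratorSpec,
    ItemId,
    calibrate_latent_correlation,
    calibrate_shift,
    generate,
    latent_to_rating,
    study_like_config,
    validate,
)
from wsas_audit.synthetic import (
    STUDY_MEAN_DIFF,
    STUDY_SPEARMAN,
    UnreachableTargetError,
    expected_rating,
    shifted_weights,
    thresholds_from_weights,
)


def uniform_config(n, seed, latent_correlation=0.5, shift=0.0, weights=None):
    w = DEFAULT_MARGINAL_WEIGHTS if weights is None else weights
    specs = tuple(
        ItemGeneratorSpec(item=it, latent_correlation=latent_correlation, shift=shift,
                          marginal_weights=w)
        for it in ItemId
    )
    return GeneratorConfig(n_respondents=n, items=specs, seed=seed)


class TestLatentToRating:
    def test_boundaries(self):
        t = thresholds_from_weights(DEFAULT_MARGINAL_WEIGHTS)
        assert latent_to_rating(-10.0, t) == 0
        assert latent_to_rating(10.0, t) == 8

    def test_equiprobable_middle(self):
        t = thresholds_from_weights(np.full(9, 1 / 9))
        assert latent_to_rating(0.0, t) == 4

    def test_threshold_inclusive_on_left(self):
        t = np.arange(1.0, 9.0)
        assert latent_to_rating(1.0, t) == 1  # z == t[0] belongs to category 1

    def test_non_monotone_thresholds_rejected(self):
        t = np.arange(1.0, 9.0)
        t[3] = t[2]
        with pytest.raises(ValueError, match="increasing"):
            latent_to_rating(0.0, t)


class TestSpecValidation:
    def test_weights_must_sum_to_one(self):
        w = DEFAULT_MARGINAL_WEIGHTS * 1.01
        with pytest.raises(ValueError, match="sum to 1"):
            ItemGeneratorSpec(item=ItemId.HOME, latent_correlation=0.5, marginal_weights=w)

    def test_correlation_strictly_inside_unit_interval(self):
        with pytest.raises(ValueError):
            ItemGeneratorSpec(item=ItemId.HOME, latent_correlation=1.0)

    def test_config_needs_all_five_items(self):
        spec = ItemGeneratorSpec(item=ItemId.HOME, latent_correlation=0.5)
        with pytest.raises(ValueError, match="one ItemGeneratorSpec per item"):
            GeneratorConfig(n_respondents=10, items=(spec,) * 5, seed=0)


class TestGenerate:
    def test_deterministic_under_fixed_seed(self):
        cfg = uniform_config(61, seed=7)
        assert generate(cfg) == generate(cfg)

    def test_different_seed_differs(self):
        assert generate(uniform_config(61, 7)) != generate(uniform_config(61, 8))

    def test_output_passes_strict_validation(self):
        table = generate(uniform_config(40, seed=3))
        rep = validate(table)
        assert rep.strict_pass and rep.n_records == 200

    def test_near_perfect_latent_dependence_survives_discretization(self):
        cfg = uniform_config(10_000, seed=5, latent_correlation=0.99)
        x, y = generate(cfg).item_pairs(ItemId.HOME)
        assert stats.spearmanr(x, y).statistic > 0.9

    def test_zero_shift_gives_zero_mean_difference(self):
        cfg = uniform_config(10_000, seed=9, latent_correlation=0.5, shift=0.0)
        x, y = generate(cfg).item_pairs(ItemId.WORK)
        assert abs((x - y).mean()) < 0.05

    def test_marginal_recovery(self):
        cfg = uniform_config(50_000, seed=11, latent_correlation=0.3)
        x, _ = generate(cfg).item_pairs(ItemId.HOME)
        freqs = np.bincount(x.astype(int), minlength=9) / len(x)
        assert np.max(np.abs(freqs - DEFAULT_MARGINAL_WEIGHTS)) < 0.02

    def test_spearman_monotone_in_latent_correlation(self):
        observed = []
        for r in (0.1, 0.4, 0.7, 0.95):
            x, y = generate(uniform_config(20_000, seed=13, latent_correlation=r)).item_pairs(
                ItemId.HOME
            )
            observed.append(stats.spearmanr(x, y).statistic)
        assert observed == sorted(observed)

    def test_mean_difference_decreasing_in_shift(self):
        diffs = []
        for s in (-0.5, 0.0, 0.5, 1.0):
            x, y = generate(uniform_config(20_000, seed=17, shift=s)).item_pairs(ItemId.HOME)
            diffs.append((x - y).mean())
        assert diffs == sorted(diffs, reverse=True)


class TestCalibration:
    def test_zero_target_maps_to_zero(self):
        assert calibrate_latent_correlation(0.0) == 0.0

    def test_attenuation_requires_larger_latent(self):
        r = calibrate_latent_correlation(0.7081, n_probe=50_000, seed=1)
        assert r >= 0.7081

    def test_unreachable_target_reports_bound(self):
        degenerate = np.full(9, 0.01 / 8)
        degenerate[4] = 0.99
        with pytest.raises(UnreachableTargetError) as exc:
            calibrate_latent_correlation(0.99, degenerate, degenerate, n_probe=20_000)
        assert exc.value.achievable_bound < 0.99

    def test_shift_calibration_closed_form(self):
        delta = calibrate_shift(-0.5)
        mu0 = expected_rating(DEFAULT_MARGINAL_WEIGHTS, 0.0)
        assert mu0 - expected_rating(DEFAULT_MARGINAL_WEIGHTS, delta) == pytest.approx(-0.5)

    def test_shifted_weights_still_a_distribution(self):
        w = shifted_weights(DEFAULT_MARGINAL_WEIGHTS, 0.62)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)


class TestStudyLikeConfig:
    def test_deterministic(self):
        a = study_like_config(0)
        b = study_like_config.__wrapped__(0)  # bypass cache: recalibrates
        assert a.to_dict() == b.to_dict()

    def test_default_sample_size_and_skewed_marginals(self):
        cfg = study_like_config(0)
        assert cfg.n_respondents == 61
        x, _ = generate(cfg.replace(n_respondents=20_000)).item_pairs(ItemId.HOME)
        assert stats.skew(x) > 0.15  # clearly right-skewed, non-normal

    def test_serialization_round_trip(self):
        cfg = study_like_config(0)
        assert GeneratorConfig.from_dict(cfg.to_dict()).to_dict() == cfg.to_dict()

    def test_design_point_recovery_scaled(self):
        # scaled-down version of the full recovery check (n = 50,000 in
        # the acceptance suite)
        table = generate(study_like_config(0).replace(n_respondents=10_000))
        for item in (ItemId.HOME, ItemId.WORK):
            x, y = table.item_pairs(item)
            assert stats.spearmanr(x, y).statistic == pytest.approx(
                STUDY_SPEARMAN[item], abs=0.04
            )
            assert (x - y).mean() == pytest.approx(STUDY_MEAN_DIFF[item], abs=0.1)
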