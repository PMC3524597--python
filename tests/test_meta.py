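import math

import numpy as np
import pytest

from greenwallcba.errors import InvalidParameterError, ZeroUncertaintyError
from greenwallcba.meta import (
    MetaResult,
    WeightedEstimate,
    impute_se,
    influence,
    quantile_interval,
    to_weighted,
    weighted_mean,
)
from greenwallcba.transfer import (
    IntervalUncertainty,
    NoUncertainty,
    ReportedRelativeSE,
)

# published pooling table: (unit value, inverse-variance weight)
PUBLISHED_WEIGHTS = {
    "peck_1999": (20.88, 0.048),
    "hunt_2008": (17.90, 0.027),
    "gao_asami_tokyo": (3.46, 0.368),
    "gao_asami_kitakyushu": (0.69, 6.351),
    "ichihara_cohen": (17.18, 0.014),
    "des_rosiers": (3.78, 0.281),
    "tomalty_recreational": (63.47, 0.001),
    "tomalty_productive": (22.22, 0.008),
}


class TestImputeSe:
    def test_interval_half_width_over_z(self):
        # oracle: relative SE = ((15-6)/(2*1.96)) / 10.5, applied to the point
        expected = ((15 - 6) / (2 * 1.96)) / 10.5 * 20.88
        se = impute_se(IntervalUncertainty(6, 15), 20.88)
        assert se == pytest.approx(expected, rel=1e-12)
        assert 1 / se**2 == pytest.approx(0.048, abs=0.0005)

    def test_wide_interval(self):
        expected = ((15 - 3) / 3.92) / 9 * 17.90
        se = impute_se(IntervalUncertainty(3, 15), 17.90)
        assert se == pytest.approx(expected, rel=1e-12)
        assert se == pytest.approx(6.088, abs=0.001)
        assert 1 / se**2 == pytest.approx(0.027, abs=0.0005)

    def test_missing_uncertainty_is_half_the_point(self):
        se = impute_se(NoUncertainty(), 63.47)
        assert se == pytest.approx(31.735, rel=1e-12)
        assert 1 / se**2 == pytest.approx(0.001, abs=0.0005)

    def test_reported_relative_se_is_preserved(self):
        assert impute_se(ReportedRelativeSE(0.25), 8.0) == pytest.approx(2.0)

    def test_zero_relative_se_rejected(self):
        from greenwallcba.errors import ValidationError

        with pytest.raises(ValidationError):
            ReportedRelativeSE(0.0)

    def test_nonpositive_point_rejected(self):
        with pytest.raises(InvalidParameterError):
            impute_se(NoUncertainty(), 0.0)


class TestFixtureWeights:
    def test_weights_reproduce_published_column(self, weighted):
        by_id = {w.study_id: w for w in weighted}
        for study_id, (effect, weight) in PUBLISHED_WEIGHTS.items():
            assert by_id[study_id].effect == pytest.approx(effect, rel=0.005)
            assert by_id[study_id].weight == pytest.approx(weight, rel=0.005, abs=5e-4)

    def test_weight_times_variance_is_one(self, weighted):
        for w in weighted:
            assert w.weight * w.variance == pytest.approx(1.0, rel=1e-12)


class TestWeightedMean:
    def test_pooled_mean_of_all_studies(self, weighted):
        assert weighted_mean(weighted).weighted_mean == pytest.approx(1.2, abs=0.05)

    def test_pooled_mean_excluding_dominant_study(self, weighted):
        rest = [w for w in weighted if w.study_id != "gao_asami_kitakyushu"]
        assert weighted_mean(rest).weighted_mean == pytest.approx(5.8, abs=0.05)

    def test_published_pairs_direct(self):
        # independent oracle on the printed (value, weight) pairs
        num = sum(w * y for y, w in PUBLISHED_WEIGHTS.values())
        den = sum(w for _, w in PUBLISHED_WEIGHTS.values())
        assert round(num / den, 1) == 1.2

    def test_equal_weights_give_arithmetic_mean(self):
        ests = [WeightedEstimate(f"s{i}", float(v), 2.0) for i, v in enumerate([1, 5, 9])]
        assert weighted_mean(ests).weighted_mean == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            weighted_mean([])

    def test_bounded_by_effects(self, weighted):
        result = weighted_mean(weighted)
        effects = [w.effect for w in weighted]
        assert min(effects) <= result.weighted_mean <= max(effects)

    def test_relative_weights_sum_to_one(self, weighted):
        result = weighted_mean(weighted)
        assert sum(result.relative_weights.values()) == pytest.approx(1.0)

    def test_single_study_returns_its_effect(self):
        est = WeightedEstimate("only", 7.3, 1.1)
        result = weighted_mean([est])
        assert result.weighted_mean == pytest.approx(7.3)
        assert result.pooled_se == pytest.approx(1.1)

    def test_invariant_to_uniform_se_rescaling(self, weighted):
        base = weighted_mean(weighted).weighted_mean
        scaled = [
            WeightedEstimate(w.study_id, w.effect, w.se * 3.7) for w in weighted
        ]
        assert weighted_mean(scaled).weighted_mean == pytest.approx(base, rel=1e-12)

    def test_pooled_se_formula(self, weighted):
        result = weighted_mean(weighted)
        assert result.pooled_se == pytest.approx(
            1 / math.sqrt(sum(w.weight for w in weighted)), rel=1e-12
        )


class TestInfluence:
    def test_dominant_study_relative_weight(self, weighted):
        rows = {r.study_id: r for r in influence(weighted)}
        # printed-weight ratio oracle: 6.351 / 7.098
        assert rows["gao_asami_kitakyushu"].relative_weight == pytest.approx(
            6.351 / 7.098, abs=0.005
        )

    def test_leave_one_out_mean(self, weighted):
        rows = {r.study_id: r for r in influence(weighted)}
        assert rows["gao_asami_kitakyushu"].loo_mean == pytest.approx(5.8, abs=0.05)

    def test_negligible_weight_study_barely_moves_mean(self):
        # continuity: a study with vanishing relative weight cannot move the mean
        ests = [
            WeightedEstimate("a", 2.0, 0.1),
            WeightedEstimate("b", 3.0, 0.1),
            WeightedEstimate("tiny", 50.0, 1e4),
        ]
        result = weighted_mean(ests)
        rows = {r.study_id: r for r in influence(ests)}
        assert rows["tiny"].relative_weight < 1e-9
        moved = abs(rows["tiny"].loo_mean - result.weighted_mean)
        assert moved < result.pooled_se / 100

    def test_requires_two_studies(self):
        with pytest.raises(InvalidParameterError):
            influence([WeightedEstimate("only", 1.0, 1.0)])


class TestOptimality:
    def test_inverse_variance_minimizes_variance(self):
        """Any perturbed weight vector yields an estimator with >= variance."""
        rng = np.random.default_rng(7)
        ses = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        n_rep = 4000
        draws = rng.normal(10.0, ses, size=(n_rep, ses.size))
        w_iv = 1 / ses**2
        iv_est = draws @ w_iv / w_iv.sum()
        for _ in range(10):
            w_pert = w_iv * np.exp(rng.normal(0, 0.5, ses.size))
            pert_est = draws @ w_pert / w_pert.sum()
            assert iv_est.var() <= pert_est.var() + 1e-12

    def test_package_matches_numpy_combination(self):
        rng = np.random.default_rng(11)
        effects = rng.uniform(1, 20, 6)
        ses = rng.uniform(0.2, 5, 6)
        ests = [
            WeightedEstimate(f"s{i}", float(y), float(s))
            for i, (y, s) in enumerate(zip(effects, ses))
        ]
        expected = np.average(effects, weights=1 / ses**2)
        assert weighted_mean(ests).weighted_mean == pytest.approx(expected, rel=1e-12)


class TestQuantileInterval:
    def test_interval_brackets_the_bulk(self, estimates):
        lo, hi = quantile_interval([e.unit_value for e in estimates], 0.90)
        values = sorted(e.unit_value for e in estimates)
        assert values[0] <= lo < hi <= values[-1]

    def test_bad_mass_rejected(self):
        with pytest.raises(InvalidParameterError):
            quantile_interval([1.0, 2.0], 1.5)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            quantile_interval([])


def test_to_weighted_respects_preset_se(estimates):
    preset = [estimates[0].with_se(2.5)]
    assert to_weighted(preset)[0].se == 2.5
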