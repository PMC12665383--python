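"""MR estimators against closed-form and hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scmr.errors import EstimationError
from scmr.mr import (
    HarmonizedInstrumentSet,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from scmr.simstudy import egger_pleiotropy_recovery


def hset(bx, by, sy, sx=0.01):
    return HarmonizedInstrumentSet.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_point_estimate_and_delta_se(self):
        est = wald_ratio(hset([0.5], [0.1], [0.05]))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_gives_or_one(self):
        est = wald_ratio(hset([0.5], [0.0], [0.05]))
        assert est.beta == 0.0 and est.or_ == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(hset([0.0], [0.1], [0.05]))


class TestIVW:
    def test_equal_ratios_give_exact_estimate(self):
        est = ivw(hset([0.2, 0.5], [0.02, 0.05], [0.01, 0.01]))
        assert est.beta == pytest.approx(0.1, abs=1e-14)

    def test_single_instrument_delegates_to_wald(self):
        h = hset([0.4], [0.08], [0.02])
        assert ivw(h).beta == pytest.approx(wald_ratio(h).beta)
        assert ivw(h).se == pytest.approx(wald_ratio(h).se)

    def test_constant_ratio_fixed_effect_se(self):
        bx = np.array([0.2, 0.3, 0.5])
        c = 0.25
        by = c * bx
        sy = np.array([0.01, 0.02, 0.015])
        est = ivw(hset(bx, by, sy), random_effects=False)
        assert est.beta == pytest.approx(c, abs=1e-12)
        assert est.se == pytest.approx(1.0 / np.sqrt(np.sum(bx ** 2 / sy ** 2)),
                                       abs=1e-12)

    @given(st.integers(2, 15), st.integers(0, 10_000))
    def test_matches_weighted_mean_of_ratios(self, m, seed):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.1, 0.5, m) * rng.choice([-1, 1], m)
        by = rng.normal(0, 0.05, m)
        sy = rng.uniform(0.005, 0.05, m)
        est = ivw(hset(bx, by, sy), random_effects=False)
        ratios = by / bx
        w = bx ** 2 / sy ** 2
        assert est.beta == pytest.approx(np.sum(w * ratios) / np.sum(w),
                                         abs=1e-10)

    def test_all_null_exposure_rejected(self):
        with pytest.raises(EstimationError):
            ivw(hset([0.0, 0.0], [0.1, 0.1], [0.05, 0.05]))


class TestEgger:
    def test_perfect_affine_relation_recovered_exactly(self):
        slope, intercept = mr_egger(hset([1.0, 2.0, 3.0], [1.1, 2.1, 3.1],
                                         [0.05, 0.05, 0.05]))
        assert slope.beta == pytest.approx(1.0, abs=1e-10)
        assert intercept.beta == pytest.approx(0.1, abs=1e-10)

    def test_line_through_origin_gives_zero_intercept(self):
        _, intercept = mr_egger(hset([1.0, 2.0, 4.0], [0.5, 1.0, 2.0],
                                     [0.03, 0.03, 0.03]))
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_below_three_instruments_not_applicable(self):
        assert mr_egger(hset([0.2, 0.3], [0.02, 0.03], [0.01, 0.01])) is None

    def test_intercept_recovers_directional_pleiotropy(self):
        """Monte-Carlo oracle: mean pleiotropic effect 0.05 across
        oriented instruments is recovered by the mean intercept."""
        res = egger_pleiotropy_recovery(n_reps=1000, alpha_mean=0.05, seed=4)
        assert 0.04 <= res["mean_intercept"] <= 0.06


class TestWeightedMedian:
    def test_middle_ratio_with_equal_weights(self):
        est = weighted_median(hset([1.0, 1.0, 1.0], [0.1, 0.2, 0.3],
                                   [0.05, 0.05, 0.05]), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_hand_interpolated_example(self):
        # ratios (0.1, 0.2, 0.4) with normalized weights (1/4, 1/4, 1/2):
        # cumulative midpoints (0.125, 0.375, 0.75); interpolating 0.5
        # between 0.375 and 0.75 gives 0.2 + (0.125/0.375) * 0.2 = 4/15
        sy = 0.05
        w = np.array([0.25, 0.25, 0.5])
        bx = np.sqrt(w) * sy  # makes bx^2/sy^2 proportional to w
        by = bx * np.array([0.1, 0.2, 0.4])
        est = weighted_median(hset(bx, by, [sy] * 3), n_boot=100, seed=0)
        assert est.beta == pytest.approx(4.0 / 15.0, abs=1e-12)

    def test_identical_ratios_and_seeded_bootstrap(self):
        h = hset([0.2, 0.3, 0.4], np.array([0.2, 0.3, 0.4]) * 0.3,
                 [0.001, 0.001, 0.001], sx=0.001)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        assert a.beta == pytest.approx(0.3, abs=1e-12)
        assert a.se == b.se
        assert a.se < 0.05


class TestWeightedMode:
    def test_density_peak_near_majority_cluster(self):
        est = weighted_mode(hset([1.0, 1.0, 1.0, 1.0],
                                 [0.2, 0.2, 0.2, 0.9],
                                 [0.05] * 4), n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_degenerate_common_ratio(self):
        est = weighted_mode(hset([0.2, 0.4, 0.5],
                                 np.array([0.2, 0.4, 0.5]) * 0.7,
                                 [0.01] * 3), n_boot=100, seed=2)
        assert est.beta == pytest.approx(0.7, abs=1e-12)

    def test_same_seed_same_bootstrap_se(self):
        h = hset([0.2, 0.3, 0.4], [0.05, 0.06, 0.09], [0.01] * 3)
        assert weighted_mode(h, n_boot=200, seed=3).se == \
            weighted_mode(h, n_boot=200, seed=3).se


class TestCochranQ:
    def test_homogeneous_ratios_give_zero(self):
        q, df, p = cochran_q(hset([0.2, 0.4], [0.02, 0.04], [0.01, 0.01]))
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_instruments(self):
        # ratios 0.1 and 0.3 with se(ratio)=0.1 each: pooled 0.2, Q = 2
        q, df, p = cochran_q(hset([1.0, 1.0], [0.1, 0.3], [0.1, 0.1]))
        assert q == pytest.approx(2.0, abs=1e-12)
        assert df == 1

    def test_egger_variant_df(self):
        q, df, _ = cochran_q(hset([0.2, 0.3, 0.5], [0.021, 0.028, 0.052],
                                  [0.01] * 3), method="egger")
        assert df == 1
        assert q >= 0


class TestLeaveOneOut:
    def test_cardinality_and_homogeneous_case(self):
        h = hset([0.2, 0.4, 0.5], np.array([0.2, 0.4, 0.5]) * 0.3, [0.01] * 3)
        table = leave_one_out(h)
        assert len(table) == 4
        assert table["excluded"].tolist()[-1] == "All"
        np.testing.assert_allclose(table["beta"], 0.3, atol=1e-12)

    def test_planted_outlier_shifts_most_on_its_exclusion(self):
        bx = np.array([0.2, 0.3, 0.4, 0.5])
        by = bx * 0.2
        by[2] += 0.3  # outlier ratio
        table = leave_one_out(hset(bx, by, [0.01] * 4))
        full = table.loc[table["excluded"] == "All", "beta"].iloc[0]
        shifts = (table[table["excluded"] != "All"]
                  .assign(shift=lambda d: (d["beta"] - full).abs()))
        assert shifts.sort_values("shift")["excluded"].iloc[-1] == "snp3"


class TestOddsRatio:
    def test_null_beta(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert np.log(hi) == pytest.approx(-np.log(lo))

    def test_small_beta_rounding(self):
        or_, _, _ = to_odds_ratio(0.0013, 1e-6)
        assert round(or_, 4) == 1.0013

    @given(st.floats(-2, 2), st.floats(1e-4, 1.0))
    def test_log_symmetry(self, beta, se):
        or_, lo, hi = to_odds_ratio(beta, se)
        assert np.log(hi) - np.log(or_) == pytest.approx(
            np.log(or_) - np.log(lo), abs=1e-9)
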