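"""The causal-estimator battery: oracle identities, robustness, equivariance."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpipe.estimators import (cochran_q_mr, ivw, leave_one_out, mode_estimate,
                               mr_egger, mr_raps, to_odds_ratio, wald_ratio,
                               weighted_median)
from mrpipe.harmonize import HarmonizedSet


def _random_set(rng, k=20, theta=0.1):
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.005, 0.05, k)
    by = rng.normal(theta * bx, sy)
    return HarmonizedSet([f"rs{i}" for i in range(k)], bx, sx, by, sy,
                         np.full(k, 0.3))


class TestWaldRatio:
    def test_arithmetic(self):
        e = wald_ratio(0.5, 0.05, -0.05, 0.01)
        assert e.beta == pytest.approx(-0.1)
        assert e.se == pytest.approx(0.02)

    def test_null_outcome(self):
        assert wald_ratio(0.3, 0.01, 0.0, 0.01).beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)

    def test_second_order_se_dominates_first_order(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            bx, by = rng.uniform(0.01, 1, 2)
            sx, sy = rng.uniform(0.001, 0.1, 2)
            first = wald_ratio(bx, sx, by, sy).se
            second = wald_ratio(bx, sx, by, sy, second_order=True).se
            assert second >= first
            # exact delta-method decomposition
            assert second == pytest.approx(
                np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))


class TestIVW:
    def test_single_snp_reduces_to_wald(self, make_set):
        s = make_set([0.2], [0.05], sy=[0.015])
        w = wald_ratio(0.2, 0.01, 0.05, 0.015)
        e = ivw(s, model="fixed")
        assert e.beta == pytest.approx(w.beta) and e.se == pytest.approx(w.se)

    def test_equal_weight_pair_averages_ratios(self, make_set):
        # equal Wald SEs: |bx| equal, sy equal
        s = make_set([0.2, 0.2], [0.02, 0.06])
        assert ivw(s, model="fixed").beta == pytest.approx((0.1 + 0.3) / 2)

    def test_matches_wald_ratio_pooling_oracle(self):
        """IVW(fixed) is the inverse-variance weighted mean of Wald ratios."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            s = _random_set(rng)
            r = s.by / s.bx
            w = s.bx**2 / s.sy**2  # = 1/se(r)^2 with se(r) = sy/|bx|
            oracle = np.sum(w * r) / np.sum(w)
            e = ivw(s, model="fixed")
            assert abs(e.beta - oracle) < 1e-10
            assert abs(e.se - 1 / np.sqrt(np.sum(w))) < 1e-10

    def test_matches_statsmodels_through_origin_wls(self):
        rng = np.random.default_rng(4)
        s = _random_set(rng)
        fit = sm.WLS(s.by, s.bx[:, None], weights=1.0 / s.sy**2).fit()
        assert ivw(s, model="fixed").beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_multiplicative_random_se_never_below_fixed(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = _random_set(rng)
            assert ivw(s).se >= ivw(s, model="fixed").se - 1e-15

    def test_empty_set_rejected(self, make_set):
        with pytest.raises(ValueError):
            ivw(HarmonizedSet([], [], [], [], [], []))


class TestEgger:
    def test_exact_line_through_origin(self, make_set):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        s = make_set(bx, 0.5 * bx)
        slope, intercept = mr_egger(s)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_directional_shift_moves_intercept_only(self, make_set):
        bx = np.array([0.1, 0.25, 0.3, 0.45, 0.6])
        s0 = make_set(bx, 0.4 * bx)
        s1 = make_set(bx, 0.4 * bx + 0.07)
        sl0, ic0 = mr_egger(s0)
        sl1, ic1 = mr_egger(s1)
        assert ic1.beta - ic0.beta == pytest.approx(0.07, abs=1e-12)
        assert sl1.beta == pytest.approx(sl0.beta, abs=1e-12)

    def test_below_three_snps_not_computed(self, make_set):
        s = make_set([0.1, 0.2], [0.05, 0.1])
        slope, intercept = mr_egger(s)
        assert not slope.computed and not intercept.computed

    def test_orientation_invariance(self, make_set):
        """Flipping the reported allele of some SNPs leaves Egger unchanged."""
        rng = np.random.default_rng(6)
        s = _random_set(rng, k=8)
        flip = rng.choice([1.0, -1.0], 8)
        s2 = HarmonizedSet(s.snp_ids, s.bx * flip, s.sx, s.by * flip, s.sy, s.eaf)
        a, b = mr_egger(s), mr_egger(s2)
        assert a[0].beta == pytest.approx(b[0].beta)
        assert a[1].beta == pytest.approx(b[1].beta)

    def test_intercept_coverage_under_zero_pleiotropy(self):
        """±2·SE around the intercept covers 0 in at least 93% of reps."""
        rng = np.random.default_rng(7)
        hits, reps = 0, 500
        for _ in range(reps):
            k = 15
            gamma = rng.uniform(0.08, 0.3, k)
            sx = np.full(k, 0.005)
            sy = np.full(k, 0.02)
            s = HarmonizedSet([f"rs{i}" for i in range(k)],
                              rng.normal(gamma, sx), sx,
                              rng.normal(0.3 * gamma, sy), sy, np.full(k, 0.3))
            _, intercept = mr_egger(s)
            hits += abs(intercept.beta) <= 2 * intercept.se
        assert hits / reps >= 0.93


class TestWeightedMedian:
    def test_equal_weight_median(self, make_set):
        s = make_set([0.1, 0.1, 0.1], [0.1, 0.2, 1.0])  # ratios 1, 2, 10
        e = weighted_median(s, n_boot=200, seed=1)
        assert e.beta == pytest.approx(2.0)

    def test_duplicating_every_snp_changes_nothing(self, make_set):
        # the median falls on a data point, where the interpolated
        # weighted median depends only on normalized weights
        bx, by = [0.1, 0.1, 0.1], [0.1, 0.2, 1.0]
        a = weighted_median(make_set(bx, by), n_boot=200, seed=2)
        b = weighted_median(make_set(bx * 2, by * 2), n_boot=200, seed=2)
        assert a.beta == pytest.approx(b.beta) == pytest.approx(2.0)

    def test_requires_seed(self, make_set):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(make_set([0.1, 0.2, 0.3], [0.02, 0.04, 0.06]))

    def test_below_three_snps_not_computed(self, make_set):
        e = weighted_median(make_set([0.1], [0.02]), n_boot=10, seed=1)
        assert not e.computed

    def test_robust_to_minority_invalid_instruments(self):
        """Valid-majority median stays near truth while IVW is dragged away."""
        rng = np.random.default_rng(8)
        theta = 0.3
        wm_est, ivw_est = [], []
        for _ in range(100):
            k, invalid = 14, 4
            gamma = rng.uniform(0.15, 0.3, k)
            alpha = np.zeros(k)
            alpha[:invalid] = 0.08
            sx, sy = np.full(k, 0.002), np.full(k, 0.002)
            s = HarmonizedSet([f"rs{i}" for i in range(k)],
                              rng.normal(gamma, sx), sx,
                              rng.normal(theta * gamma + alpha, sy), sy,
                              np.full(k, 0.3))
            wm_est.append(weighted_median(s, n_boot=50, seed=9).beta)
            ivw_est.append(ivw(s, model="fixed").beta)
        assert abs(np.mean(wm_est) - theta) < 0.02
        assert abs(np.mean(ivw_est) - theta) > 0.05


class TestModeEstimators:
    def test_modal_cluster(self, make_set):
        s = make_set([0.1, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.5])  # ratios 1,1,1,5
        e = mode_estimate(s, weighted=False, n_boot=100, seed=3)
        assert e.beta == pytest.approx(1.0, abs=0.05)

    def test_weighted_equals_simple_under_equal_weights(self, make_set):
        # equal ratio SEs: equal |bx| and sy
        s = make_set([0.2, 0.2, 0.2, 0.2], [0.02, 0.03, 0.05, 0.4])
        a = mode_estimate(s, weighted=True, n_boot=50, seed=4)
        b = mode_estimate(s, weighted=False, n_boot=50, seed=4)
        assert a.beta == pytest.approx(b.beta)

    def test_unimodal_agreement_with_median_and_ivw(self):
        rng = np.random.default_rng(10)
        k = 40
        gamma = rng.uniform(0.2, 0.4, k)
        sx, sy = np.full(k, 0.001), np.full(k, 0.002)
        s = HarmonizedSet([f"rs{i}" for i in range(k)],
                          rng.normal(gamma, sx), sx,
                          rng.normal(0.25 * gamma, sy), sy, np.full(k, 0.3))
        m = mode_estimate(s, weighted=True, n_boot=50, seed=5).beta
        w = weighted_median(s, n_boot=50, seed=5).beta
        i = ivw(s, model="fixed").beta
        assert m == pytest.approx(0.25, abs=0.01)
        assert abs(m - w) < 0.01 and abs(m - i) < 0.01

    def test_below_three_snps_not_computed(self, make_set):
        e = mode_estimate(make_set([0.1, 0.2], [0.02, 0.04]), n_boot=10, seed=1)
        assert not e.computed


class TestMrRaps:
    def test_reduces_to_ivw_without_exposure_error(self, make_set):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.1, 0.4, 10)
        by = rng.normal(0.2 * bx, 0.01)
        s = HarmonizedSet([f"rs{i}" for i in range(10)], bx, np.full(10, 1e-10),
                          by, np.full(10, 0.01), np.full(10, 0.3))
        raps = mr_raps(s, overdispersion=False, loss="l2", seed=1)
        fixed = ivw(s, model="fixed")
        assert raps.beta == pytest.approx(fixed.beta, abs=1e-6)
        assert raps.se == pytest.approx(fixed.se, rel=1e-3)

    def test_exact_proportionality_root(self, make_set):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        s = HarmonizedSet(["a", "b", "c", "d"], bx, np.full(4, 0.01),
                          0.7 * bx, np.full(4, 1e-8), np.full(4, 0.3))
        e = mr_raps(s, overdispersion=False, loss="l2", seed=1)
        assert e.beta == pytest.approx(0.7, abs=1e-6)

    def test_corrects_weak_instrument_dilution(self):
        """With mean F ≈ 12 the profile score removes the IVW attenuation."""
        rng = np.random.default_rng(12)
        theta, reps = 0.3, 200
        raps_b, ivw_b = [], []
        for _ in range(reps):
            k, n_exp = 20, 2603
            maf = rng.uniform(0.1, 0.4, k)
            r2j = 12.0 / n_exp
            gamma = np.sqrt(r2j / (2 * maf * (1 - maf))) * rng.choice([-1, 1], k)
            sx = 1 / np.sqrt(2 * maf * (1 - maf) * n_exp)
            sy = 1 / np.sqrt(2 * maf * (1 - maf) * 33_000)
            s = HarmonizedSet([f"rs{i}" for i in range(k)],
                              rng.normal(gamma, sx), sx,
                              rng.normal(theta * gamma, sy), sy, maf)
            raps_b.append(mr_raps(s, overdispersion=False, loss="l2", seed=1).beta)
            ivw_b.append(ivw(s, model="fixed").beta)
        assert abs(np.mean(raps_b) - theta) < abs(np.mean(ivw_b) - theta)
        assert abs(np.mean(ivw_b) - theta) > 0.01  # dilution is real

    def test_huber_overdispersion_variant_runs(self):
        rng = np.random.default_rng(13)
        s = _random_set(rng, k=15)
        e = mr_raps(s, overdispersion=True, loss="huber", seed=1)
        assert e.computed and e.se > 0

    def test_below_three_snps_not_computed(self, make_set):
        assert not mr_raps(make_set([0.1, 0.2], [0.02, 0.04]), seed=1).computed


class TestCochranQMr:
    def test_equal_ratios_give_zero(self, make_set):
        bx = np.array([0.1, 0.2, 0.3])
        q = cochran_q_mr(make_set(bx, 0.5 * bx))
        assert q.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_hand_arithmetic(self, make_set):
        # ratios 0 and 1 with unit ratio SEs: bx = 1, sy = 1
        s = make_set([1.0, 1.0], [0.0, 1.0], sy=[1.0, 1.0])
        q = cochran_q_mr(s)
        assert q.q_stat == pytest.approx(0.5) and q.df == 1

    def test_single_snp_not_computed(self, make_set):
        assert not cochran_q_mr(make_set([0.1], [0.05])).computed

    def test_null_distribution_matches_chi_square(self):
        from scipy import stats
        rng = np.random.default_rng(14)
        k, reps = 15, 2000
        qs = []
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.4, k)
            sy = rng.uniform(0.01, 0.05, k)
            s = HarmonizedSet([f"r{i}" for i in range(k)], bx, np.full(k, 1e-6),
                              rng.normal(0.2 * bx, sy), sy, np.full(k, 0.3))
            qs.append(cochran_q_mr(s).q_stat)
        assert stats.kstest(qs, stats.chi2(k - 1).cdf).pvalue > 0.01


class TestLeaveOneOut:
    def test_identical_snps_leave_estimate_unchanged(self, make_set):
        s = make_set([0.2, 0.2, 0.2], [0.05, 0.05, 0.05])
        res = leave_one_out(s)
        betas = {e.beta for e in res}
        assert len(res) == 4
        assert max(betas) - min(betas) < 1e-12

    def test_outlier_omission_causes_largest_shift(self, make_set):
        bx = np.array([0.2, 0.25, 0.3, 0.35, 0.2])
        by = 0.4 * bx
        by[2] += 0.5  # gross outlier
        res = leave_one_out(make_set(bx, by))
        full = next(e for e in res if e.label == "all").beta
        shifts = {e.label: abs(e.beta - full) for e in res if e.label != "all"}
        assert max(shifts, key=shifts.get) == "rs2"

    def test_cardinality(self, make_set):
        s = make_set([0.1, 0.2, 0.3, 0.4], [0.03, 0.06, 0.09, 0.12])
        res = leave_one_out(s)
        assert len(res) == 5
        assert sorted(e.label for e in res) == sorted(s.snp_ids + ["all"])


class TestOddsRatioConversion:
    def test_null_beta(self):
        assert to_odds_ratio(0.0, 0.1)[0] == pytest.approx(1.0)

    def test_monotone_ci(self):
        o, lo, hi = to_odds_ratio(np.log(0.91), 0.028)
        assert lo < o < hi and o == pytest.approx(0.91)

    def test_round_trip(self):
        o, _, _ = to_odds_ratio(0.37, 0.1)
        assert np.log(o) == pytest.approx(0.37)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.0)


@st.composite
def harmonized_sets(draw):
    k = draw(st.integers(4, 10))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
    return HarmonizedSet([f"rs{i}" for i in range(k)], bx,
                         rng.uniform(0.005, 0.02, k),
                         rng.normal(0.2 * bx, 0.02), rng.uniform(0.01, 0.05, k),
                         np.full(k, 0.3))


@given(harmonized_sets(), st.sampled_from([0.5, 2.0, -1.5]))
@settings(max_examples=25, deadline=None)
def test_scale_equivariance_of_estimators(s, c):
    """Rescaling the exposure by c divides every causal estimate by c."""
    s2 = HarmonizedSet(s.snp_ids, c * s.bx, abs(c) * s.sx, s.by, s.sy, s.eaf)
    assert ivw(s2, model="fixed").beta == pytest.approx(ivw(s, model="fixed").beta / c)
    assert (weighted_median(s2, n_boot=10, seed=1).beta
            == pytest.approx(weighted_median(s, n_boot=10, seed=1).beta / c))
    assert (mr_raps(s2, overdispersion=False, loss="l2", seed=1).beta
            == pytest.approx(mr_raps(s, overdispersion=False, loss="l2", seed=1).beta / c,
                             abs=1e-7))


@given(harmonized_sets())
@settings(max_examples=25, deadline=None)
def test_outcome_sign_equivariance(s):
    """Negating all outcome effects negates estimates and preserves Q."""
    s2 = HarmonizedSet(s.snp_ids, s.bx, s.sx, -s.by, s.sy, s.eaf)
    assert ivw(s2, model="fixed").beta == pytest.approx(-ivw(s, model="fixed").beta)
    assert cochran_q_mr(s2).q_stat == pytest.approx(cochran_q_mr(s).q_stat)
    sl2, ic2 = mr_egger(s2)
    sl, ic = mr_egger(s)
    assert sl2.beta == pytest.approx(-sl.beta)
    assert ic2.beta == pytest.approx(-ic.beta)
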