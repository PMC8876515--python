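import numpy as np
import pytest
from scipy import stats

from mrkit.estimators import (
    MrEstimate,
    Z95,
    ivw,
    mr_egger,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
)
from mrkit.synthetic_data import SimulationConfig, simulate_dataset
from mrkit.summary_io import harmonize
from tests.conftest import make_instruments, random_instruments


def origin_wls_oracle(bx, by, sy):
    """Independent origin-constrained WLS slope via lstsq on scaled data."""
    sw = 1.0 / np.asarray(sy)
    sol, *_ = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)
    return float(sol[0])


class TestWaldRatios:
    def test_direct_arithmetic(self):
        inst = make_instruments([0.02, 0.04], [0.003, 0.003],
                                [-0.01, 0.0], [0.03, 0.03])
        ratios = wald_ratios(inst)
        assert ratios[0].theta == pytest.approx(-0.5)
        assert ratios[0].se == pytest.approx(1.5)
        assert ratios[1].theta == 0.0

    def test_sign_flip_symmetry(self):
        a = make_instruments([0.02], [0.003], [-0.01], [0.03])
        b = make_instruments([-0.02], [0.003], [0.01], [0.03])
        assert wald_ratios(a)[0].theta == wald_ratios(b)[0].theta

    def test_zero_exposure_beta_names_snp(self):
        inst = make_instruments([0.0, 0.02], [0.003] * 2, [0.01] * 2, [0.03] * 2)
        with pytest.raises(ValueError, match="rs0000"):
            wald_ratios(inst)


class TestIvw:
    def test_degenerate_identical_ratios(self):
        inst = make_instruments([0.02, 0.04], [0.003] * 2,
                                [0.006, 0.012], [0.03, 0.03])
        est = ivw(inst, model="fixed")
        assert est.theta == pytest.approx(0.3)
        # Q = 0 -> random-effects SE equals fixed SE
        assert ivw(inst, model="random").se == est.se

    def test_duplicated_copies_shrink_se(self):
        one = make_instruments([0.02, 0.021], [0.003] * 2, [0.006, 0.0063], [0.03] * 2)
        j = 4
        many = make_instruments([0.02, 0.021] * j, [0.003] * 2 * j,
                                [0.006, 0.0063] * j, [0.03] * 2 * j)
        assert ivw(many, "fixed").theta == pytest.approx(ivw(one, "fixed").theta)
        assert ivw(many, "fixed").se == pytest.approx(ivw(one, "fixed").se / np.sqrt(j))

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            inst = random_instruments(rng)
            bx, _, by, sy = inst.arrays()
            assert ivw(inst, "fixed").theta == pytest.approx(
                origin_wls_oracle(bx, by, sy), abs=1e-10)

    def test_point_estimate_same_under_both_models(self, rng):
        inst = random_instruments(rng)
        assert ivw(inst, "fixed").theta == ivw(inst, "random").theta

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(10):
            inst = random_instruments(rng)
            assert ivw(inst, "random").se >= ivw(inst, "fixed").se

    def test_subset_sign_flip_invariance(self, rng):
        inst = random_instruments(rng, j=10)
        t = inst.table.copy()
        flip = [0, 3, 7]
        t.loc[flip, ["beta_exposure", "beta_outcome"]] *= -1
        flipped = make_instruments(
            t["beta_exposure"], t["se_exposure"], t["beta_outcome"], t["se_outcome"])
        assert ivw(flipped, "fixed").theta == pytest.approx(
            ivw(inst, "fixed").theta, abs=1e-12)

    def test_requires_two_instruments(self):
        inst = make_instruments([0.02], [0.003], [0.01], [0.03])
        with pytest.raises(ValueError, match="wald_ratios"):
            ivw(inst)

    def test_invalid_model_name(self, rng):
        with pytest.raises(ValueError):
            ivw(random_instruments(rng), model="bayesian")


class TestWeightedMedian:
    def test_median_of_equal_weights(self):
        # ratios (1, 2, 9) with equal weights -> interpolated median 2
        inst = make_instruments([0.02] * 3, [0.003] * 3,
                                [0.02, 0.04, 0.18], [0.03] * 3)
        est = weighted_median(inst, n_boot=200, seed=0)
        assert est.theta == pytest.approx(2.0)

    def test_all_equal_ratios(self):
        inst = make_instruments([0.02, 0.03, 0.04], [1e-5] * 3,
                                [0.01, 0.015, 0.02], [1e-5] * 3)
        est = weighted_median(inst, n_boot=500, seed=1)
        assert est.theta == pytest.approx(0.5)
        assert est.se < 1e-3  # tight inputs: bootstrap scatter collapses

    def test_equal_weights_match_unweighted_median_odd_j(self, rng):
        j = 9
        theta_j = np.sort(rng.normal(0, 1, j))
        inst = make_instruments(np.full(j, 0.02), np.full(j, 0.003),
                                0.02 * theta_j, np.full(j, 0.03))
        est = weighted_median(inst, n_boot=200, seed=0)
        # interpolation convention pulls toward the two central ratios
        lo, hi = np.sort(theta_j)[[j // 2 - 1, j // 2 + 1]]
        assert lo <= est.theta <= hi
        assert est.theta == pytest.approx(np.median(theta_j), abs=(hi - lo))

    def test_tolerates_30pct_invalid_instruments(self):
        cfg = SimulationConfig(
            j=50, theta_true=0.2, r2_target=0.02, seed=77,
            pleiotropy_mode="directional", mu_alpha=0.05, tau_alpha=0.005,
            invalid_fraction=0.3, n_outcome=200_000,
        )
        exposure, outcome, _, truth = simulate_dataset(cfg)
        inst = harmonize(exposure, outcome)
        wm = weighted_median(inst, n_boot=1000, seed=5)
        est_ivw = ivw(inst)
        assert abs(wm.theta - 0.2) < 3 * wm.se
        assert abs(est_ivw.theta - 0.2) > 3 * est_ivw.se  # IVW biased away

    def test_needs_three_instruments(self):
        inst = make_instruments([0.02, 0.03], [0.003] * 2, [0.01] * 2, [0.03] * 2)
        with pytest.raises(ValueError):
            weighted_median(inst)

    def test_low_n_boot_flagged(self):
        inst = make_instruments([0.02] * 3, [0.003] * 3,
                                [0.02, 0.04, 0.18], [0.03] * 3)
        est = weighted_median(inst, n_boot=50, seed=0)
        assert "low_n_boot" in est.method

    def test_seed_reproducibility(self, rng):
        inst = random_instruments(rng)
        a = weighted_median(inst, n_boot=300, seed=9)
        b = weighted_median(inst, n_boot=300, seed=9)
        assert a.se == b.se


class TestMrEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        a, b = 0.004, -0.6
        by = a + b * bx
        inst = make_instruments(bx, np.full(5, 0.003), by, np.full(5, 0.03))
        res = mr_egger(inst)
        assert res.intercept == pytest.approx(a, abs=1e-12)
        assert res.slope.theta == pytest.approx(b, abs=1e-12)

    def test_orientation_rule_invariance(self):
        # after orienting to positive exposure betas this is the exact line
        # by' = 0.002 + 0.5 * bx'
        bx = np.array([0.01, -0.02, 0.03, -0.04, 0.05])
        by = 0.5 * bx + 0.002 * np.sign(bx)
        inst = make_instruments(bx, np.full(5, 0.003), by, np.full(5, 0.03))
        res = mr_egger(inst)
        assert res.slope.theta == pytest.approx(0.5, abs=1e-10)
        assert res.intercept == pytest.approx(0.002, abs=1e-10)

    def test_balanced_pleiotropy_intercept_size(self):
        """Under a true zero intercept the intercept test rejects ~5%."""
        root = np.random.SeedSequence(314)
        rejections = 0
        n_reps = 1000
        for child in root.spawn(n_reps):
            r = np.random.default_rng(child)
            j = 30
            bx = r.uniform(0.01, 0.05, j)
            sy = np.full(j, 0.02)
            alpha_j = r.normal(0.0, 0.01, j)  # balanced: mean zero
            by = 0.3 * bx + alpha_j + r.normal(0, sy)
            inst = make_instruments(bx, np.full(j, 0.003), by, sy)
            res = mr_egger(inst)
            rejections += res.intercept_pval < 0.05
        assert 0.025 <= rejections / n_reps <= 0.085

    def test_directional_pleiotropy_recovered(self):
        """Intercept recovers the planted mean direct effect; IVW is biased."""
        root = np.random.SeedSequence(2718)
        intercepts, ivw_thetas = [], []
        n_reps = 200
        for child in root.spawn(n_reps):
            r = np.random.default_rng(child)
            j = 40
            bx = r.uniform(0.01, 0.05, j)
            sy = np.full(j, 0.01)
            alpha_j = r.normal(0.02, 0.005, j)
            by = 0.3 * bx + alpha_j + r.normal(0, sy)
            inst = make_instruments(bx, np.full(j, 0.003), by, sy)
            intercepts.append(mr_egger(inst).intercept)
            ivw_thetas.append(ivw(inst, "fixed").theta)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(n_reps)
        assert abs(np.mean(intercepts) - 0.02) < 4 * mc_se
        assert np.mean(ivw_thetas) > 0.3 + 0.1  # IVW absorbs the pleiotropy

    def test_collinear_design_rejected(self):
        inst = make_instruments([0.02] * 4, [0.003] * 4,
                                [0.01, 0.011, 0.009, 0.0105], [0.03] * 4)
        with pytest.raises(ValueError, match="collinear"):
            mr_egger(inst)

    def test_needs_three_instruments(self):
        inst = make_instruments([0.02, 0.03], [0.003] * 2, [0.01] * 2, [0.03] * 2)
        with pytest.raises(ValueError):
            mr_egger(inst)


class TestOddsRatio:
    def test_null_theta(self):
        est = MrEstimate("ivw_fixed", 0.0, 0.1, -0.196, 0.196, 1.0, 5, 1.0, 0.0, 0.0)
        assert to_odds_ratio(est).odds_ratio == pytest.approx(1.0)

    def test_paper_scale_back_transform(self):
        # theta chosen so the OR CI rounds to the published 0.54 (0.41-0.71)
        theta = -0.616
        se = (0.892 - 0.342) / (2 * Z95)
        est = MrEstimate("ivw_fixed", theta, se, theta - Z95 * se, theta + Z95 * se,
                         1e-5, 111, np.nan, np.nan, np.nan)
        out = to_odds_ratio(est)
        assert round(out.odds_ratio, 2) == 0.54
        assert round(out.or_ci_low, 2) == 0.41
        assert round(out.or_ci_high, 2) == 0.71

    def test_reciprocal_symmetry(self, rng):
        for theta in rng.normal(0, 1, 20):
            a = MrEstimate("m", theta, 0.1, theta - 0.2, theta + 0.2, 0.5, 3,
                           np.nan, np.nan, np.nan)
            b = MrEstimate("m", -theta, 0.1, -theta - 0.2, -theta + 0.2, 0.5, 3,
                           np.nan, np.nan, np.nan)
            assert to_odds_ratio(a).odds_ratio * to_odds_ratio(b).odds_ratio == \
                pytest.approx(1.0)

    def test_ci_endpoints_are_exp_of_theta_ci(self, rng):
        inst = random_instruments(rng)
        est = ivw(inst)
        assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))
        assert est.or_ci_high == pytest.approx(np.exp(est.ci_high))
        assert est.ci_low < est.ci_high


class TestEstimateInvariants:
    def test_pval_consistent_with_z(self, rng):
        inst = random_instruments(rng)
        est = ivw(inst, "fixed")
        z = abs(est.theta) / est.se
        assert est.pval == pytest.approx(2 * stats.norm.sf(z))
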