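import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit.estimators import (
    EstimationError,
    egger,
    heterogeneity,
    ivw,
    mr_raps,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from mrkit.instruments import HarmonizedData
from mrkit.simulate import SimConfig, simulate_gwas_pair
from mrkit.instruments import harmonize


class TestWaldRatios:
    @pytest.mark.parametrize(
        "bexp,bout,seout,ratio,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (2.0, 0.5, 0.1, 0.25, 0.05), (-1.0, 0.5, 0.1, -0.5, 0.1)],
    )
    def test_first_order(self, make_hd, bexp, bout, seout, ratio, se):
        wr = wald_ratios(make_hd([bexp, 1.0], [bout, 0.1], seout))
        assert wr.ratio[0] == pytest.approx(ratio)
        assert wr.ratio_se[0] == pytest.approx(se)

    def test_zero_exposure_effect_excluded(self, make_hd):
        wr = wald_ratios(make_hd([0.0, 1.0], [0.1, 0.1], 0.1))
        assert len(wr) == 1


class TestIvw:
    def test_degenerate_two_identical(self, make_hd):
        h = make_hd([1.0, 1.0], [0.4, 0.4], 1.0)
        assert ivw(h).beta == pytest.approx(0.4)

    def test_weighted_mean_oracle(self, make_hd):
        # unit weights: beta = 0.4, fixed se = 1/sqrt(2)
        h = make_hd([1.0, 1.0], [0.5, 0.3], 1.0)
        est = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.4, rel=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(2), rel=1e-12)

    def test_equals_zero_intercept_wls(self, make_hd):
        rng = np.random.default_rng(1)
        bexp = rng.normal(0.1, 0.03, 12)
        bout = 0.3 * bexp + rng.normal(0, 0.02, 12)
        seout = rng.uniform(0.01, 0.05, 12)
        h = make_hd(bexp, bout, seout)
        wls = sm.WLS(bout, bexp, weights=1.0 / seout**2).fit()
        assert ivw(h).beta == pytest.approx(float(wls.params[0]), abs=1e-10)

    def test_needs_two_instruments(self, make_hd):
        with pytest.raises(EstimationError):
            ivw(make_hd([1.0], [0.5], 0.1))

    def test_random_effects_never_deflates(self, make_hd):
        h = make_hd([1.0, 1.0, 1.0], [0.5, 0.3, 0.41], 1.0)
        assert ivw(h).se >= ivw(h, model="fixed").se


class TestEgger:
    def test_three_point_closed_form(self, make_hd):
        # unit weights through (1,1),(2,1.5),(3,2): exact line y = 0.5 + 0.5x
        h = make_hd([1.0, 2.0, 3.0], [1.0, 1.5, 2.0], 1.0)
        est = egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.5, abs=1e-10)

    def test_proportional_gives_zero_intercept(self, make_hd):
        h = make_hd([1.0, 2.0, 3.0], [0.7, 1.4, 2.1], 1.0)
        est = egger(h)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)
        assert est.beta == pytest.approx(0.7, abs=1e-10)

    def test_orientation_invariance(self, make_hd):
        # negating an exposure effect (and its outcome effect) is a relabeling
        h1 = make_hd([1.0, 2.0, 3.0], [1.0, 1.5, 2.0], 1.0)
        h2 = make_hd([1.0, -2.0, 3.0], [1.0, -1.5, 2.0], 1.0)
        assert egger(h2).beta == pytest.approx(egger(h1).beta, abs=1e-12)
        assert egger(h2).intercept == pytest.approx(egger(h1).intercept, abs=1e-12)

    def test_needs_three(self, make_hd):
        with pytest.raises(EstimationError):
            egger(make_hd([1.0, 2.0], [1.0, 1.5], 1.0))


class TestWeightedMedian:
    def test_all_equal(self, make_hd):
        h = make_hd([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], 0.1)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_interpolation_oracle(self, make_hd):
        # equal weights on ratios {0.1, 0.2, 0.9}: s = {1/6, 1/2, 5/6} hits 0.5 at 0.2
        h = make_hd([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], 1.0)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.2, abs=1e-12)

    def test_bootstrap_reproducible(self, make_hd):
        h = make_hd([1.0, 1.0, 1.0, 1.0], [0.1, 0.2, 0.3, 0.9], 0.2)
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_equal(self, make_hd):
        h = make_hd([1.0, 1.0, 1.0], [0.5, 0.5, 0.5], 0.1)
        assert weighted_mode(h, n_boot=10, seed=0).beta == pytest.approx(0.5)

    def test_majority_cluster(self, make_hd):
        h = make_hd([1.0, 1.0, 1.0], [0.5, 0.5, 3.0], 0.1)
        assert weighted_mode(h, n_boot=10, seed=0).beta == pytest.approx(0.5, abs=0.05)

    def test_large_bandwidth_approaches_weighted_mean(self, make_hd):
        bout = np.array([0.1, 0.3, 0.5, 0.9])
        h = make_hd(np.ones(4), bout, 0.1)
        est = weighted_mode(h, phi=1e3, n_boot=10, seed=0)
        assert est.beta == pytest.approx(np.mean(bout), abs=0.02)


class TestMrRaps:
    def test_reduces_to_fixed_ivw_without_exposure_noise(self, make_hd):
        rng = np.random.default_rng(4)
        bexp = rng.normal(0.1, 0.02, 20)
        bout = 0.25 * bexp + rng.normal(0, 0.01, 20)
        seout = rng.uniform(0.005, 0.02, 20)
        h = make_hd(bexp, bout, seout, se_exp=1e-12)
        assert mr_raps(h, loss="l2").beta == pytest.approx(
            ivw(h, model="fixed").beta, abs=1e-8
        )

    def test_simulation_truth_recovery(self):
        ests = []
        for s in range(20):
            e, o, _ = simulate_gwas_pair(
                SimConfig(n_snps=200, true_slope=0.2, exposure_h2=0.05, n_exp=500_000, n_out=100_000, seed=400 + s)
            )
            h = harmonize(e, o, list(e.table["snp_id"]))
            ests.append(mr_raps(h).beta)
        mc_se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.2) < 3 * mc_se

    def test_tukey_more_robust_than_l2_with_outliers(self):
        e, o, _ = simulate_gwas_pair(
            SimConfig(
                n_snps=100,
                true_slope=0.2,
                exposure_h2=0.05,
                n_exp=500_000,
                n_out=100_000,
                pleiotropy="directional",
                pleiotropy_mean=0.05,
                pleiotropy_sd=0.0,
                invalid_fraction=0.05,
                seed=77,
            )
        )
        h = harmonize(e, o, list(e.table["snp_id"]))
        bias_l2 = abs(mr_raps(h, loss="l2").beta - 0.2)
        bias_tk = abs(mr_raps(h, loss="tukey").beta - 0.2)
        assert bias_tk < bias_l2

    def test_overdispersion_estimated_under_balanced_pleiotropy(self):
        e, o, _ = simulate_gwas_pair(
            SimConfig(
                n_snps=150,
                true_slope=0.2,
                exposure_h2=0.05,
                n_exp=500_000,
                n_out=100_000,
                pleiotropy="balanced",
                pleiotropy_sd=0.02,
                invalid_fraction=1.0,
                seed=5,
            )
        )
        h = harmonize(e, o, list(e.table["snp_id"]))
        est = mr_raps(h, loss="l2", overdispersion=True)
        assert est.diagnostics["tau2"] > 0
        assert est.beta == pytest.approx(0.2, abs=0.05)


class TestHeterogeneity:
    def test_identical_ratios(self, make_hd):
        h = make_hd([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], 1.0)
        het = heterogeneity(h)
        assert het["cochran_q"]["Q"] == pytest.approx(0.0, abs=1e-20)
        assert het["cochran_q"]["p"] == pytest.approx(1.0)

    def test_arithmetic_oracle(self, make_hd):
        h = make_hd([1.0, 1.0], [0.5, 0.3], 1.0)
        het = heterogeneity(h)
        assert het["cochran_q"]["Q"] == pytest.approx(0.02, rel=1e-12)
        assert het["cochran_q"]["df"] == 1
        assert het["cochran_q"]["p"] == pytest.approx(stats.chi2.sf(0.02, 1), rel=1e-12)
        assert het["cochran_q"]["p"] == pytest.approx(0.888, abs=5e-4)

    def test_rucker_never_exceeds_cochran(self, make_hd):
        rng = np.random.default_rng(9)
        for _ in range(10):
            k = rng.integers(4, 12)
            h = make_hd(
                rng.normal(0.1, 0.05, k), rng.normal(0.02, 0.05, k), rng.uniform(0.01, 0.1, k)
            )
            het = heterogeneity(h)
            assert het["rucker_q"]["Q"] <= het["cochran_q"]["Q"] + 1e-10


class TestToOddsRatio:
    def test_null_effect(self):
        assert to_odds_ratio(0.0, 0.1)[0] == pytest.approx(1.0)

    def test_degenerate_ci(self):
        orv, lo, hi = to_odds_ratio(np.log(2.0), 0.0)
        assert orv == pytest.approx(2.0) and lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_ci_oracle(self):
        z = stats.norm.ppf(0.975)
        _, lo, hi = to_odds_ratio(0.2, 0.1, 0.95)
        assert lo == pytest.approx(np.exp(0.2 - z * 0.1), rel=1e-12)
        assert hi == pytest.approx(np.exp(0.2 + z * 0.1), rel=1e-12)
        assert lo == pytest.approx(np.exp(0.004), abs=1e-4)
        assert hi == pytest.approx(np.exp(0.396), abs=1e-4)


class TestEquivariance:
    def _methods(self, h, seed=3):
        return {
            "ivw": ivw(h).beta,
            "egger": egger(h).beta,
            "median": weighted_median(h, n_boot=10, seed=seed).beta,
            "raps": mr_raps(h).beta,
        }

    def test_negating_outcome_negates_estimates(self, make_hd):
        rng = np.random.default_rng(11)
        bexp = rng.normal(0.1, 0.02, 10)
        bout = 0.3 * bexp + rng.normal(0, 0.01, 10)
        seout = rng.uniform(0.01, 0.03, 10)
        pos = self._methods(make_hd(bexp, bout, seout))
        neg = self._methods(make_hd(bexp, -bout, seout))
        for k in pos:
            assert neg[k] == pytest.approx(-pos[k], rel=1e-6, abs=1e-9), k

    def test_rescaling_exposure_inversely_rescales_estimates(self, make_hd):
        rng = np.random.default_rng(12)
        bexp = rng.normal(0.1, 0.02, 10)
        bout = 0.3 * bexp + rng.normal(0, 0.01, 10)
        seout = rng.uniform(0.01, 0.03, 10)
        c = 2.5
        base = self._methods(make_hd(bexp, bout, seout))
        scaled = self._methods(make_hd(c * bexp, bout, seout, se_exp=0.01 * c))
        for k in base:
            assert scaled[k] == pytest.approx(base[k] / c, rel=1e-6, abs=1e-9), k
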