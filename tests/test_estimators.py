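import numpy as np
import pytest

import mrmediate as mm
from mrmediate.estimators import (METHODS_FIVE, _weighted_median_point,
                                  run_all_methods, wald_ratio_arrays)

from conftest import make_harmonized


class TestWaldRatio:
    def test_basic_ratio_and_se(self):
        r, s = wald_ratio_arrays([0.2], [0.02], [0.05], [0.01])
        assert r[0] == pytest.approx(0.25)
        assert s[0] == pytest.approx(0.01 / 0.2)

    def test_second_order_se_is_larger(self):
        _, s1 = wald_ratio_arrays([0.2], [0.02], [0.05], [0.01])
        _, s2 = wald_ratio_arrays([0.2], [0.02], [0.05], [0.01],
                                  second_order=True)
        assert s2[0] > s1[0]

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio_arrays([0.0], [0.02], [0.05], [0.01])


class TestIVW:
    def test_matches_precision_weighted_mean_of_ratios(self):
        # ratios 0.4 (w=100) and 0.6 (w=25): pooled (0.4*100+0.6*25)/125
        h = make_harmonized([1.0, 1.0], [1e-6, 1e-6], [0.4, 0.6],
                            [0.1, 0.2])
        res = mm.ivw(h, model="fixed")
        assert res.beta == pytest.approx(0.44)
        assert res.se == pytest.approx(np.sqrt(1 / 125))

    def test_fixed_equals_general_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            k = rng.integers(3, 6)
            bx = rng.uniform(0.1, 0.5, k)
            by = rng.normal(0.3 * bx, 0.05)
            sy = rng.uniform(0.02, 0.1, k)
            h = make_harmonized(bx, np.full(k, 1e-8), by, sy)
            ratios, rse = wald_ratio_arrays(bx, np.zeros(k), by, sy)
            w = 1 / rse**2
            oracle = np.sum(w * ratios) / np.sum(w)
            assert mm.ivw(h, model="fixed").beta == pytest.approx(oracle)

    def test_random_effects_never_narrower_than_fixed(self, clean_harmonized):
        fx = mm.ivw(clean_harmonized, model="fixed")
        rnd = mm.ivw(clean_harmonized, model="random")
        assert rnd.beta == pytest.approx(fx.beta)
        assert rnd.se >= fx.se

    def test_consensus_ratio_recovered_exactly(self):
        h = make_harmonized([0.2, 0.3, 0.4], [0.01] * 3,
                            [0.1, 0.15, 0.2], [0.01, 0.02, 0.03])
        assert mm.ivw(h).beta == pytest.approx(0.5)

    def test_single_snp_downgrades_to_wald(self):
        h = make_harmonized([0.2], [0.02], [0.05], [0.01])
        res = mm.ivw(h)
        assert res.extra["downgraded_to"] == "WaldRatio"
        assert res.beta == pytest.approx(0.25)

    def test_or_and_ci_from_log_odds(self):
        h = make_harmonized([1.0, 1.0], [1e-6, 1e-6], [-0.053, -0.053],
                            [0.01, 0.01])
        res = mm.ivw(h)
        assert round(res.or_point, 3) == 0.948
        assert res.ci_low < res.or_point < res.ci_high

    def test_invalid_model_rejected(self, clean_harmonized):
        with pytest.raises(ValueError):
            mm.ivw(clean_harmonized, model="bogus")


class TestEgger:
    def test_recovers_slope_and_intercept_on_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.02 + 0.5 * bx
        h = make_harmonized(bx, [0.01] * 5, by, [0.01] * 5)
        res = mm.egger(h)
        assert res.beta == pytest.approx(0.5, abs=1e-8)
        assert res.extra["intercept"] == pytest.approx(0.02, abs=1e-8)

    def test_orientation_to_positive_exposure_frame(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4, 0.5])
        by = 0.02 * np.sign(bx) + 0.5 * bx
        h = make_harmonized(bx, [0.01] * 5, by, [0.01] * 5)
        res = mm.egger(h)
        assert res.beta == pytest.approx(0.5, abs=1e-8)
        assert res.extra["intercept"] == pytest.approx(0.02, abs=1e-8)

    def test_zero_intercept_matches_ivw_closely(self, clean_harmonized):
        eg = mm.egger(clean_harmonized)
        iv = mm.ivw(clean_harmonized)
        # same data, unconstrained intercept near zero: slopes agree within
        # the wider Egger interval
        assert abs(eg.beta - iv.beta) < 2 * eg.se

    def test_degenerate_design_rejected(self):
        h = make_harmonized([0.2] * 4, [0.01] * 4, [0.1, 0.11, 0.09, 0.1],
                            [0.01] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            mm.egger(h)

    def test_too_few_snps_rejected(self):
        h = make_harmonized([0.2, 0.3], [0.01] * 2, [0.1, 0.15], [0.01] * 2)
        with pytest.raises(ValueError):
            mm.egger(h)


class TestWeightedMedian:
    def test_point_is_middle_ratio_with_equal_weights(self):
        p = _weighted_median_point(np.array([0.1, 0.5, 0.9]),
                                   np.array([1.0, 1.0, 1.0]))
        assert p == pytest.approx(0.5)

    def test_equal_weights_match_ordinary_median(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            r = rng.normal(size=9)
            p = _weighted_median_point(r, np.ones(9))
            assert p == pytest.approx(np.median(r))

    def test_dominant_weight_pulls_estimate(self):
        p = _weighted_median_point(np.array([0.1, 0.5, 0.9]),
                                   np.array([10.0, 1.0, 1.0]))
        assert p < 0.5

    def test_estimator_on_consensus_data(self):
        h = make_harmonized([0.2, 0.3, 0.4], [0.01] * 3,
                            [0.1, 0.15, 0.2], [0.01, 0.02, 0.03])
        res = mm.weighted_median(h, n_boot=200, seed=0)
        assert res.beta == pytest.approx(0.5)

    def test_seed_reproducibility(self, clean_harmonized):
        a = mm.weighted_median(clean_harmonized, n_boot=100, seed=9)
        b = mm.weighted_median(clean_harmonized, n_boot=100, seed=9)
        assert a.beta == b.beta and a.se == b.se


class TestModeEstimators:
    def _bimodal(self):
        # 7 SNPs share ratio 0.2, 3 share 0.8 -> mode should pick 0.2
        bx = np.full(10, 0.3)
        bx += np.linspace(0, 0.05, 10)  # avoid degenerate identical design
        ratios = np.array([0.2] * 7 + [0.8] * 3)
        by = ratios * bx
        return make_harmonized(bx, [0.01] * 10, by, [0.01] * 10)

    def test_mode_picks_largest_cluster(self):
        res = mm.mode_estimate(self._bimodal(), weighted=True, n_boot=50,
                               seed=1)
        assert abs(res.beta - 0.2) < 0.1

    def test_simple_mode_also_picks_largest_cluster(self):
        res = mm.mode_estimate(self._bimodal(), weighted=False, n_boot=50,
                               seed=1)
        assert abs(res.beta - 0.2) < 0.1

    def test_consensus_data_recovered(self):
        h = make_harmonized([0.2, 0.3, 0.4, 0.5], [0.01] * 4,
                            [0.06, 0.09, 0.12, 0.15], [0.01] * 4)
        res = mm.mode_estimate(h, n_boot=50, seed=0)
        assert res.beta == pytest.approx(0.3, abs=0.02)


class TestEquivariance:
    def test_exposure_unit_rescaling(self, clean_harmonized):
        """Rescaling the exposure by c divides every causal estimate by c."""
        c = 2.5
        k = clean_harmonized.kept_table
        scaled = k.copy()
        scaled["beta_exposure"] *= c
        scaled["se_exposure"] *= c
        for fn in (lambda d: mm.ivw(d),
                   lambda d: mm.egger(d),
                   lambda d: mm.weighted_median(d, n_boot=100, seed=4),
                   lambda d: mm.mode_estimate(d, n_boot=50, seed=4)):
            assert fn(scaled).beta * c == pytest.approx(fn(k).beta, rel=1e-6)


class TestBattery:
    def test_clean_battery_complete_and_concordant(self, clean_harmonized):
        b = run_all_methods(clean_harmonized, n_boot=100, seed=0)
        assert set(b.results) == set(METHODS_FIVE)
        assert b.direction_concordant
        assert not b.errors

    def test_two_snp_battery_flagged_incomplete(self):
        h = make_harmonized([0.2, 0.3], [0.01] * 2, [0.1, 0.15], [0.01] * 2)
        b = run_all_methods(h, n_boot=50, seed=0)
        assert "IVW" in b.results
        assert "Egger" in b.errors
        assert not b.direction_concordant
        assert b.concordance_reason == "incomplete battery"

    def test_bwmr_included_on_request(self, clean_harmonized):
        b = run_all_methods(clean_harmonized, n_boot=50, seed=0,
                            include_bwmr=True,
                            bwmr_kwargs={"n_iter": 600})
        assert "BWMR" in b.results

    def test_to_frame_has_all_rows(self, clean_harmonized):
        b = run_all_methods(clean_harmonized, n_boot=50, seed=0)
        df = b.to_frame()
        assert len(df) == 5
        assert {"method", "beta", "se", "pval", "or"} <= set(df.columns)
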