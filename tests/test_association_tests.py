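import numpy as np
import pytest
from scipy import stats

from crgwas.association_tests import (
    FragmentSkipped,
    PermutationPlan,
    build_fragment_design,
    burden_score,
    combined_multivariate_pooled,
    dispatch_fragment_tests,
    lr_test,
    multivariate_test,
    permutation_threshold,
    scale_by_threshold,
    single_snp_scan,
)
from crgwas.core_data import GenotypeMatrix, compute_maf
from crgwas.function_prediction import FrequencyFunctionFit


def make_geno(calls):
    calls = np.asarray(calls, dtype=float)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(calls.shape[0])],
        snp_ids=[f"v{j}" for j in range(calls.shape[1])],
        calls=calls,
    )


PAPER_FIT = FrequencyFunctionFit("power", a=0.3562, b=-1.4162, r_squared=1.0)


class TestLrTest:
    def test_orthogonal_regressor_gives_zero(self):
        res = lr_test(np.array([1.0, -1.0, 1.0, -1.0]),
                      np.array([1.0, 1.0, -1.0, -1.0]))
        assert res.beta1 == pytest.approx(0.0)
        assert res.lr == pytest.approx(0.0)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="inestimable"):
            lr_test(np.arange(5, dtype=float), np.ones(5))

    def test_matches_gaussian_ml_oracle(self):
        """Closed form n ln(RSS0/RSS1) equals -2 (l0 - l1) from independent
        ML fits of the two Gaussian regressions (statsmodels llf)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = rng.integers(8, 30)
            y = rng.standard_normal(n)
            z = rng.standard_normal(n)
            res = lr_test(y, z)
            l1 = sm.OLS(y, sm.add_constant(z)).fit().llf
            l0 = sm.OLS(y, np.ones((n, 1))).fit().llf
            assert res.lr == pytest.approx(2 * (l1 - l0), abs=1e-6)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(13)
        reps = 2000
        rej = 0
        for _ in range(reps):
            y = rng.standard_normal(100)
            z = rng.standard_normal(100)
            rej += lr_test(y, z).p_asymptotic < 0.05
        # binomial 99% CI around 0.05 at 2000 reps: +/- 0.0126
        assert 0.037 <= rej / reps <= 0.063


class TestSingleSnpScan:
    def test_bonferroni_flags_and_skips(self):
        rng = np.random.default_rng(14)
        calls = (rng.random((40, 6)) < 0.3).astype(float)
        calls[:, 5] = 0.0  # monomorphic
        g = make_geno(calls)
        maf = compute_maf(g)
        y = calls[:, 0] * 3.0 + 0.1 * rng.standard_normal(40)
        res = single_snp_scan(y, g, maf, alpha=0.05)
        assert len(res) == 5
        by_unit = {r.unit: r for r in res}
        assert by_unit["v0"].significant
        assert by_unit["v0"].lr == max(r.lr for r in res)

    def test_orientation_invariance_of_lr(self):
        rng = np.random.default_rng(15)
        calls = (rng.random((30, 1)) < 0.4).astype(float)
        g1 = make_geno(calls)
        g2 = make_geno(1.0 - calls)  # flipped coding, reader re-orients
        y = rng.standard_normal(30)
        r1 = single_snp_scan(y, g1, compute_maf(g1))[0]
        r2 = single_snp_scan(y, g2, compute_maf(g2))[0]
        assert r1.lr == pytest.approx(r2.lr, abs=1e-10)


class TestBurdenScore:
    def test_sum_is_mean_count(self):
        calls = np.array([[0, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 1]] * 8,
                         dtype=float)
        g = make_geno(calls)
        maf = np.array([0.01, 0.02, 0.03])
        s = burden_score(g, [0, 1, 2], maf, "sum")
        assert s.z[0] == pytest.approx(2 / 3)
        assert s.m == 3

    def test_weighted_sum_single_carrier(self):
        # n = 100, p = 0.05: weight 1/sqrt(100 * 0.05 * 0.95) = 0.4588
        calls = np.zeros((100, 3))
        calls[0, 0] = 1
        calls[1, 1] = 1
        calls[2, 2] = 1
        g = make_geno(calls)
        maf = np.array([0.05 - 1e-9, 0.01, 0.01])
        s = burden_score(g, [0, 1, 2], np.array([0.0499, 0.01, 0.01]),
                         "weighted_sum")
        w = 1 / np.sqrt(100 * 0.0499 * (1 - 0.0499))
        assert s.z[0] == pytest.approx(w, abs=1e-4)
        assert s.z[0] == pytest.approx(0.4588, abs=5e-3)

    def test_function_aided_contribution(self):
        # S = 2.4277 (probably damaging) at p = 1%: S * p^F = 2.4277 * 0.3562
        calls = np.zeros((100, 3))
        calls[0] = [1, 0, 0]
        calls[1] = [0, 1, 0]
        calls[2] = [0, 0, 1]
        g = make_geno(calls)
        maf = np.array([0.01, 0.01, 0.01])
        s = burden_score(g, [0, 1, 2], maf, "function_aided_sum",
                         s_weights=np.array([2.4277, 0.6772, 0.6772]),
                         fit=PAPER_FIT)
        assert s.z[0] == pytest.approx(2.4277 * 0.3562, abs=1e-4)
        assert s.z[0] == pytest.approx(0.8648, abs=1e-4)

    def test_min_rare_cutoff(self):
        g = make_geno(np.eye(10)[:, :2])
        with pytest.raises(FragmentSkipped, match="insufficient rare"):
            burden_score(g, [0, 1], np.array([0.01, 0.01]), "sum")

    def test_common_snps_excluded(self):
        calls = np.eye(20)[:, :4]
        g = make_geno(calls)
        maf = np.array([0.01, 0.02, 0.03, 0.3])
        s = burden_score(g, [0, 1, 2, 3], maf, "sum")
        assert s.m == 3 and "v3" not in s.snp_ids

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(16)
        calls = (rng.random((20, 4)) < 0.05).astype(float)
        calls[0, :] = 1  # guarantee polymorphism
        g = make_geno(calls)
        maf = np.full(4, 0.03)
        z = burden_score(g, np.arange(4), maf, "sum").z
        perm = rng.permutation(20)
        g2 = GenotypeMatrix(samples=[g.samples[i] for i in perm],
                            snp_ids=g.snp_ids, calls=calls[perm])
        z2 = burden_score(g2, np.arange(4), maf, "sum").z
        np.testing.assert_allclose(z2, z[perm])


class TestMultivariate:
    def test_single_column_reduces_to_lr_test(self):
        rng = np.random.default_rng(17)
        y = rng.standard_normal(50)
        z = rng.standard_normal(50)
        a = lr_test(y, z)
        b = multivariate_test(y, z[:, None])
        assert b.lr == pytest.approx(a.lr, abs=1e-10)
        assert b.df == 1

    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(18)
        y = rng.standard_normal(50)
        z = rng.standard_normal(50)
        res = multivariate_test(y, np.column_stack([z, z]))
        assert res.df == 1

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(19)
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="saturated"):
            multivariate_test(y, rng.standard_normal((10, 9)))

    def test_chi2_calibration_under_null(self):
        rng = np.random.default_rng(20)
        reps = 2000
        rej = 0
        for _ in range(reps):
            y = rng.standard_normal(100)
            v = rng.standard_normal((100, 5))
            rej += multivariate_test(y, v).p_asymptotic < 0.05
        assert 0.037 <= rej / reps <= 0.063


class TestCombined:
    def test_reduces_to_multivariate_without_rares(self):
        rng = np.random.default_rng(21)
        y = rng.standard_normal(60)
        commons = (rng.random((60, 3)) < 0.3).astype(float)
        a = combined_multivariate_pooled(y, commons, None)
        b = multivariate_test(y, commons)
        assert a.lr == pytest.approx(b.lr, abs=1e-10)

    def test_reduces_to_lr_test_without_commons(self):
        rng = np.random.default_rng(22)
        calls = (rng.random((60, 4)) < 0.04).astype(float)
        calls[0] = 1
        g = make_geno(calls)
        pooled = burden_score(g, np.arange(4), np.full(4, 0.03), "weighted_sum")
        y = rng.standard_normal(60)
        a = combined_multivariate_pooled(y, None, pooled)
        b = lr_test(y, pooled.z)
        assert a.lr == pytest.approx(b.lr, abs=1e-10)

    def test_rejects_wrong_pooling_method(self):
        g = make_geno(np.eye(10)[:, :3])
        pooled = burden_score(g, np.arange(3), np.full(3, 0.05 - 1e-6), "sum")
        with pytest.raises(ValueError, match="weighted_sum"):
            combined_multivariate_pooled(np.zeros(10), None, pooled)

    def test_combined_captures_both_signals(self):
        rng = np.random.default_rng(23)
        stronger = 0
        used = 0
        for _ in range(30):
            n = 100
            common = (rng.random(n) < 0.3).astype(float)
            rares = (rng.random((n, 4)) < 0.03).astype(float)
            g = make_geno(np.column_stack([common, rares]))
            maf = compute_maf(g)
            if ((maf[1:] == 0) | (maf[1:] >= 0.05)).any() or maf[0] < 0.05:
                continue
            used += 1
            pooled = burden_score(g, np.arange(1, 5), maf, "weighted_sum")
            y = (0.8 * common + 0.8 * rares.sum(axis=1)
                 + rng.standard_normal(n))
            comb = combined_multivariate_pooled(y, common[:, None], pooled)
            m_common = multivariate_test(y, common[:, None])
            m_pooled = lr_test(y, pooled.z)
            stronger += comb.lr >= max(m_common.lr, m_pooled.lr) * 0.999
        assert used >= 10
        assert stronger / used >= 0.9


class TestDispatch:
    @pytest.mark.parametrize(
        "n_rare,n_common,expected",
        [
            (0, 5, ["multivariate"]),
            (4, 0, ["sum", "weighted_sum", "function_aided_sum"]),
            (2, 3, ["multivariate"]),  # rare tests blocked below the cutoff
            (3, 2, ["sum", "weighted_sum", "function_aided_sum",
                    "combined_multivariate_pooled"]),
            (1, 0, []),
        ],
    )
    def test_rules(self, n_rare, n_common, expected):
        assert dispatch_fragment_tests(n_rare, n_common) == expected


class TestPermutation:
    def _designs(self, rng, n=60, n_frag=15):
        designs = []
        for f in range(n_frag):
            z = rng.standard_normal(n)
            designs.append(build_fragment_design(f"f{f}", "sum", z[:, None]))
        return designs

    def test_same_seed_identical_thresholds(self):
        rng = np.random.default_rng(24)
        designs = self._designs(rng)
        y = rng.standard_normal(60)
        plan = PermutationPlan(n_perm=150, seed=7)
        a = permutation_threshold(y, designs, plan)
        b = permutation_threshold(y, designs, plan)
        assert a.lr99 == b.lr99
        np.testing.assert_array_equal(a.maxima, b.maxima)

    def test_quantile_monotone(self):
        rng = np.random.default_rng(25)
        designs = self._designs(rng)
        y = rng.standard_normal(60)
        lo = permutation_threshold(y, designs,
                                   PermutationPlan(150, 7, quantile=0.90))
        hi = permutation_threshold(y, designs,
                                   PermutationPlan(150, 7, quantile=0.99))
        assert hi.lr99 >= lo.lr99

    def test_experimentwise_error_controlled_on_null(self):
        rng = np.random.default_rng(26)
        n_frag = 40
        exceed = []
        for _ in range(10):
            designs = self._designs(rng, n=50, n_frag=n_frag)
            y = rng.standard_normal(50)
            perm = permutation_threshold(y, designs,
                                         PermutationPlan(200, 3))
            exceed.append((perm.observed_lr > perm.lr99).mean())
        # fragment-level exceedance stays near/below the nominal 1%
        assert np.mean(exceed) <= 0.01 + 2 * np.sqrt(0.01 * 0.99 / n_frag)

    def test_degenerate_distribution(self):
        from crgwas.association_tests import PermutationResult
        maxima = np.full(100, 3.3)
        assert float(np.quantile(maxima, 0.99)) == 3.3


class TestScaleByThreshold:
    def test_boundary_and_floor(self):
        r = lr_test(np.array([1.0, 2.0, 1.5, 0.5, 2.5]),
                    np.array([0.0, 1.0, 1.0, 0.0, 1.0]))
        scale_by_threshold(r, r.lr if r.lr > 0 else 1.0)
        assert r.lr_ratio == pytest.approx(1.0)
        assert r.significant

    def test_invalid_threshold(self):
        r = lr_test(np.arange(5.0), np.array([0, 1, 0, 1, 1.0]))
        with pytest.raises(ValueError):
            scale_by_threshold(r, 0.0)

    def test_ranking_scale_invariance(self):
        rng = np.random.default_rng(27)
        lrs = rng.random(10) * 5
        lr99 = 2.0
        order1 = np.argsort(-lrs / lr99)
        order2 = np.argsort(-(3.0 * lrs) / (3.0 * lr99))
        np.testing.assert_array_equal(order1, order2)
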