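import numpy as np
import pytest
from scipy import optimize, stats

from crgwas.core_data import GenotypeMatrix
from crgwas.structure_adjust import (
    CovariateSet,
    KinshipMatrix,
    estimate_kinship,
    fit_mixed_model,
    grammar_residuals,
    inflation_factor,
    nearest_psd,
    null_covariates,
    pca_covariates,
    select_structure_model,
)
from crgwas.synthetic_data import SimulationSpec, simulate_genotypes


def random_kinship(rng, n):
    """A valid random kinship-like PSD matrix with unit diagonal."""
    b = rng.random((n, max(3, n // 4)))
    k = b @ b.T
    d = np.sqrt(np.diag(k))
    k = k / np.outer(d, d)
    return KinshipMatrix(0.5 * (k + k.T))


def reml_loglik_direct(y, x, k2, sg2, se2):
    """Dense-matrix REML log-likelihood, the independent oracle."""
    n, q = x.shape
    v = sg2 * k2 + se2 * np.eye(n)
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    r = y - x @ beta
    _, ld_v = np.linalg.slogdet(v)
    _, ld_x = np.linalg.slogdet(xvx)
    return -0.5 * ((n - q) * np.log(2 * np.pi) + ld_v + ld_x + r @ vi @ r)


class TestKinship:
    def test_identical_samples_have_kinship_one(self):
        calls = np.array([[0, 1, 0, 1, 1], [0, 1, 0, 1, 1], [1, 0, 1, 0, 0]],
                         dtype=float)
        g = GenotypeMatrix(samples=list("abc"), snp_ids=list("vwxyz"),
                           calls=calls)
        k = estimate_kinship(g).values
        assert k[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(k) == 1.0)

    def test_average_pair_centered_at_zero(self):
        rng = np.random.default_rng(0)
        calls = (rng.random((20, 200)) < 0.3).astype(float)
        g = GenotypeMatrix(samples=[f"s{i}" for i in range(20)],
                          snp_ids=[f"m{j}" for j in range(200)], calls=calls)
        k = estimate_kinship(g).values
        off = k[~np.eye(20, dtype=bool)]
        # rescaling clips at zero, so the off-diagonal mode sits at/near 0
        assert np.median(off) < 0.2

    def test_subpopulation_structure_recovered(self):
        spec = SimulationSpec(seed=9, n_samples=60, n_fragments=40,
                              n_subpops=2, divergence=1.0)
        geno, labels, _ = simulate_genotypes(spec)
        k = estimate_kinship(geno).values
        same = np.equal.outer(labels, labels) & ~np.eye(len(labels), dtype=bool)
        diff = ~np.equal.outer(labels, labels)
        assert k[same].mean() > k[diff].mean()

    def test_too_few_samples(self, tiny_geno):
        g = GenotypeMatrix(samples=["a", "b"], snp_ids=["s"],
                           calls=np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            estimate_kinship(g)


class TestMixedModel:
    def test_ols_equivalence_without_kinship(self):
        rng = np.random.default_rng(1)
        n = 50
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        fit = fit_mixed_model(y, CovariateSet("c", x), use_kinship=False)
        beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)
        assert fit.sigma_g2 == 0.0

    def test_reml_matches_dense_oracle(self):
        """Profile 1-D REML equals a generic 2-D optimizer's solution."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 40
            kin = random_kinship(rng, n)
            k2 = 2 * kin.values
            x = np.column_stack([np.ones(n), rng.standard_normal(n)])
            chol = np.linalg.cholesky(k2 + 1e-8 * np.eye(n))
            y = (x @ rng.normal(0, 1, 2) + chol @ rng.standard_normal(n)
                 + rng.standard_normal(n))
            fit = fit_mixed_model(y, CovariateSet("c", x), kin)

            def neg(params):
                sg2, se2 = np.exp(params)
                return -reml_loglik_direct(y, x, k2, sg2, se2)

            best = min(
                (optimize.minimize(neg, s, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
                 for s in ([0.0, 0.0], [-2.0, 0.5], [1.0, -1.0])),
                key=lambda r: r.fun,
            )
            assert fit.loglik_reml == pytest.approx(-best.fun, rel=1e-4, abs=1e-4)

    def test_null_variance_recovery(self):
        # i.i.d. phenotypes against an identifiable (family-block) kinship:
        # the polygenic variance estimate should collapse to ~0
        n, fam = 200, 10
        k = np.kron(np.eye(n // fam), np.full((fam, fam), 0.5))
        np.fill_diagonal(k, 1.0)
        kin = KinshipMatrix(k)
        rng = np.random.default_rng(3)
        hits = 0
        reps = 60
        for _ in range(reps):
            y = rng.standard_normal(n)
            fit = fit_mixed_model(y, null_covariates(n), kin)
            hits += fit.sigma_g2 <= 0.05 * y.var()
        assert hits / reps >= 0.9

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(4)
        n = 300
        kin = random_kinship(rng, n)
        k2 = nearest_psd(2 * kin.values)
        chol = np.linalg.cholesky(k2 + 1e-10 * np.eye(n))
        sg, se = [], []
        for _ in range(30):
            y = (np.sqrt(2.0) * chol @ rng.standard_normal(n)
                 + rng.standard_normal(n))
            fit = fit_mixed_model(y, null_covariates(n), kin)
            sg.append(fit.sigma_g2)
            se.append(fit.sigma_e2)
        assert np.mean(sg) == pytest.approx(2.0, rel=0.15)
        assert np.mean(se) == pytest.approx(1.0, rel=0.15)


class TestModelSelection:
    def test_structure_covariates_win_when_confounded(self):
        rng = np.random.default_rng(5)
        wins = 0
        reps = 40
        spec = SimulationSpec(seed=20, n_samples=80, n_fragments=30,
                              divergence=1.2)
        geno, labels, _ = simulate_genotypes(spec)
        kin = estimate_kinship(geno)
        cands = [null_covariates(80), pca_covariates(geno, 1)]
        for _ in range(reps):
            y = 1.0 * labels + rng.standard_normal(80)
            best, _ = select_structure_model(y, cands, kin)
            wins += (best.covariates.label != "null") or best.use_kinship
        assert wins / reps >= 0.8

    def test_null_model_wins_on_iid_noise(self):
        rng = np.random.default_rng(6)
        spec = SimulationSpec(seed=21, n_samples=80, n_fragments=30)
        geno, _, _ = simulate_genotypes(spec)
        kin = estimate_kinship(geno)
        cands = [null_covariates(80), pca_covariates(geno, 2)]
        labels = []
        for _ in range(20):
            y = rng.standard_normal(80)
            best, _ = select_structure_model(y, cands, kin)
            labels.append(best.covariates.label)
        assert labels.count("null") >= 10

    def test_tie_broken_toward_fewer_parameters(self):
        rng = np.random.default_rng(7)
        n = 40
        y = rng.standard_normal(n)
        c1 = null_covariates(n)
        c2 = null_covariates(n)
        best, table = select_structure_model(y, [c1, c2], None)
        assert best.n_params == 2
        assert len(table) == 2


class TestGrammar:
    def test_intercept_only_reduces_to_centering(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(30) + 5
        fit = fit_mixed_model(y, null_covariates(30), use_kinship=False)
        np.testing.assert_allclose(grammar_residuals(fit), y - y.mean(),
                                   atol=1e-10)

    def test_residual_mean_zero_with_intercept(self):
        rng = np.random.default_rng(9)
        kin = random_kinship(rng, 50)
        y = rng.standard_normal(50)
        fit = fit_mixed_model(y, null_covariates(50), kin)
        assert abs(grammar_residuals(fit).mean()) < 1e-6

    def test_deconfounds_structured_phenotype(self):
        spec = SimulationSpec(seed=22, n_samples=80, n_fragments=40,
                              divergence=1.2)
        geno, labels, _ = simulate_genotypes(spec)
        kin = estimate_kinship(geno)
        rng = np.random.default_rng(10)
        better = 0
        reps = 20
        for _ in range(reps):
            y = 1.5 * labels + rng.standard_normal(80)
            fit = fit_mixed_model(y, pca_covariates(geno, 2), kin)
            y_adj = grammar_residuals(fit)
            r_raw = abs(np.corrcoef(y, labels)[0, 1])
            r_adj = abs(np.corrcoef(y_adj, labels)[0, 1])
            better += r_adj < r_raw
        assert better / reps >= 0.9


class TestInflationFactor:
    def test_reference_median_gives_lambda_one(self):
        adj = inflation_factor(np.full(100, 0.4549))
        assert adj.lam == pytest.approx(1.0)

    def test_inflated_chi2_detected(self):
        rng = np.random.default_rng(11)
        draws = 2.0 * rng.chisquare(1, size=100_000)
        adj = inflation_factor(draws)
        assert 1.95 <= adj.lam <= 2.05
        out = adj.adjust(draws)
        assert np.median(out) == pytest.approx(0.4549, rel=0.03)

    def test_deflation_only_by_default(self):
        stats_ = np.full(50, 0.8 * 0.4549)
        adj = inflation_factor(stats_)
        assert adj.lam == pytest.approx(0.8)
        np.testing.assert_array_equal(adj.adjust(stats_), stats_)

    def test_symmetric_mode_inflates(self):
        stats_ = np.full(50, 0.8 * 0.4549)
        adj = inflation_factor(stats_, mode="symmetric")
        assert adj.adjust(stats_)[0] == pytest.approx(0.4549)
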