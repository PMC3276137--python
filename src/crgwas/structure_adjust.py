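"""Population-structure control: kinship, the unified mixed model, GRAMMAR.

The phenotype model is y = X beta + u + e with u ~ N(0, 2K sigma_g^2) and
e ~ N(0, I sigma_e^2), so Var(y) = V = 2K sigma_g^2 + I sigma_e^2.  With a
single random effect the (RE)ML problem reduces, after a spectral
decomposition of 2K, to a one-dimensional optimization over the variance
ratio gamma = sigma_g^2 / sigma_e^2.  Candidate structure covariates
(intercept-only, genotype PCs, file-supplied STRUCTURE Q or nMDS coordinates)
crossed with {with K, without K} are compared by BIC, and the winning model's
residuals y_adj = y - X beta_hat - u_hat are carried forward as the
GRAMMAR-adjusted phenotype for all marker tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

#: Median of the chi-square(1) distribution, the genomic-control reference.
CHI2_1_MEDIAN = 0.4549


@dataclass
class KinshipMatrix:
    values: np.ndarray
    estimator: str = "allele-sharing"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def estimate_kinship(geno, min_snps_warn: int = 10) -> KinshipMatrix:
    """Marker-based relative kinship from allele-sharing similarity.

    Missing calls are mean-imputed per SNP for this computation only.  The
    raw similarity S_ik = 1 - mean_j |x_ij - x_kj| / ploidy (the exact-match
    proportion for integer calls) is rescaled against the mean off-diagonal
    similarity so that an average-related pair gets kinship 0:
    K_ik = max(0, (S_ik - S_bar) / (1 - S_bar)), with unit diagonal.
    """
    if geno.n_samples < 3:
        raise ValueError("kinship needs at least 3 samples")
    if geno.n_snps < min_snps_warn:
        logger.warning("kinship estimated from only %d SNPs", geno.n_snps)
    x = geno.mean_imputed()
    dist = squareform(pdist(x, metric="cityblock"))
    sim = 1.0 - dist / (geno.n_snps * geno.ploidy)
    off = ~np.eye(geno.n_samples, dtype=bool)
    s_bar = sim[off].mean()
    if s_bar >= 1.0:
        raise ValueError("panel has no genotypic variation between samples")
    kin = np.maximum(0.0, (sim - s_bar) / (1.0 - s_bar))
    np.fill_diagonal(kin, 1.0)
    return KinshipMatrix(values=kin)


def nearest_psd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    w, v = np.linalg.eigh(mat)
    if w.min() >= -eps:
        return mat
    logger.info("clipping %d negative kinship eigenvalues (min %.3g)",
                int((w < 0).sum()), float(w.min()))
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


@dataclass
class CovariateSet:
    """Fixed-effect design (always includes an intercept column)."""

    label: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        n, q = self.matrix.shape
        if q >= n:
            raise ValueError("more covariates than samples")
        if np.linalg.matrix_rank(self.matrix) < q:
            raise ValueError(f"covariate set {self.label!r} is rank deficient")

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


def null_covariates(n: int) -> CovariateSet:
    return CovariateSet("null", np.ones((n, 1)))


def pca_covariates(geno, k: int) -> CovariateSet:
    """Top-k genotype principal components plus intercept."""
    x = geno.mean_imputed()
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    return CovariateSet(f"pca({k})", np.column_stack([np.ones(len(pcs)), pcs]))


def covariates_from_file(path, samples: list[str], label: str = "Q") -> CovariateSet:
    """File-supplied structure coordinates (STRUCTURE Q / nMDS), intercept added."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in samples if s not in df.index]
    if missing:
        raise ValueError(f"covariate file lacks samples: {missing[:5]}")
    mat = df.loc[samples].to_numpy(dtype=float)
    return CovariateSet(label, np.column_stack([np.ones(len(samples)), mat]))


@dataclass
class MixedModelFit:
    """One fitted variance-component model and its GRAMMAR residuals."""

    covariates: CovariateSet
    use_kinship: bool
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    u_hat: np.ndarray
    loglik_ml: float
    loglik_reml: float
    bic: float
    y_adj: np.ndarray

    @property
    def n_params(self) -> int:
        return self.covariates.q + (2 if self.use_kinship else 1)


def _gaussian_ols(y: np.ndarray, x: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    return beta, resid, rss


def fit_mixed_model(
    y: np.ndarray,
    covariates: CovariateSet,
    kinship: KinshipMatrix | None = None,
    use_kinship: bool = True,
    tol: float = 1e-8,
) -> MixedModelFit:
    """Fit y = X beta + u + e with Var(u) = 2K sigma_g^2 by profile REML.

    The spectral decomposition 2K = U D U' turns the covariance into
    sigma_e^2 * diag(1 + gamma d_i) after rotation, so REML needs only a 1-D
    search over gamma = sigma_g^2 / sigma_e^2.  beta_hat is GLS at the
    optimum; u_hat = 2K sigma_g^2 V^-1 (y - X beta_hat).  BIC is computed
    from the ML log-likelihood so fixed-effect counts compare across models.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = covariates.matrix
    q = covariates.q

    if not use_kinship or kinship is None:
        beta, resid, rss = _gaussian_ols(y, x)
        if rss <= 0:
            raise ValueError("perfect fixed-effect fit; variance inestimable")
        s2_ml = rss / n
        s2_reml = rss / (n - q)
        ll_ml = -0.5 * n * (np.log(2 * np.pi * s2_ml) + 1)
        _, logdet_xx = np.linalg.slogdet(x.T @ x)
        ll_reml = (
            -0.5 * (n - q) * (np.log(2 * np.pi * s2_reml) + 1) - 0.5 * logdet_xx
        )
        bic = -2 * ll_ml + (q + 1) * np.log(n)
        return MixedModelFit(covariates, False, 0.0, s2_reml, beta,
                             np.zeros(n), ll_ml, ll_reml, bic, resid)

    a = nearest_psd(2.0 * kinship.values)
    d, u_eig = np.linalg.eigh(a)
    d = np.clip(d, 0.0, None)
    yt = u_eig.T @ y
    xt = u_eig.T @ x

    def _profile(gamma: float, reml: bool) -> tuple[float, np.ndarray, float]:
        w = 1.0 + gamma * d
        wi = 1.0 / w
        xtw = xt * wi[:, None]
        xx = xtw.T @ xt
        beta = np.linalg.solve(xx, xtw.T @ yt)
        r = yt - xt @ beta
        rss = float(r @ (wi * r))
        logdet_v = float(np.sum(np.log(w)))
        if reml:
            _, logdet_xx = np.linalg.slogdet(xx)
            s2 = rss / (n - q)
            ll = -0.5 * (
                (n - q) * np.log(2 * np.pi * s2) + logdet_v + logdet_xx + (n - q)
            )
        else:
            s2 = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet_v + n)
        return ll, beta, s2

    def _neg_reml(log_gamma: float) -> float:
        return -_profile(np.exp(log_gamma), reml=True)[0]

    res = optimize.minimize_scalar(
        _neg_reml, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": tol},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"REML optimization failed: {res}")
    # boundary check: gamma -> 0 (no polygenic variance)
    gamma = float(np.exp(res.x))
    ll0 = _profile(0.0, reml=True)[0]
    if ll0 >= -res.fun:
        gamma = 0.0

    ll_reml, beta, s2e = _profile(gamma, reml=True)
    s2g = gamma * s2e
    ll_ml = _profile(gamma, reml=False)[0]

    # BLUP of the polygenic effect on the original scale
    v = s2g * a + s2e * np.eye(n)
    resid_fixed = y - x @ beta
    u_hat = s2g * a @ np.linalg.solve(v, resid_fixed)
    y_adj = resid_fixed - u_hat
    bic = -2 * ll_ml + (q + 2) * np.log(n)
    return MixedModelFit(covariates, True, float(s2g), float(s2e), beta,
                         u_hat, float(ll_ml), float(ll_reml), float(bic), y_adj)


def select_structure_model(
    y: np.ndarray,
    covariate_sets: list[CovariateSet],
    kinship: KinshipMatrix | None,
) -> tuple[MixedModelFit, pd.DataFrame]:
    """Fit every covariate set with and without kinship; return min-BIC fit.

    Ties break toward fewer parameters.  A BIC table over the whole model
    grid is returned for logging/audit.
    """
    if not covariate_sets:
        raise ValueError("no candidate covariate sets")
    rows, fits = [], []
    for cov in covariate_sets:
        for use_k in ([False, True] if kinship is not None else [False]):
            try:
                fit = fit_mixed_model(y, cov, kinship, use_kinship=use_k)
            except Exception as exc:
                logger.warning("model %s%s failed: %s", cov.label,
                               "+K" if use_k else "", exc)
                continue
            fits.append(fit)
            rows.append(
                {
                    "model": cov.label + ("+K" if use_k else ""),
                    "q_fixed": cov.q,
                    "sigma_g2": fit.sigma_g2,
                    "sigma_e2": fit.sigma_e2,
                    "loglik_ml": fit.loglik_ml,
                    "bic": fit.bic,
                }
            )
    if not fits:
        raise RuntimeError("every candidate structure model failed to fit")
    table = pd.DataFrame(rows)
    order = sorted(range(len(fits)), key=lambda i: (fits[i].bic, fits[i].n_params))
    best = fits[order[0]]
    logger.info("selected structure model %s (BIC %.2f)",
                table.iloc[order[0]]["model"], best.bic)
    return best, table


def grammar_residuals(fit: MixedModelFit) -> np.ndarray:
    """GRAMMAR-adjusted phenotype y_adj = y - X beta_hat - u_hat."""
    return fit.y_adj


@dataclass
class InflationAdjustment:
    """Genomic-control lambda and the deflation it applies."""

    lam: float
    mode: str = "deflate-only"

    def adjust(self, stats_: np.ndarray) -> np.ndarray:
        stats_ = np.asarray(stats_, dtype=float)
        if self.mode == "off":
            return stats_
        divisor = self.lam if self.mode == "symmetric" else max(self.lam, 1.0)
        return stats_ / divisor


def inflation_factor(lr_stats: np.ndarray, mode: str = "deflate-only") -> InflationAdjustment:
    """Median-based genomic-control lambda for nominally chi-square(1) statistics.

    lambda = median(stats) / 0.4549.  Default mode divides by max(lambda, 1):
    deflation only, so an already well-calibrated scan is never inflated.
    """
    lr_stats = np.asarray(lr_stats, dtype=float)
    if (lr_stats < 0).any():
        raise ValueError("statistics must be non-negative")
    if len(lr_stats) < 20:
        logger.warning("inflation factor from only %d statistics", len(lr_stats))
    lam = float(np.median(lr_stats) / CHI2_1_MEDIAN)
    return InflationAdjustment(lam=lam, mode=mode)
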