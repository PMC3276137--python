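"""Association statistics on GRAMMAR-adjusted phenotypes.

Six tests are provided, dispatched per gene fragment by its variant content:

* single-SNP likelihood-ratio test (Bonferroni-controlled scan),
* multivariate test over a fragment's common variants,
* three rare-variant collapsing tests — sum, weighted sum
  (1/sqrt(n p (1-p)) weights), and the function-aided sum test whose per-SNP
  weight S_j * p_j^F combines a predicted-damage score with the fitted
  power-law proportion of functional SNPs at that MAF,
* a combined multivariate + pooled test treating the weighted-sum collapse of
  the rare variants as one extra pseudo-variant next to the common ones.

All tests share the Gaussian regression LR = n * ln(RSS0 / RSS1) against the
intercept-only null.  Experiment-wise thresholds come from permuting the
adjusted phenotype and recording the maximum statistic per (trait, method);
LR99 is the 99th percentile of those maxima and LR/LR99 puts the different
tests on a common scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .function_prediction import (
    FrequencyFunctionFit,
    SWeightMap,
    predicted_functional_proportion,
)

logger = logging.getLogger(__name__)

#: Minimum number of rare variants for any collapsing test; guards against
#: complete LD between two rare SNPs mimicking a burden signal.
MIN_RARE_VARIANTS = 3

RARE_METHODS = ("sum", "weighted_sum", "function_aided_sum")

#: Cap applied when the alternative fit is numerically perfect (RSS1 ~ 0).
_RSS_FLOOR_REL = 1e-12


class FragmentSkipped(Exception):
    """A fragment does not qualify for the requested test."""


@dataclass
class TestResult:
    """One (trait, unit, method) likelihood-ratio test record."""

    __test__ = False  # not a pytest class

    trait: str
    unit: str
    method: str
    lr: float
    df: int
    p_asymptotic: float
    beta0: float | None = None
    beta1: float | None = None
    p_permutation: float | None = None
    lr99: float | None = None
    lr_ratio: float | None = None
    significant: bool | None = None


@dataclass
class BurdenScore:
    """Per-sample collapsed score over a fragment's rare variants."""

    method: str
    z: np.ndarray
    snp_ids: list[str]

    @property
    def m(self) -> int:
        return len(self.snp_ids)


def _rss_split(y: np.ndarray, z: np.ndarray) -> tuple[float, float, float, float]:
    """RSS under intercept-only and intercept+z models, plus beta0/beta1."""
    yc = y - y.mean()
    zc = z - z.mean()
    rss0 = float(yc @ yc)
    szz = float(zc @ zc)
    if szz == 0:
        raise ValueError("inestimable regressor: z is constant")
    beta1 = float(yc @ zc) / szz
    beta0 = float(y.mean() - beta1 * z.mean())
    rss1 = rss0 - beta1**2 * szz
    return rss0, rss1, beta0, beta1


def _lr_from_rss(n: int, rss0: float, rss1: float) -> float:
    if rss0 <= 0:
        return 0.0
    floor = rss0 * _RSS_FLOOR_REL
    if rss1 < floor:
        logger.warning("perfect alternative fit; LR capped")
        rss1 = floor
    return float(n * np.log(rss0 / rss1))


def lr_test(y_adj: np.ndarray, z: np.ndarray, trait: str = "", unit: str = "",
            method: str = "single_snp") -> TestResult:
    """Gaussian LR test of y_adj on one regressor: LR = n ln(RSS0/RSS1), 1 df."""
    y_adj = np.asarray(y_adj, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(y_adj)
    if n < 4 or len(z) != n:
        raise ValueError("need matched y and z with n >= 4")
    rss0, rss1, beta0, beta1 = _rss_split(y_adj, z)
    lr = _lr_from_rss(n, rss0, rss1)
    p = float(stats.chi2.sf(lr, 1))
    return TestResult(trait=trait, unit=unit, method=method, lr=lr, df=1,
                      p_asymptotic=p, beta0=beta0, beta1=beta1)


def single_snp_scan(y_adj: np.ndarray, geno, maf: np.ndarray,
                    alpha: float = 0.05, trait: str = "") -> list[TestResult]:
    """One LR test per polymorphic SNP with Bonferroni significance flags.

    Missing calls are mean-imputed per SNP.  Monomorphic SNPs are skipped
    and counted in the log.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    x = geno.mean_imputed()
    poly = np.asarray(maf) > 0
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("single-SNP scan: skipped %d monomorphic SNPs", n_skipped)
    m_tested = int(poly.sum())
    threshold = alpha / max(m_tested, 1)
    out = []
    for j in np.where(poly)[0]:
        res = lr_test(y_adj, x[:, j], trait=trait, unit=geno.snp_ids[j],
                      method="single_snp")
        res.significant = res.p_asymptotic <= threshold
        out.append(res)
    return out


def burden_score(
    geno,
    snp_indices: np.ndarray,
    maf: np.ndarray,
    method: str,
    s_weights: np.ndarray | None = None,
    fit: FrequencyFunctionFit | None = None,
    maf_threshold: float = 0.05,
    min_rare: int = MIN_RARE_VARIANTS,
) -> BurdenScore:
    """Collapse a fragment's rare variants into one per-sample score.

    sum:                z_i = (sum_j x_ij) / m
    weighted_sum:       z_i = sum_j x_ij / sqrt(n p_j (1 - p_j))
    function_aided_sum: z_i = sum_j S_j p_j^F x_ij

    Only rare polymorphic SNPs (0 < MAF < threshold, strict) contribute;
    fragments with fewer than ``min_rare`` of them are skipped.
    """
    snp_indices = np.asarray(snp_indices, dtype=int)
    maf = np.asarray(maf, dtype=float)
    rare = snp_indices[(maf[snp_indices] > 0) & (maf[snp_indices] < maf_threshold)]
    if len(rare) < min_rare:
        raise FragmentSkipped(
            f"insufficient rare variants ({len(rare)} < {min_rare})"
        )
    x = geno.mean_imputed()[:, rare]
    p = maf[rare]
    n = geno.n_samples
    if method == "sum":
        z = x.sum(axis=1) / len(rare)
    elif method == "weighted_sum":
        z = (x / np.sqrt(n * p * (1.0 - p))).sum(axis=1)
    elif method == "function_aided_sum":
        if fit is None:
            raise ValueError("function_aided_sum needs a frequency-function fit")
        if s_weights is None:
            raise ValueError("function_aided_sum needs per-SNP S weights")
        s = np.asarray(s_weights, dtype=float)
        if len(s) != len(snp_indices):
            raise ValueError("s_weights must align with snp_indices")
        s = s[np.isin(snp_indices, rare)]
        p_units = p * 100.0 if fit.maf_units == "percent" else p
        pf = predicted_functional_proportion(p_units, fit)
        z = (x * s * pf).sum(axis=1)
    else:
        raise ValueError(f"unknown burden method {method!r}")
    return BurdenScore(method=method, z=z,
                       snp_ids=[geno.snp_ids[j] for j in rare])


def _independent_columns(mat: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Greedy maximal linearly independent column subset, first-kept order."""
    keep: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(mat.shape[1]):
        v = mat[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        for b in basis:
            v = v - (b @ v) * b
        if np.linalg.norm(v) > tol * norm0:
            basis.append(v / np.linalg.norm(v))
            keep.append(j)
    return keep


def multivariate_test(y_adj: np.ndarray, variant_matrix: np.ndarray,
                      trait: str = "", unit: str = "",
                      method: str = "multivariate") -> TestResult:
    """Joint LR test of y_adj on all (linearly independent) variant columns.

    Collinear columns are reduced to a maximal independent set in input
    order; df counts the retained columns.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    v = np.atleast_2d(np.asarray(variant_matrix, dtype=float))
    if v.shape[0] != len(y_adj):
        raise ValueError("variant matrix rows must match samples")
    n = len(y_adj)
    vc = v - v.mean(axis=0)
    keep = _independent_columns(vc)
    if not keep:
        raise ValueError("no polymorphic variant columns")
    if len(keep) < v.shape[1]:
        logger.info("dropped %d collinear columns", v.shape[1] - len(keep))
    if len(keep) >= n - 2:
        raise ValueError("saturated model: too many variant columns")
    q, _ = np.linalg.qr(vc[:, keep])
    yc = y_adj - y_adj.mean()
    rss0 = float(yc @ yc)
    proj = q.T @ yc
    rss1 = rss0 - float(proj @ proj)
    lr = _lr_from_rss(n, rss0, rss1)
    df = len(keep)
    return TestResult(trait=trait, unit=unit, method=method, lr=lr, df=df,
                      p_asymptotic=float(stats.chi2.sf(lr, df)))


def combined_multivariate_pooled(
    y_adj: np.ndarray,
    common_matrix: np.ndarray | None,
    pooled: BurdenScore | None,
    trait: str = "",
    unit: str = "",
) -> TestResult:
    """Multivariate test over common variants plus the weighted-sum collapse
    of the rare variants treated as one extra pseudo-variant."""
    if pooled is not None and pooled.method != "weighted_sum":
        raise ValueError("pooled score must come from the weighted_sum collapse")
    cols = []
    if common_matrix is not None and common_matrix.size:
        cols.append(np.atleast_2d(np.asarray(common_matrix, dtype=float)))
    if pooled is not None:
        cols.append(pooled.z[:, None])
    if not cols:
        raise ValueError("need common variants or a valid pooled score")
    design = np.column_stack(cols)
    return multivariate_test(y_adj, design, trait=trait, unit=unit,
                             method="combined_multivariate_pooled")


def dispatch_fragment_tests(n_rare: int, n_common: int,
                            min_rare: int = MIN_RARE_VARIANTS) -> list[str]:
    """Which tests apply to a fragment, by its rare/common variant content.

    Fragments with >= min_rare rare variants get the three collapsing tests,
    plus the combined test when common variants are also present; fragments
    below the rare cutoff fall back to the multivariate common-variant test.
    """
    if n_rare >= min_rare:
        tests = list(RARE_METHODS)
        if n_common >= 1:
            tests.append("combined_multivariate_pooled")
        return tests
    if n_common >= 1:
        return ["multivariate"]
    return []


@dataclass
class FragmentDesign:
    """Precomputed orthonormal design for fast permutation re-testing."""

    unit: str
    method: str
    q: np.ndarray  # orthonormal basis of the centered design columns
    df: int


def build_fragment_design(unit: str, method: str,
                          design_columns: np.ndarray) -> FragmentDesign:
    dc = np.atleast_2d(np.asarray(design_columns, dtype=float))
    dc = dc - dc.mean(axis=0)
    keep = _independent_columns(dc)
    if not keep:
        raise ValueError(f"fragment {unit}: degenerate design")
    q, _ = np.linalg.qr(dc[:, keep])
    return FragmentDesign(unit=unit, method=method, q=q, df=len(keep))


def _lr_battery(y: np.ndarray, designs: list[FragmentDesign]) -> np.ndarray:
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    out = np.empty(len(designs))
    for i, d in enumerate(designs):
        proj = d.q.T @ yc
        out[i] = _lr_from_rss(len(y), rss0, rss0 - float(proj @ proj))
    return out


@dataclass
class PermutationPlan:
    """Seeded experiment-wise permutation scheme per (trait, method)."""

    n_perm: int = 1000
    seed: int = 0
    quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("need at least 100 permutations")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")


@dataclass
class PermutationResult:
    lr99: float
    maxima: np.ndarray
    observed_lr: np.ndarray
    p_permutation: np.ndarray


def permutation_threshold(
    y_adj: np.ndarray,
    designs: list[FragmentDesign],
    plan: PermutationPlan,
) -> PermutationResult:
    """Experiment-wise LR threshold from permuting the adjusted phenotype.

    For each permutation the maximum LR across all fragments (one method) is
    recorded; LR99 is the empirical ``plan.quantile`` percentile of the
    maxima (linear/type-7 interpolation).  Per-fragment permutation p-values
    are the fraction of maxima at or above the observed statistic.
    """
    if not designs:
        raise ValueError("empty test battery")
    y_adj = np.asarray(y_adj, dtype=float)
    rng = np.random.default_rng(plan.seed)
    observed = _lr_battery(y_adj, designs)
    maxima = np.empty(plan.n_perm)
    for b in range(plan.n_perm):
        maxima[b] = _lr_battery(rng.permutation(y_adj), designs).max()
    lr99 = float(np.quantile(maxima, plan.quantile))
    p_perm = (maxima[None, :] >= observed[:, None]).mean(axis=1)
    return PermutationResult(lr99=lr99, maxima=maxima,
                             observed_lr=observed, p_permutation=p_perm)


def scale_by_threshold(result: TestResult, lr99: float) -> TestResult:
    """Attach LR99, the cross-method LR/LR99 scale, and its >= 1 flag."""
    if lr99 <= 0:
        raise ValueError("LR99 must be positive")
    result.lr99 = float(lr99)
    result.lr_ratio = result.lr / lr99
    result.significant = result.lr_ratio >= 1.0
    return result
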