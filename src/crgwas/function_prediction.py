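"""Functional calls, MAF binning, and the MAF -> proportion-functional fit.

Nonsynonymous SNPs carry PolyPhen (benign / possibly_damaging /
probably_damaging) and SIFT (tolerant / intolerant) categories.  Damaging and
intolerant calls count as functional; nonsense changes are always functional.
The proportion of functional SNPs decays steeply with minor-allele frequency
and is summarized by a power law p^F = a * p^b fitted to 20 MAF bins of 2.5%
width, which then supplies the frequency part of the function-aided sum-test
weight S_j * p_j^F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Per-category S weights: mean probabilistic scores of amino-acid change.
DEFAULT_S_WEIGHTS = {
    "benign_or_synonymous": 0.6772,
    "possibly_damaging": 1.7051,
    "probably_damaging": 2.4277,
}


@dataclass
class FunctionCallRules:
    """Which prediction categories count as functional."""

    polyphen_functional: frozenset[str] = frozenset(
        {"possibly_damaging", "probably_damaging"}
    )
    sift_functional: frozenset[str] = frozenset({"intolerant"})
    nonsense_always_functional: bool = True


@dataclass
class SWeightMap:
    """Damage-severity weights S_j used by the function-aided sum test."""

    weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_S_WEIGHTS)
    )

    def __post_init__(self) -> None:
        w = self.weights
        if any(v <= 0 for v in w.values()):
            raise ValueError("S weights must be positive")
        order = ["benign_or_synonymous", "possibly_damaging", "probably_damaging"]
        vals = [w[k] for k in order if k in w]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("S weights must be non-decreasing in damage severity")

    def for_snp(self, polyphen: str, site_class: str) -> float:
        """S weight for one SNP; unscored/synonymous SNPs take the benign weight."""
        if polyphen in ("possibly_damaging", "probably_damaging"):
            return self.weights[polyphen]
        return self.weights["benign_or_synonymous"]


def call_functional(
    annotation, rules: FunctionCallRules | None = None, predictor: str = "polyphen"
) -> bool:
    """Binary functional call for one annotated SNP under one predictor.

    ``annotation`` is any mapping/row with keys ``nonsense``, ``polyphen``,
    ``sift``.  Nonsense changes are functional regardless of predictor; SNPs
    without a prediction are non-functional (tallied as unscored by callers).
    """
    rules = rules or FunctionCallRules()
    if rules.nonsense_always_functional and bool(annotation["nonsense"]):
        return True
    if predictor == "polyphen":
        return annotation["polyphen"] in rules.polyphen_functional
    if predictor == "sift":
        return annotation["sift"] in rules.sift_functional
    raise ValueError(f"unknown predictor {predictor!r}")


def call_functional_table(
    annotations: pd.DataFrame,
    rules: FunctionCallRules | None = None,
    predictor: str = "polyphen",
) -> np.ndarray:
    """Vectorized `call_functional` over an annotation table."""
    rules = rules or FunctionCallRules()
    calls = np.array(
        [call_functional(row, rules, predictor) for _, row in annotations.iterrows()]
    )
    unscored = (
        (~annotations["nonsense"].astype(bool))
        & (annotations[predictor] == "none")
    ).sum()
    if unscored:
        logger.info("%d SNPs unscored by %s (treated as non-functional)",
                    int(unscored), predictor)
    return calls


@dataclass
class MafBinning:
    """Fixed-width MAF bins over (0, 0.5], left-open right-closed."""

    n_bins: int = 20
    width: float = 0.025
    counts_total: np.ndarray | None = None
    counts_functional: np.ndarray | None = None

    @property
    def midpoints(self) -> np.ndarray:
        """Bin midpoints on the MAF fraction scale."""
        return (np.arange(self.n_bins) + 0.5) * self.width

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.counts_total > 0,
                self.counts_functional / self.counts_total,
                np.nan,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "midpoint": self.midpoints,
                "n_total": self.counts_total,
                "n_functional": self.counts_functional,
                "prop_functional": self.proportions,
            }
        )


def bin_by_maf(
    mafs: np.ndarray,
    functional_calls: np.ndarray,
    binning: MafBinning | None = None,
) -> MafBinning:
    """Tabulate functional/total counts per MAF bin.

    A SNP with MAF m falls in bin ceil(m / width); a boundary value belongs to
    the lower bin.  Monomorphic SNPs (m = 0) are rejected.
    """
    binning = binning or MafBinning()
    mafs = np.asarray(mafs, dtype=float)
    functional_calls = np.asarray(functional_calls, dtype=bool)
    if (mafs <= 0).any() or (mafs > binning.n_bins * binning.width + 1e-12).any():
        raise ValueError("MAFs must lie in (0, 0.5]; drop monomorphic SNPs first")
    idx = np.ceil(mafs / binning.width - 1e-9).astype(int) - 1
    idx = np.clip(idx, 0, binning.n_bins - 1)
    total = np.bincount(idx, minlength=binning.n_bins)
    func = np.bincount(idx, weights=functional_calls, minlength=binning.n_bins)
    return MafBinning(
        n_bins=binning.n_bins,
        width=binning.width,
        counts_total=total,
        counts_functional=func.astype(int),
    )


@dataclass
class FrequencyFunctionFit:
    """Fitted MAF -> proportion-functional curve.

    power:       p^F = a * p^b          (fit by OLS of ln prop on ln p)
    logarithmic: p^F = a * ln(p) + b
    linear:      p^F = a * p + b

    ``maf_units`` controls the scale of p in the fit ('percent' by default:
    the curve coefficients are only internally consistent as proportions when
    p is expressed in percent over the observed MAF range).
    """

    model: str
    a: float
    b: float
    r_squared: float
    maf_units: str = "percent"


def _to_units(p_fraction: np.ndarray, units: str) -> np.ndarray:
    if units == "percent":
        return p_fraction * 100.0
    if units == "fraction":
        return p_fraction
    raise ValueError(f"unknown maf_units {units!r}")


def fit_frequency_function(
    binning: MafBinning,
    model: str = "power",
    maf_units: str = "percent",
    use_bin_mean: np.ndarray | None = None,
) -> FrequencyFunctionFit:
    """Fit one of the three candidate regressions to the binned proportions.

    R-squared is always computed on the original proportion scale (squared
    correlation of fitted vs observed) so the three models are comparable.
    Zero-proportion bins are excluded from the log-space power fit.
    """
    props = binning.proportions
    p = _to_units(
        use_bin_mean if use_bin_mean is not None else binning.midpoints, maf_units
    )
    usable = (binning.counts_total > 0) & ~np.isnan(props)
    if model == "power":
        usable &= props > 0
    if usable.sum() < 3:
        raise ValueError("need at least 3 usable bins to fit")
    x, y = p[usable], props[usable]

    if model == "power":
        if np.ptp(np.log(y)) == 0 and np.ptp(np.log(x)) == 0:
            raise ValueError("no variation in log space")
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        a, b = float(np.exp(intercept)), float(slope)
        fitted = a * x**b
    elif model == "logarithmic":
        a, b = (float(v) for v in np.polyfit(np.log(x), y, 1))
        fitted = a * np.log(x) + b
    elif model == "linear":
        a, b = (float(v) for v in np.polyfit(x, y, 1))
        fitted = a * x + b
    else:
        raise ValueError(f"unknown model {model!r}")

    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r2 = 1.0 if np.allclose(fitted, y) else 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return FrequencyFunctionFit(model=model, a=a, b=b, r_squared=r2, maf_units=maf_units)


def predicted_functional_proportion(
    p: float | np.ndarray, fit: FrequencyFunctionFit, clip: bool = False
):
    """Evaluate the fitted curve at MAF ``p`` (in the fit's units).

    The unclipped value is used as a test weight; ``clip=True`` returns
    min(1, value) for display as a proportion.
    """
    p = np.asarray(p, dtype=float)
    if (p <= 0).any():
        raise ValueError("p must be positive")
    if fit.model == "power":
        val = fit.a * p**fit.b
    elif fit.model == "logarithmic":
        val = fit.a * np.log(p) + fit.b
    elif fit.model == "linear":
        val = fit.a * p + fit.b
    else:  # pragma: no cover
        raise ValueError(f"unknown model {fit.model!r}")
    if clip:
        val = np.minimum(val, 1.0)
    return float(val) if val.ndim == 0 else val


def congruency_test(polyphen_calls: np.ndarray, sift_calls: np.ndarray):
    """Pearson chi-square (1 df, no continuity correction) for agreement
    between two binary functional-call vectors over the same SNPs.

    Returns (chi_square, p_value, 2x2 table, proportion both-nonfunctional).
    """
    a = np.asarray(polyphen_calls, dtype=bool)
    b = np.asarray(sift_calls, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors must cover the same SNPs")
    table = np.array(
        [
            [(a & b).sum(), (a & ~b).sum()],
            [(~a & b).sum(), (~a & ~b).sum()],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a marginal total is zero; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    both_nonfunctional = table[1, 1] / table.sum()
    return float(chi2), float(p), table, float(both_nonfunctional)
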