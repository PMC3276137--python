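"""Decision layer that turns test statistics into candidate-gene routes.

Significant units are filtered along four routes: confirmation against an
a priori candidate list (p <= 0.001 in every applicable method), a top-30
triage of the remaining tests, a >= 3 predicted-functional-SNP evidence rule,
and cross-method consistency (Venn overlap of the three collapsing tests).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

from .association_tests import TestResult
from .core_data import CandidateGeneList

ROUTES = ("a_priori_confirmed", "top30_functional", "top30_network_pending", "rejected")


@dataclass
class FilterReport:
    unit: str
    trait: str
    route: str
    n_functional_snps: int = 0
    n_methods_significant: int = 0


def _pvalue(result: TestResult) -> tuple[float, str]:
    """Permutation p-value when available, else asymptotic; source recorded."""
    if result.p_permutation is not None:
        return result.p_permutation, "permutation"
    return result.p_asymptotic, "asymptotic"


def confirm_a_priori(
    results_by_unit: dict[tuple[str, str], list[TestResult]],
    unit_gene: dict[str, str | None],
    candidates: CandidateGeneList,
    alpha: float = 0.001,
) -> list[FilterReport]:
    """Units whose gene is on the a priori list and significant at ``alpha``
    in every method applicable to that unit.

    ``results_by_unit`` maps (trait, unit) to that unit's results across all
    applicable methods.
    """
    confirmed = []
    for (trait, unit), results in sorted(results_by_unit.items()):
        gene = unit_gene.get(unit)
        if gene is None or gene not in candidates:
            continue
        if not results:
            continue
        pvals = [_pvalue(r)[0] for r in results]
        n_sig = sum(p <= alpha for p in pvals)
        if n_sig == len(results):
            confirmed.append(
                FilterReport(unit=unit, trait=trait, route="a_priori_confirmed",
                             n_methods_significant=n_sig)
            )
    return confirmed


def top_k(results: list[TestResult], k: int = 30) -> list[TestResult]:
    """Top-k tests by LR/LR99 descending, ties by (LR desc, unit id asc).

    The ranking spans the whole battery (all traits x units of one track) so
    different methods compete on the common LR/LR99 scale.
    """
    missing = [r for r in results if r.lr_ratio is None]
    if missing:
        raise ValueError("every result needs lr_ratio before top-k ranking")
    ranked = sorted(results, key=lambda r: (-r.lr_ratio, -r.lr, r.unit, r.trait))
    return ranked[:k]


def functional_snp_filter(
    fragment_snp_ids: list[str],
    functional_by_snp: dict[str, bool],
    min_count: int = 3,
) -> tuple[bool, int]:
    """Evidence rule: the fragment carries >= min_count predicted-functional
    SNPs.  Three is the default cutoff so complete LD between two rare SNPs
    cannot fake a burden of evidence.  Returns (passes, count)."""
    count = sum(bool(functional_by_snp.get(s, False)) for s in fragment_snp_ids)
    return count >= min_count, count


def cross_method_consistency(
    results_by_method: dict[str, list[TestResult]],
    alpha: float = 0.01,
) -> tuple[set[tuple[str, str]], dict[str, int]]:
    """Intersection of significant (trait, unit) cells across methods, with
    Venn cell counts (per-method exclusive, pairwise, all-method, none)."""
    methods = sorted(results_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    universes = {
        m: {(r.trait, r.unit) for r in results_by_method[m]} for m in methods
    }
    universe = set.union(*universes.values())
    if set.intersection(*universes.values()) != universe:
        raise ValueError("methods must share the same (trait, unit) universe")

    sig = {
        m: {
            (r.trait, r.unit)
            for r in results_by_method[m]
            if _pvalue(r)[0] <= alpha
        }
        for m in methods
    }
    counts: dict[str, int] = {}
    assigned: set[tuple[str, str]] = set()
    # exclusive cells from largest overlap down to singletons
    for size in range(len(methods), 0, -1):
        for combo in combinations(methods, size):
            cell = set.intersection(*(sig[m] for m in combo))
            for m in set(methods) - set(combo):
                cell -= sig[m]
            cell -= assigned
            counts["&".join(combo)] = len(cell)
            assigned |= cell
    counts["none"] = len(universe - assigned)
    intersection = set.intersection(*(sig[m] for m in methods))
    return intersection, counts


def route_units(
    results_by_unit: dict[tuple[str, str], list[TestResult]],
    unit_gene: dict[str, str | None],
    candidates: CandidateGeneList,
    ranked_results: list[TestResult],
    functional_pass: dict[str, bool],
    alpha: float = 0.001,
    k: int = 30,
) -> list[FilterReport]:
    """Assign every tested (trait, unit) exactly one filter route.

    a priori confirmation takes precedence; remaining units inside the top-k
    triage go to the functional-evidence route if their fragment passes the
    >= 3-functional-SNP rule, else await gene-network support; everything
    else is rejected.
    """
    confirmed = {
        (r.trait, r.unit): r
        for r in confirm_a_priori(results_by_unit, unit_gene, candidates, alpha)
    }
    top = top_k(ranked_results, k)
    top_cells = defaultdict(list)
    for r in top:
        top_cells[(r.trait, r.unit)].append(r)

    reports = []
    for (trait, unit), results in sorted(results_by_unit.items()):
        if (trait, unit) in confirmed:
            reports.append(confirmed[(trait, unit)])
            continue
        n_sig = sum(_pvalue(r)[0] <= alpha for r in results)
        if (trait, unit) in top_cells:
            if functional_pass.get(unit, False):
                route = "top30_functional"
            else:
                route = "top30_network_pending"
        else:
            route = "rejected"
        reports.append(
            FilterReport(unit=unit, trait=trait, route=route,
                         n_methods_significant=n_sig)
        )
    return reports
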