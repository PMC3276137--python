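"""End-to-end orchestration of the composite association workflow.

Stages: load (or simulate) inputs -> impute/normalize phenotypes -> kinship
and BIC structure-model selection -> GRAMMAR adjustment -> per-fragment test
dispatch and permutation thresholds -> genomic-control deflation of the
single-SNP scan -> candidate filtering (a priori conjunction, top-30 triage,
functional-SNP rule) -> gene-network pruning, retrieval and intersection.
Every run records its resolved configuration and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_tests as at
from . import candidate_filter as cf
from . import core_data as cd
from . import function_prediction as fp
from . import gene_network as gn
from . import structure_adjust as sa

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    genotypes: str = ""
    genotype_format: str = "tsv"
    phenotypes: str = ""
    annotations: str = ""
    candidates: str = ""
    network: str = ""
    covariates: str = ""
    outdir: str = "crgwas_out"
    ploidy: int = 1
    maf_threshold: float = 0.05
    min_rare: int = 3
    impute_k: int = 3
    pca_components: tuple[int, ...] = (1, 2, 3)
    n_perm: int = 1000
    perm_seed: int = 1
    quantile: float = 0.99
    alpha_confirm: float = 0.001
    alpha_consistency: float = 0.01
    top_k: int = 30
    auc_target: float = 0.95
    top_n: int = 200
    regression_model: str = "power"
    maf_units: str = "percent"
    lambda_mode: str = "deflate-only"
    run_network: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.pca_components, list):
            cfg.pca_components = tuple(cfg.pca_components)
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    results: list[at.TestResult] = field(default_factory=list)
    single_snp: dict[str, list[at.TestResult]] = field(default_factory=dict)
    lambda_by_trait: dict[str, float] = field(default_factory=dict)
    reports: list[cf.FilterReport] = field(default_factory=list)
    venn: dict[str, int] = field(default_factory=dict)
    fit_polyphen: fp.FrequencyFunctionFit | None = None
    network_retained: list[str] = field(default_factory=list)
    network_retrieved: list[tuple[str, float]] = field(default_factory=list)
    posterior_candidates: list[dict] = field(default_factory=list)

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": r.trait, "unit": r.unit, "method": r.method,
                    "LR": r.lr, "df": r.df, "p_asym": r.p_asymptotic,
                    "p_perm": r.p_permutation, "LR99": r.lr99,
                    "lr_ratio": r.lr_ratio, "significant": r.significant,
                }
                for r in self.results
            ]
        )


def _stage(name: str):
    logger.info("stage: %s", name)


def prepare_phenotypes(pheno: cd.PhenotypeTable, impute_k: int) -> cd.PhenotypeTable:
    return cd.normalize_phenotypes(cd.impute_phenotypes(pheno, k_neighbors=impute_k))


def fit_functional_curve(
    annotations: pd.DataFrame,
    maf: np.ndarray,
    snp_ids: list[str],
    model: str = "power",
    maf_units: str = "percent",
    predictor: str = "polyphen",
    fallback: tuple[float, float] = (0.3562, -1.4162),
):
    """Functional calls, MAF binning and the frequency-function fit from the
    panel's own annotated polymorphic SNPs.

    Panels too small to populate three usable bins fall back to the
    reference power-law coefficients (the MAF-functionality relation is a
    population-level property, not a per-panel one); the fallback is logged
    and carries r_squared = NaN.
    """
    ann = annotations.set_index("snp_id").loc[snp_ids].reset_index()
    calls = fp.call_functional_table(ann, predictor=predictor)
    poly = maf > 0
    bins = fp.bin_by_maf(maf[poly], calls[poly])
    try:
        fit = fp.fit_frequency_function(bins, model=model, maf_units=maf_units)
    except ValueError as exc:
        logger.warning("frequency-function fit not estimable from panel (%s); "
                       "using reference power-law coefficients %s", exc, fallback)
        fit = fp.FrequencyFunctionFit(model="power", a=fallback[0],
                                      b=fallback[1], r_squared=float("nan"),
                                      maf_units=maf_units)
    return calls, bins, fit


def adjust_traits(
    pheno: cd.PhenotypeTable,
    geno: cd.GenotypeMatrix,
    kinship: sa.KinshipMatrix,
    pca_components: tuple[int, ...] = (1, 2, 3),
    covariate_file: str = "",
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """BIC model selection + GRAMMAR residuals per trait.

    Returns (trait -> adjusted phenotype, trait -> selected model label).
    """
    n = geno.n_samples
    cands = [sa.null_covariates(n)]
    for k in pca_components:
        if k < n - 2:
            cands.append(sa.pca_covariates(geno, k))
    if covariate_file:
        cands.append(sa.covariates_from_file(covariate_file, list(geno.samples)))
    y_adj, chosen = {}, {}
    for t, trait in enumerate(pheno.traits):
        fit, table = sa.select_structure_model(pheno.values[:, t], cands, kinship)
        y_adj[trait] = sa.grammar_residuals(fit)
        chosen[trait] = fit.covariates.label + ("+K" if fit.use_kinship else "")
    return y_adj, chosen


def build_fragment_batteries(
    geno: cd.GenotypeMatrix,
    annotations: pd.DataFrame,
    maf: np.ndarray,
    fit: fp.FrequencyFunctionFit,
    s_map: fp.SWeightMap | None = None,
    maf_threshold: float = 0.05,
    min_rare: int = 3,
) -> dict[str, list[at.FragmentDesign]]:
    """Per-method lists of precomputed fragment designs.

    Each fragment is dispatched by its rare/common content; the design for
    every applicable test is orthonormalized once so observed statistics and
    permutation replicates share the same code path.
    """
    s_map = s_map or fp.SWeightMap()
    ann = annotations.set_index("snp_id")
    frag_snps: dict[str, list[int]] = {}
    for j, snp in enumerate(geno.snp_ids):
        frag = ann.loc[snp, "fragment_id"]
        frag_snps.setdefault(str(frag), []).append(j)

    batteries: dict[str, list[at.FragmentDesign]] = {}
    x_imp = geno.mean_imputed()
    for frag in sorted(frag_snps):
        idx = np.asarray(frag_snps[frag])
        rare = idx[(maf[idx] > 0) & (maf[idx] < maf_threshold)]
        common = idx[maf[idx] >= maf_threshold]
        methods = at.dispatch_fragment_tests(len(rare), len(common), min_rare)
        if not methods:
            continue
        s_weights = np.array(
            [
                s_map.for_snp(ann.loc[geno.snp_ids[j], "polyphen"],
                              ann.loc[geno.snp_ids[j], "site_class"])
                for j in idx
            ]
        )
        pooled = None
        for method in methods:
            try:
                if method in at.RARE_METHODS:
                    score = at.burden_score(
                        geno, idx, maf, method, s_weights=s_weights, fit=fit,
                        maf_threshold=maf_threshold, min_rare=min_rare)
                    design = score.z[:, None]
                elif method == "multivariate":
                    design = x_imp[:, common]
                else:  # combined_multivariate_pooled
                    if pooled is None:
                        pooled = at.burden_score(
                            geno, idx, maf, "weighted_sum",
                            maf_threshold=maf_threshold, min_rare=min_rare)
                    design = np.column_stack([x_imp[:, common], pooled.z])
                fd = at.build_fragment_design(frag, method, design)
            except (at.FragmentSkipped, ValueError) as exc:
                logger.info("fragment %s skipped for %s: %s", frag, method, exc)
                continue
            batteries.setdefault(method, []).append(fd)
    return batteries


def run_association(
    y_adj_by_trait: dict[str, np.ndarray],
    batteries: dict[str, list[at.FragmentDesign]],
    n_perm: int = 1000,
    perm_seed: int = 1,
    quantile: float = 0.99,
) -> list[at.TestResult]:
    """Observed LRs, permutation thresholds and LR/LR99 for every
    (trait, method, fragment) cell."""
    results: list[at.TestResult] = []
    for ti, (trait, y_adj) in enumerate(sorted(y_adj_by_trait.items())):
        for mi, (method, designs) in enumerate(sorted(batteries.items())):
            plan = at.PermutationPlan(
                n_perm=n_perm,
                seed=(perm_seed + 1009 * ti + 9176 * mi) % (2**31 - 1),
                quantile=quantile,
            )
            perm = at.permutation_threshold(y_adj, designs, plan)
            from scipy import stats as _st
            for i, d in enumerate(designs):
                res = at.TestResult(
                    trait=trait, unit=d.unit, method=method,
                    lr=float(perm.observed_lr[i]), df=d.df,
                    p_asymptotic=float(_st.chi2.sf(perm.observed_lr[i], d.df)),
                    p_permutation=float(perm.p_permutation[i]),
                )
                at.scale_by_threshold(res, perm.lr99)
                results.append(res)
    return results


def run_pipeline(
    config: PipelineConfig,
    geno: cd.GenotypeMatrix | None = None,
    pheno: cd.PhenotypeTable | None = None,
    annotations: pd.DataFrame | None = None,
    candidates: cd.CandidateGeneList | None = None,
    network: gn.GeneNetwork | None = None,
) -> PipelineResult:
    """Run the full composite workflow.

    Inputs may be passed in memory (as from the synthetic generators) or read
    from the paths in ``config``.
    """
    out = PipelineResult(config=config)
    _stage("load")
    if geno is None:
        geno = cd.read_genotypes(config.genotypes, config.genotype_format,
                                 config.ploidy)
    if pheno is None:
        pheno = cd.read_phenotypes(config.phenotypes)
    if annotations is None:
        annotations = cd.read_annotations(config.annotations)
    if candidates is None and config.candidates:
        candidates = cd.read_candidate_list(config.candidates)
    if network is None and config.run_network:
        if not config.network:
            raise FileNotFoundError("stage network: no network file configured")
        network = gn.load_network(config.network)

    maf = cd.compute_maf(geno)

    _stage("phenotype preparation")
    pheno = prepare_phenotypes(pheno, config.impute_k)

    _stage("function prediction")
    calls, bins, fit = fit_functional_curve(
        annotations, maf, geno.snp_ids,
        model=config.regression_model, maf_units=config.maf_units)
    out.fit_polyphen = fit

    _stage("structure adjustment")
    kinship = sa.estimate_kinship(geno)
    y_adj, chosen_models = adjust_traits(
        pheno, geno, kinship, config.pca_components, config.covariates)

    _stage("single-SNP scan with genomic control")
    for trait in pheno.traits:
        scan = at.single_snp_scan(y_adj[trait], geno, maf, trait=trait)
        lam = sa.inflation_factor([r.lr for r in scan], mode=config.lambda_mode)
        adj = lam.adjust(np.array([r.lr for r in scan]))
        from scipy import stats as _st
        for r, a in zip(scan, adj):
            r.lr = float(a)
            r.p_asymptotic = float(_st.chi2.sf(a, 1))
        out.single_snp[trait] = scan
        out.lambda_by_trait[trait] = lam.lam

    _stage("fragment tests and permutation thresholds")
    batteries = build_fragment_batteries(
        geno, annotations, maf, fit,
        maf_threshold=config.maf_threshold, min_rare=config.min_rare)
    out.results = run_association(
        y_adj, batteries, n_perm=config.n_perm,
        perm_seed=config.perm_seed, quantile=config.quantile)

    _stage("candidate filtering")
    unit_gene = {
        str(f): (str(g) if pd.notna(g) else None)
        for f, g in annotations.groupby("fragment_id")["gene_id"].first().items()
    }
    functional_by_snp = dict(zip(geno.snp_ids, (bool(c) for c in calls)))
    frag_pass = {
        frag: cf.functional_snp_filter(
            grp["snp_id"].tolist(), functional_by_snp)[0]
        for frag, grp in annotations.groupby("fragment_id")
    }
    results_by_unit: dict[tuple[str, str], list[at.TestResult]] = {}
    for r in out.results:
        results_by_unit.setdefault((r.trait, r.unit), []).append(r)
    out.reports = cf.route_units(
        results_by_unit, unit_gene, candidates or cd.CandidateGeneList(set()),
        out.results, frag_pass, alpha=config.alpha_confirm, k=config.top_k)

    rare_by_method = {
        m: [r for r in out.results if r.method == m]
        for m in at.RARE_METHODS
    }
    if all(rare_by_method.values()):
        try:
            _, out.venn = cf.cross_method_consistency(
                rare_by_method, alpha=config.alpha_consistency)
        except ValueError as exc:
            logger.warning("cross-method consistency skipped: %s", exc)

    if network is not None and candidates is not None:
        _stage("gene network interrogation")
        connected, _, _ = gn.connected_partition(network, sorted(candidates.genes))
        if len(connected) >= 3:
            try:
                retained, _ = gn.prune_seeds(
                    network, connected, auc_target=config.auc_target)
            except RuntimeError as exc:
                logger.warning("network pruning failed: %s", exc)
                retained = sorted(connected)
            out.network_retained = retained
            out.network_retrieved = gn.retrieve_neighbors(
                network, retained, top_n=config.top_n)
            pending = [
                r for r in out.reports if r.route == "top30_network_pending"
            ]
            genes = []
            for rep in pending:
                g = unit_gene.get(rep.unit)
                if g is not None:
                    genes.append(g)
            out.posterior_candidates = gn.intersect_candidates(
                genes, out.network_retrieved)

    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.results_frame().to_csv(outdir / "fragment_tests.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(
        [
            {"unit": r.unit, "trait": r.trait, "route": r.route,
             "n_functional_snps": r.n_functional_snps,
             "n_methods_significant": r.n_methods_significant}
            for r in result.reports
        ]
    ).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    with open(outdir / "venn.json", "w") as fh:
        json.dump(result.venn, fh, indent=1)
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=1, default=str)
    if result.network_retained:
        (outdir / "retained_seeds.txt").write_text(
            "\n".join(result.network_retained) + "\n")
    if result.network_retrieved:
        pd.DataFrame(result.network_retrieved,
                     columns=["gene", "score"]).to_csv(
            outdir / "network_retrieval.tsv", sep="\t", index=False)
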