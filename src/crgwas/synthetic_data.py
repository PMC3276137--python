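"""Synthetic panels with the statistical structure the pipeline assumes.

The generators emulate a resequenced candidate-gene panel of inbred
accessions: short gene fragments carrying a SNP spectrum in which about half
of all variants are rare (MAF < 5%), a proportion of functional variants that
decays as a power law of MAF, population structure with a polygenic
background Var(y) = 2K sigma_g^2 + I sigma_e^2, fragments carrying several
rare causal variants, and a gene network in which the a priori seed genes
form a tight high-LLS cluster over a sparse noise background.  Every
generator is a pure function of its spec (seed included) and returns truth
records alongside the data so recovery can be checked without
reverse-engineering the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import GenotypeMatrix, PhenotypeTable, compute_maf
from .function_prediction import DEFAULT_S_WEIGHTS
from .gene_network import GeneNetwork
from .structure_adjust import KinshipMatrix, nearest_psd

import networkx as nx


@dataclass
class SimulationSpec:
    """Study-condition knobs for the synthetic panel.

    Defaults mirror the conditions the pipeline was designed around: ~50%
    rare SNPs, the fitted power law p^F = 0.3562 p^-1.4162 (p in percent) for
    the probability a SNP is functional, inbred haploid-coded accessions in a
    structured panel.
    """

    seed: int
    n_samples: int = 96
    n_fragments: int = 60
    snps_per_fragment: tuple[int, int] = (8, 16)
    rare_fraction: float = 0.5
    maf_rare: tuple[float, float] | None = None  # default (1/n, 0.05)
    maf_common: tuple[float, float] = (0.05, 0.5)
    functional_a: float = 0.3562
    functional_b: float = -1.4162
    p_probably_given_functional: float = 0.5
    p_nonsense_given_functional: float = 0.05
    p_nonsyn_given_nonfunctional: float = 0.25
    sift_agreement: float = 0.9
    n_subpops: int = 2
    #: sd of per-subpopulation log carrier weights; 0 = panmictic panel
    divergence: float = 0.5
    n_traits: int = 4
    trait_cor: float = 0.5
    h2_polygenic: float = 0.3
    subpop_shift: float = 0.5
    causal_fragments: int = 0
    #: phenotypic variance explained by one planted fragment; a major
    #: flowering-time locus (the FRI archetype) accounts for ~20%
    causal_h2: float = 0.2
    effect_model: str = "uniform"  # or "s_weighted"


def _fragment_sizes(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.snps_per_fragment
    return rng.integers(lo, hi + 1, size=spec.n_fragments)


def simulate_genotypes(spec: SimulationSpec):
    """Genotypes for a structured inbred panel.

    Each SNP draws a target MAF from the rare/common mixture and realizes it
    as an exact minor-allele count (so the realized MAF spectrum tracks the
    target law); carriers are drawn with subpopulation-biased weights
    exp(N(0, divergence^2)) per subpopulation, which differentiates allele
    frequencies between subpopulations when divergence > 0.
    Returns (GenotypeMatrix, subpop labels, fragment_id per SNP).
    """
    if spec.n_samples < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sizes = _fragment_sizes(spec, rng)
    m = int(sizes.sum())
    labels = np.repeat(np.arange(spec.n_subpops), int(np.ceil(n / spec.n_subpops)))[:n]

    maf_rare = spec.maf_rare or (1.0 / n, 0.05)
    is_rare = rng.random(m) < spec.rare_fraction
    target = np.where(
        is_rare,
        rng.uniform(*maf_rare, size=m),
        rng.uniform(*spec.maf_common, size=m),
    )
    counts = np.clip(np.round(target * n).astype(int), 1, n // 2)
    # keep realized rarity faithful to the drawn mixture component: a
    # rare-targeted SNP stays strictly below the 5% threshold, a common one
    # at or above it
    c_rare_max = int(np.ceil(0.05 * n)) - 1
    counts[is_rare] = np.clip(counts[is_rare], 1, max(c_rare_max, 1))
    counts[~is_rare] = np.clip(counts[~is_rare], c_rare_max + 1, n // 2)
    calls = np.zeros((n, m))
    # carrier weights: subpopulation-specific multipliers per SNP
    for j in range(m):
        bias = rng.normal(0.0, spec.divergence, size=spec.n_subpops)
        w = np.exp(bias)[labels]
        carriers = rng.choice(n, size=counts[j], replace=False, p=w / w.sum())
        calls[carriers, j] = 1.0

    snp_ids, frag_ids = [], []
    for f, size in enumerate(sizes):
        for k in range(size):
            snp_ids.append(f"frag{f:04d}_snp{k:02d}")
            frag_ids.append(f"frag{f:04d}")
    # orient to minor allele
    freq = calls.mean(axis=0)
    flip = freq > 0.5
    calls[:, flip] = 1.0 - calls[:, flip]
    geno = GenotypeMatrix(
        samples=[f"acc{i:03d}" for i in range(n)],
        snp_ids=snp_ids,
        calls=calls,
        ploidy=1,
    )
    return geno, labels, np.asarray(frag_ids, dtype=object)


def simulate_annotations(geno: GenotypeMatrix, fragment_ids: np.ndarray,
                         spec: SimulationSpec) -> pd.DataFrame:
    """Per-SNP annotations with power-law functional decay.

    Each polymorphic SNP is functional with probability
    min(1, a * (100 p)^b); functional SNPs are nonsynonymous and split into
    probably/possibly damaging (with a small nonsense fraction), while
    nonfunctional SNPs distribute over benign-nonsynonymous, synonymous,
    intronic and intergenic classes.  SIFT calls agree with PolyPhen with
    probability ``sift_agreement``.  Delta scores scatter around the
    per-category S means.
    """
    rng = np.random.default_rng(spec.seed + 1)
    maf = compute_maf(geno)
    rows = []
    for j, snp in enumerate(geno.snp_ids):
        p = maf[j]
        gene = f"gene_{fragment_ids[j]}"
        if p <= 0:
            p_func = 0.0
        else:
            p_func = min(1.0, spec.functional_a * (p * 100.0) ** spec.functional_b)
        functional = rng.random() < p_func
        nonsense = False
        if functional:
            site = "nonsynonymous"
            if rng.random() < spec.p_nonsense_given_functional:
                nonsense = True
                polyphen = "probably_damaging"
            elif rng.random() < spec.p_probably_given_functional:
                polyphen = "probably_damaging"
            else:
                polyphen = "possibly_damaging"
            sift = "intolerant" if rng.random() < spec.sift_agreement else "tolerant"
        else:
            if rng.random() < spec.p_nonsyn_given_nonfunctional:
                site = "nonsynonymous"
                polyphen = "benign"
                sift = "tolerant" if rng.random() < spec.sift_agreement else "intolerant"
            else:
                site = rng.choice(["synonymous", "intronic", "intergenic"])
                polyphen = "none"
                sift = "none"
        if polyphen in ("possibly_damaging", "probably_damaging"):
            delta = max(0.0, rng.normal(DEFAULT_S_WEIGHTS[polyphen], 0.2))
        elif polyphen == "benign" or site == "synonymous":
            delta = max(0.0, rng.normal(DEFAULT_S_WEIGHTS["benign_or_synonymous"], 0.2))
        else:
            delta = np.nan
        rows.append(
            {
                "snp_id": snp,
                "fragment_id": fragment_ids[j],
                "gene_id": gene,
                "site_class": site,
                "nonsense": nonsense,
                "polyphen": polyphen,
                "sift": sift,
                "delta_score": delta,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PhenotypeTruth:
    """Ground truth written alongside simulated phenotypes."""

    causal_fragments: list[str] = field(default_factory=list)
    causal_snps: dict[str, list[str]] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0


def simulate_phenotypes(
    geno: GenotypeMatrix,
    labels: np.ndarray,
    kinship: KinshipMatrix,
    fragment_ids: np.ndarray,
    spec: SimulationSpec,
    s_weights_per_snp: np.ndarray | None = None,
) -> tuple[PhenotypeTable, PhenotypeTruth]:
    """Structured multi-trait phenotypes with optional planted causal fragments.

    y_t = subpop shift + polygenic MVN(0, 2K sigma_g^2) + causal burden +
    shared factor (inducing trait correlation) + N(0, sigma_e^2).  Under the
    s_weighted effect model each causal rare SNP's effect is proportional to
    S_j * p_j^F so the function-aided weighting matches the generative
    architecture.
    """
    if not 0 <= spec.h2_polygenic < 1:
        raise ValueError("h2_polygenic must be in [0, 1)")
    rng = np.random.default_rng(spec.seed + 2)
    n = geno.n_samples
    maf = compute_maf(geno)

    a2k = nearest_psd(2.0 * kinship.values)
    w, v = np.linalg.eigh(a2k)
    w = np.clip(w, 0, None)
    chol_like = v * np.sqrt(w)

    s2g = spec.h2_polygenic
    s2e = 1.0 - spec.h2_polygenic
    truth = PhenotypeTruth(sigma_g2=s2g, sigma_e2=s2e)

    # planted causal fragments: pick those with >= 3 rare variants
    causal_cols: np.ndarray | None = None
    if spec.causal_fragments > 0:
        frags = pd.Series(fragment_ids)
        rare_mask = (maf > 0) & (maf < 0.05)
        counts = frags[rare_mask].value_counts()
        eligible = sorted(counts[counts >= 3].index)
        if len(eligible) < spec.causal_fragments:
            raise ValueError("not enough fragments with >= 3 rare variants")
        chosen = list(rng.choice(eligible, size=spec.causal_fragments, replace=False))
        truth.causal_fragments = chosen
        burden = np.zeros(n)
        for frag in chosen:
            idx = np.where((frags == frag).to_numpy() & rare_mask)[0]
            truth.causal_snps[frag] = [geno.snp_ids[j] for j in idx]
            for j in idx:
                if spec.effect_model == "s_weighted":
                    s_j = (
                        s_weights_per_snp[j]
                        if s_weights_per_snp is not None
                        else DEFAULT_S_WEIGHTS["probably_damaging"]
                    )
                    pf = spec.functional_a * (maf[j] * 100.0) ** spec.functional_b
                    eff = s_j * pf
                else:
                    eff = 1.0
                truth.effects[geno.snp_ids[j]] = eff
                burden += eff * np.nan_to_num(geno.calls[:, j])
        causal_cols = burden

    shared = rng.standard_normal(n)
    shift = (labels - labels.mean()) * spec.subpop_shift
    values = np.empty((n, spec.n_traits))
    lam = np.sqrt(max(spec.trait_cor, 0.0))
    for t in range(spec.n_traits):
        g = chol_like @ rng.standard_normal(n) * np.sqrt(s2g)
        e = rng.standard_normal(n) * np.sqrt(s2e)
        y = shift + g + lam * shared + np.sqrt(max(0.0, 1 - lam**2)) * e
        if causal_cols is not None and causal_cols.std() > 0:
            # scale the planted burden so it explains causal_h2 of the
            # trait's total variance
            scale = np.sqrt(
                spec.causal_h2 / (1 - spec.causal_h2) * y.var()
            ) / causal_cols.std()
            y = y + scale * causal_cols
        values[:, t] = y
    pheno = PhenotypeTable(
        samples=list(geno.samples),
        traits=[f"trait{t:02d}" for t in range(spec.n_traits)],
        values=values,
    )
    return pheno, truth


def simulate_network(
    n_genes: int,
    seed_cluster_size: int,
    seed: int,
    within_lls: tuple[float, float] = (1.5, 3.0),
    noise_lls: tuple[float, float] = (0.1, 0.5),
    within_density: float = 1.0,
    noise_density: float = 0.01,
    extra_isolated_seeds: int = 0,
) -> tuple[GeneNetwork, list[str]]:
    """A planted-cluster gene network: seeds densely wired with high LLS over
    an Erdos-Renyi noise background with low LLS.

    ``extra_isolated_seeds`` appends background genes to the planted seed
    list without any preferential wiring, giving pruning something to remove.
    """
    if seed_cluster_size < 3:
        raise ValueError("seed cluster needs at least 3 genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cluster = genes[:seed_cluster_size]
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i in range(seed_cluster_size):
        for j in range(i + 1, seed_cluster_size):
            if rng.random() < within_density:
                g.add_edge(cluster[i], cluster[j],
                           lls=float(rng.uniform(*within_lls)))
    n_noise = int(noise_density * n_genes * (n_genes - 1) / 2)
    for _ in range(n_noise):
        i, j = rng.integers(0, n_genes, size=2)
        if i == j:
            continue
        a, b = genes[i], genes[j]
        if g.has_edge(a, b):
            continue
        g.add_edge(a, b, lls=float(rng.uniform(*noise_lls)))
    seeds = list(cluster)
    if extra_isolated_seeds:
        seeds += genes[seed_cluster_size:seed_cluster_size + extra_isolated_seeds]
    return GeneNetwork(graph=g), seeds


# ---------------------------------------------------------------------------
# Writers in the same TSV formats the readers consume (dogfooding).

def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.calls, index=geno.samples, columns=geno.snp_ids)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_phenotypes_tsv(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_annotations_tsv(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_network_tsv(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['lls']}\n")


def write_candidates(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
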