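"""Probabilistic gene-network interrogation by guilt-by-association.

A functional gene network is an undirected graph whose edges carry
log-likelihood scores (LLS) for a true functional interaction.  A priori
candidate genes serve as seeds: each gene is scored by the summed LLS of its
edges into the seed set, the seed set's coherence is measured by a
leave-one-out ROC AUC (seeds as positives, all other network genes as
negatives), poorly connected seeds are pruned until the AUC reaches a target,
and the retained seeds retrieve their top-scoring network neighbors for
intersection with the top association hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneNetwork:
    """Undirected gene graph with positive log-likelihood edge scores."""

    graph: nx.Graph
    n_rejected_edges: int = 0
    n_merged_duplicates: int = 0

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def load_network(path: str | Path) -> GeneNetwork:
    """Build a network from a 3-column TSV (gene_a, gene_b, lls).

    Duplicate pairs merge by maximum LLS; self-edges and non-positive scores
    are rejected and counted.
    """
    g = nx.Graph()
    rejected = merged = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            a, b, raw = parts
            try:
                lls = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad LLS {raw!r}") from exc
            if a == b or lls <= 0:
                rejected += 1
                continue
            if g.has_edge(a, b):
                merged += 1
                if lls <= g[a][b]["lls"]:
                    continue
            g.add_edge(a, b, lls=lls)
    if rejected:
        logger.info("rejected %d self/non-positive edges", rejected)
    if merged:
        logger.info("merged %d duplicate edges by max LLS", merged)
    return GeneNetwork(graph=g, n_rejected_edges=rejected,
                       n_merged_duplicates=merged)


def connected_partition(
    net: GeneNetwork, query_genes: list[str] | set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition query genes into (connected, disconnected, absent).

    connected: in the network with at least one edge to another query gene;
    disconnected: in the network but with no edge to any other query;
    absent: not a network node.
    """
    queries = set(query_genes)
    if not queries:
        raise ValueError("empty query list")
    absent = {q for q in queries if q not in net.graph}
    present = queries - absent
    connected = {
        q for q in present
        if any(nb in queries for nb in net.graph.neighbors(q))
    }
    disconnected = present - connected
    return connected, disconnected, absent


def seed_score(net: GeneNetwork, gene: str, seeds: set[str],
               mode: str = "sum") -> float:
    """Connectivity of one gene to the seed set: summed (or max) LLS over
    edges from the gene to seeds other than itself."""
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} absent from network")
    scores = [
        net.graph[gene][nb]["lls"]
        for nb in net.graph.neighbors(gene)
        if nb in seeds and nb != gene
    ]
    if not scores:
        return 0.0
    return float(sum(scores)) if mode == "sum" else float(max(scores))


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """ROC AUC via the midrank Mann-Whitney statistic."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores, method="average")
    r_pos = ranks[: len(pos)].sum()
    n_pos, n_neg = len(pos), len(neg)
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class SeedEvaluation:
    seeds: list[str]
    seed_scores: dict[str, float]
    nonseed_scores: dict[str, float]
    auc: float


def loo_roc_auc(net: GeneNetwork, seeds: set[str] | list[str],
                mode: str = "sum") -> SeedEvaluation:
    """Leave-one-out ROC AUC of seed retrieval.

    Each seed is scored against the remaining seeds (its own fold's bait);
    every non-seed network gene is scored against the full seed set.  The
    AUC is the probability a random seed outranks a random non-seed
    (midranks for ties).
    """
    seed_in = sorted(s for s in set(seeds) if s in net.graph)
    if len(seed_in) < 3:
        raise ValueError("need at least 3 seeds present in the network")
    seed_set = set(seed_in)
    s_scores = {
        s: seed_score(net, s, seed_set - {s}, mode=mode) for s in seed_in
    }
    n_scores = {
        g: seed_score(net, g, seed_set, mode=mode)
        for g in net.graph.nodes
        if g not in seed_set
    }
    if not n_scores:
        raise ValueError("network has no non-seed genes to rank against")
    auc = _auc_mann_whitney(
        np.array([s_scores[s] for s in seed_in]),
        np.array(list(n_scores.values())),
    )
    return SeedEvaluation(seeds=seed_in, seed_scores=s_scores,
                          nonseed_scores=n_scores, auc=auc)


@dataclass
class PruneTrail:
    removed: list[tuple[str, float]] = field(default_factory=list)  # (gene, auc after)
    initial_auc: float = float("nan")


def prune_seeds(
    net: GeneNetwork,
    seeds: set[str] | list[str],
    auc_target: float = 0.95,
    min_seeds: int = 3,
    mode: str = "sum",
) -> tuple[list[str], PruneTrail]:
    """Iteratively drop the least-connected seed until the LOO AUC reaches
    the target.

    Ties on the minimal LOO score break to the lexicographically smallest
    gene id.  Raises if the target is unreachable before ``min_seeds``.
    """
    current = sorted(s for s in set(seeds) if s in net.graph)
    trail = PruneTrail()
    ev = loo_roc_auc(net, current, mode=mode)
    trail.initial_auc = ev.auc
    while ev.auc < auc_target:
        if len(current) <= min_seeds:
            raise RuntimeError(
                f"AUC target {auc_target} unreachable: {len(current)} seeds "
                f"left at AUC {ev.auc:.4f}; trail={trail.removed}"
            )
        victim = min(current, key=lambda g: (ev.seed_scores[g], g))
        current.remove(victim)
        ev = loo_roc_auc(net, current, mode=mode)
        trail.removed.append((victim, ev.auc))
    return current, trail


def retrieve_neighbors(
    net: GeneNetwork,
    retained_seeds: set[str] | list[str],
    top_n: int = 200,
    mode: str = "sum",
) -> list[tuple[str, float]]:
    """Top-N non-seed genes ranked by connectivity to the retained seeds.

    Zero-score genes are excluded; ties break by gene id ascending.
    """
    seed_set = set(retained_seeds)
    if not seed_set:
        raise ValueError("empty seed set")
    scored = [
        (g, seed_score(net, g, seed_set, mode=mode))
        for g in net.graph.nodes
        if g not in seed_set
    ]
    scored = [(g, s) for g, s in scored if s > 0]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_n]


def intersect_candidates(
    top_test_genes: list[str],
    retrieved: list[tuple[str, float]],
) -> list[dict]:
    """Posterior candidates: top-test genes (not on the a priori list) that
    the network also retrieves, with their test rank and network score."""
    retrieved_scores = dict(retrieved)
    if top_test_genes and retrieved and not (
        set(g[:2] for g in top_test_genes) & set(g[:2] for g in retrieved_scores)
    ):
        logger.warning("gene id namespaces look disjoint; check inputs")
    out = []
    for rank, gene in enumerate(top_test_genes, start=1):
        if gene in retrieved_scores:
            out.append(
                {"gene": gene, "test_rank": rank,
                 "network_score": retrieved_scores[gene]}
            )
    return out
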