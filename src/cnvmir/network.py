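"""Guilt-by-association construction of the disease gene network.

Candidate genes from two study designs (association and rare-CNV) are
merged, filtered on brain-relevance criteria (>= 1 of 3 for candidates,
>= 2 of 3 for other genes), and every brain-relevant gene is scored
additively over its first-degree neighbors in the weight-filtered
interaction network: +2.5 per candidate neighbor, +0.5 per brain-relevant
neighbor, -1 per other neighbor.  Genes scoring >= 1.5 are retained as
partners, and the final network is the subgraph induced on candidates plus
retained partners, with isolated nodes dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .types import InteractionEdge, PipelineConfig, ValidationError

logger = logging.getLogger("cnvmir")


@dataclass(frozen=True)
class GbaScore:
    gene: str
    score: float
    n_candidate_neighbors: int
    n_brain_neighbors: int
    n_other_neighbors: int


@dataclass
class DiseaseNetwork:
    candidates: set[str]
    partners: set[str]
    edges: list[InteractionEdge]
    scores: dict[str, GbaScore]

    @property
    def nodes(self) -> set[str]:
        return self.candidates | self.partners

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def merge_candidates(list_a: list[str], list_b: list[str]) -> tuple[set[str], dict[str, int]]:
    """Union of the two candidate lists, with overlap bookkeeping."""
    a, b = set(list_a), set(list_b)
    union = a | b
    stats = {
        "n_a": len(a),
        "n_b": len(b),
        "n_shared": len(a & b),
        "n_union": len(union),
    }
    return union, stats


def apply_relevance_filter(
    genes: set[str], annotations: pd.DataFrame, min_criteria: int
) -> set[str]:
    """Genes meeting at least *min_criteria* of the three relevance flags.

    *annotations* is indexed by gene with boolean columns expression /
    function / phenotype.  A gene absent from the table meets 0 criteria.
    """
    kept: set[str] = set()
    missing = 0
    cols = ["expression", "function", "phenotype"]
    met = annotations[cols].sum(axis=1)
    for g in genes:
        if g in met.index:
            if met[g] >= min_criteria:
                kept.add(g)
        else:
            missing += 1
    if missing:
        logger.info("relevance filter: %d gene(s) unannotated (treated as 0 criteria)", missing)
    return kept


def criteria_met(genes: set[str], annotations: pd.DataFrame) -> dict[str, int]:
    met = annotations[["expression", "function", "phenotype"]].sum(axis=1)
    return {g: int(met.get(g, 0)) for g in genes}


def build_graph(edges: list[InteractionEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, weight=e.weight)
    return g


def _score_gene(
    gene: str,
    graph: nx.Graph,
    candidates: set[str],
    brain_genes: set[str],
    weights: tuple[float, float, float],
) -> GbaScore:
    penalty, w_brain, w_candidate = weights
    n_cand = n_brain = n_other = 0
    for nb in graph.neighbors(gene):
        if nb in candidates:
            n_cand += 1
        elif nb in brain_genes:
            n_brain += 1
        else:
            n_other += 1
    score = w_candidate * n_cand + w_brain * n_brain + penalty * n_other
    return GbaScore(gene, score, n_cand, n_brain, n_other)


def gba_score(
    graph: nx.Graph,
    candidates: set[str],
    brain_genes: set[str],
    weights: tuple[float, float, float] = (-1.0, 0.5, 2.5),
) -> dict[str, GbaScore]:
    """Additive first-degree-neighbor score for every brain-relevant gene.

    *weights* is (penalty per other neighbor, bonus per brain-relevant
    neighbor, bonus per candidate neighbor).  Genes absent from the graph
    receive no score.  Candidates and brain genes must be disjoint.
    """
    if candidates & brain_genes:
        overlap = sorted(candidates & brain_genes)[:5]
        raise ValidationError(f"candidate and brain-relevant sets overlap: {overlap}...")
    return {
        g: _score_gene(g, graph, candidates, brain_genes, weights)
        for g in sorted(brain_genes)
        if g in graph
    }


def build_network(
    graph: nx.Graph,
    candidates: set[str],
    scores: dict[str, GbaScore],
    retain_min: float = 1.5,
) -> DiseaseNetwork:
    """Induce the final network on candidates plus high-scoring partners.

    Partners are scored genes with score >= retain_min (inclusive).  Edges
    are all interactions with both endpoints inside the node set; nodes left
    without any edge are dropped, so a candidate with no retained neighbor
    disappears from the final network.
    """
    partners = {g for g, s in scores.items() if s.score >= retain_min}
    keep = (candidates | partners)
    edges = [
        InteractionEdge(a, b, graph[a][b].get("weight", 1.0))
        for a, b in graph.edges()
        if a in keep and b in keep
    ]
    connected = {g for e in edges for g in e.pair}
    return DiseaseNetwork(
        candidates=candidates & connected,
        partners=partners & connected,
        edges=sorted(edges, key=lambda e: e.pair),
        scores=scores,
    )


def rank_by_score(
    network: DiseaseNetwork,
    graph: nx.Graph,
    brain_genes: set[str],
    weights: tuple[float, float, float] = (-1.0, 0.5, 2.5),
    top_n: int | None = None,
) -> list[tuple[str, float]]:
    """Rank all network genes by the additive score, descending.

    Candidates are not scored during construction, so the same additive
    formula is applied to them here to produce a single ranking over the
    whole network.  Ties break lexicographically on gene id.
    """
    if top_n is not None and top_n <= 0:
        raise ValidationError(f"top_n must be positive, got {top_n}")
    ranking: list[tuple[str, float]] = []
    for g in network.nodes:
        if g in network.scores:
            s = network.scores[g].score
        else:
            s = _score_gene(g, graph, network.candidates, brain_genes, weights).score
        ranking.append((g, s))
    ranking.sort(key=lambda t: (-t[1], t[0]))
    return ranking if top_n is None else ranking[:top_n]


def network_summary(
    network: DiseaseNetwork, n_candidates_initial: int, n_brain_initial: int
) -> dict[str, int]:
    return {
        "n_nodes": len(network.nodes),
        "n_candidates": len(network.candidates),
        "n_partners": len(network.partners),
        "n_edges": network.n_edges,
        "n_candidates_initial": n_candidates_initial,
        "n_brain_initial": n_brain_initial,
    }
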