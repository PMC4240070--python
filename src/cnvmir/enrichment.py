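"""Gene-set enrichment of miRNA target lists against an all-target background.

For each (miRNA, gene-set) pair a 2x2 contingency table is built within the
universe of all predicted miRNA targets: targets of the miRNA in / not in
the set versus targets of other miRNAs in / not in the set, counting only
genes that belong to at least one gene-set.  Over-representation is tested
with the one-tailed (right tail) Fisher exact test, Benjamini-Hochberg
adjusted per run, and results across the three top-k runs are combined by a
consensus filter.  Surviving sets can be exported as an enrichment-map
similarity graph (nodes = sets, edges = Jaccard/overlap combined
coefficient above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targets import TopKLists
from .types import GeneSet, PipelineConfig


@dataclass(frozen=True)
class ContingencyCells:
    """Cells of the miRNA x gene-set table (within the gene-set universe).

    a: targets of the miRNA in the set;
    b: targets of the miRNA in some other set but not this one;
    c: background (other-miRNA) targets in the set;
    d: background targets in some other set but not this one.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def filter_genesets(
    collection: list[GeneSet],
    min_size: int,
    max_size: int,
    universe: set[str] | None = None,
) -> list[GeneSet]:
    """Keep gene-sets whose size within *universe* lies in [min_size, max_size].

    Bounds are inclusive.  If a universe is given, each set is first
    restricted to it (sets are sized on analyzable genes only).
    """
    out: list[GeneSet] = []
    for gs in collection:
        genes = gs.genes if universe is None else gs.genes & universe
        if min_size <= len(genes) <= max_size:
            out.append(GeneSet(gs.set_id, gs.name, frozenset(genes), gs.source))
    return out


def build_contingency(
    targets_i: set[str],
    background: set[str],
    gs_j: GeneSet,
    all_sets_union: set[str],
) -> ContingencyCells:
    """Count the four cells; genes belonging to no gene-set are uncounted."""
    if not background:
        raise ValueError("background gene universe is empty")
    t = targets_i & background
    gs = gs_j.genes & all_sets_union
    rest = background - t
    a = len(t & gs)
    b = len((t & all_sets_union) - gs)
    c = len(rest & gs)
    d = len((rest & all_sets_union) - gs)
    return ContingencyCells(a, b, c, d)


def fisher_one_tailed(cells: ContingencyCells) -> float:
    """Right-tail Fisher exact p: P(X >= a) with all margins fixed."""
    a, b, c, d = cells.a, cells.b, cells.c, cells.d
    if a == 0:
        return 1.0  # P(X >= 0) = 1, also covering the degenerate empty table
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    topk_lists: dict[str, TopKLists],
    background: set[str],
    genesets: list[GeneSet],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-(miRNA, set, k) enrichment table with p and per-run BH FDR.

    Gene-sets are size-filtered within the background universe.  A miRNA
    with fewer targets than the smallest k level contributes a single run at
    its full list length (short-list mode).  FDR is adjusted within each
    (miRNA, k) run across the gene-set collection.
    """
    config = config or PipelineConfig()
    filtered = filter_genesets(
        genesets, config.geneset_min, config.geneset_max, universe=background
    )
    union = set().union(*(gs.genes for gs in filtered)) if filtered else set()
    rows: list[dict] = []
    for mirna_id, lists in sorted(topk_lists.items()):
        n_targets = lists.n_targets
        if n_targets == 0:
            continue
        short = n_targets < min(config.topk_levels)
        levels = (config.topk_levels[0],) if short else config.topk_levels
        for k in levels:
            targets = set(lists.lists.get(k, ())) & background
            pvals, recs = [], []
            for gs in filtered:
                cells = build_contingency(targets, background, gs, union)
                p = fisher_one_tailed(cells)
                pvals.append(p)
                recs.append((gs.set_id, cells, p))
            fdrs = bh_fdr(pvals)
            for (set_id, cells, p), fdr in zip(recs, fdrs):
                rows.append(
                    {
                        "mirna_id": mirna_id,
                        "set_id": set_id,
                        "k_level": k,
                        "short_list": short,
                        "a": cells.a,
                        "b": cells.b,
                        "c": cells.c,
                        "d": cells.d,
                        "p": p,
                        "fdr": fdr,
                        "nominal_hit": p <= (config.short_list_p if short else config.nominal_p),
                        "fdr25": fdr <= config.fdr_border,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "set_id", "k_level", "short_list",
            "a", "b", "c", "d", "p", "fdr", "nominal_hit", "fdr25",
        ],
    )


def consensus_filter(results: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-(miRNA, set) consensus flags over the top-k runs.

    Standard case: nominal p <= 0.01 in at least 2 of the 3 runs.  Short-list
    case (a miRNA whose full list is below the smallest k, hence one run):
    the single p must be <= 0.005.
    """
    config = config or PipelineConfig()
    if results.empty:
        return pd.DataFrame(
            columns=["mirna_id", "set_id", "n_runs", "n_nominal", "min_p", "min_fdr", "consensus", "fdr25"]
        )
    rows = []
    for (mirna_id, set_id), grp in results.groupby(["mirna_id", "set_id"], sort=True):
        short = bool(grp["short_list"].iloc[0])
        if short:
            hits = int((grp["p"] <= config.short_list_p).sum())
            consensus = hits >= 1
        else:
            hits = int((grp["p"] <= config.nominal_p).sum())
            consensus = hits >= config.consensus_min_runs
        rows.append(
            {
                "mirna_id": mirna_id,
                "set_id": set_id,
                "n_runs": len(grp),
                "n_nominal": hits,
                "min_p": float(grp["p"].min()),
                "min_fdr": float(grp["fdr"].min()),
                "consensus": consensus,
                "fdr25": bool((grp["fdr"] <= config.fdr_border).any()),
            }
        )
    return pd.DataFrame(rows)


def similarity_coefficients(set_a: frozenset[str], set_b: frozenset[str]) -> tuple[float, float, float]:
    """(jaccard, overlap, combined) for two gene-sets.

    combined = 0.5 * |A&B|/|A|B| + 0.5 * |A&B|/min(|A|,|B|), the equal-weight
    enrichment-map convention.
    """
    inter = len(set_a & set_b)
    if inter == 0:
        return 0.0, 0.0, 0.0
    jac = inter / len(set_a | set_b)
    ovl = inter / min(len(set_a), len(set_b))
    return jac, ovl, 0.5 * jac + 0.5 * ovl


def enrichment_map_export(
    consensus: pd.DataFrame,
    genesets: list[GeneSet],
    similarity_threshold: float = 0.225,
    jaccard_weight: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables of the similarity graph over consensus gene-sets.

    Nodes carry the set size, the miRNAs hitting the set, a multi-miRNA
    flag, and whether any contributing run reached the FDR border.  Edges
    connect sets whose combined coefficient meets the threshold.
    """
    flagged = consensus[consensus["consensus"]]
    by_set: dict[str, GeneSet] = {gs.set_id: gs for gs in genesets}
    node_rows = []
    for set_id, grp in flagged.groupby("set_id", sort=True):
        gs = by_set[set_id]
        mirnas = sorted(grp["mirna_id"].unique())
        node_rows.append(
            {
                "set_id": set_id,
                "name": gs.name,
                "size": gs.size,
                "mirnas": ",".join(mirnas),
                "n_mirnas": len(mirnas),
                "multi_mirna": len(mirnas) > 1,
                "fdr25": bool(grp["fdr25"].any()),
            }
        )
    nodes = pd.DataFrame(
        node_rows,
        columns=["set_id", "name", "size", "mirnas", "n_mirnas", "multi_mirna", "fdr25"],
    )
    edge_rows = []
    ids = list(nodes["set_id"])
    for i, sa in enumerate(ids):
        for sb in ids[i + 1:]:
            inter = len(by_set[sa].genes & by_set[sb].genes)
            if inter == 0:
                continue
            jac = inter / len(by_set[sa].genes | by_set[sb].genes)
            ovl = inter / min(by_set[sa].size, by_set[sb].size)
            combined = jaccard_weight * jac + (1.0 - jaccard_weight) * ovl
            if combined >= similarity_threshold:
                edge_rows.append(
                    {"set_a": sa, "set_b": sb, "jaccard": jac, "overlap_coef": ovl, "combined": combined}
                )
    edges = pd.DataFrame(
        edge_rows, columns=["set_a", "set_b", "jaccard", "overlap_coef", "combined"]
    )
    return nodes, edges
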