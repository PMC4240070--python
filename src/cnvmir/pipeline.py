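"""End-to-end orchestration: density, targets, enrichment, network, overlap.

Each stage reads plain TSV/GFF/GMT inputs, writes plain TSV/JSON outputs
under the run directory, and records its counts in a manifest, so any stage
can be rerun and inspected independently.  Identical inputs and
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import density as dn
from . import enrichment as en
from . import io as cio
from . import network as nw
from . import overlap as ov
from . import targets as tg
from .synth import TOOL_POLARITY, TOOL1, TOOL2
from .types import PipelineConfig


logger = logging.getLogger("cnvmir")


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "counts": self.counts,
                    "outputs": self.outputs,
                    "started": self.started,
                    "finished": self.finished,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return inner
    return wrap


@_stage("density")
def run_density(config: PipelineConfig, gff_path: str, outdir: Path) -> dict:
    loci = cio.read_mirna_gff(gff_path)
    result = dn.region_density(loci, config.region, config.window_flank_bp)
    pd.DataFrame(
        [
            {
                "region": f"{config.region.chrom}:{config.region.start}-{config.region.end}",
                "region_count": result.region_count,
                "n_comparison_loci": len(result.window_counts) - result.region_count,
                "percentile_exceeded": result.percentile_exceeded,
            }
        ]
    ).to_csv(outdir / "density_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(result.window_counts.items()), columns=["mirna_id", "window_count"]
    ).to_csv(outdir / "window_counts.tsv", sep="\t", index=False)
    return {
        "n_loci": len(loci),
        "region_count": result.region_count,
        "percentile_exceeded": result.percentile_exceeded,
    }


@_stage("targets")
def run_targets(
    config: PipelineConfig, scores1: str, scores2: str, gff_path: str, outdir: Path
) -> tuple[dict, dict[str, tg.TopKLists], dict[str, list[tg.PercentileTarget]]]:
    loci = cio.read_mirna_gff(gff_path)
    known = {l.mirna_id for l in loci}
    rec1 = cio.read_score_table(scores1, TOOL1, TOOL_POLARITY[TOOL1])
    rec2 = cio.read_score_table(scores2, TOOL2, TOOL_POLARITY[TOOL2])
    p1 = tg.collapse_arms(tg.percentile_transform(rec1, TOOL_POLARITY[TOOL1]), known)
    p2 = tg.collapse_arms(tg.percentile_transform(rec2, TOOL_POLARITY[TOOL2]), known)
    integrated = tg.integrate_tools(p1, p2)
    topk_lists = {
        m: tg.topk(targets, config.topk_levels) for m, targets in integrated.items()
    }
    rows = []
    for m in sorted(integrated):
        targets = integrated[m]
        rows.append(
            {
                "mirna_id": m,
                "n_targets": len(targets),
                "mean_top_score": tg.mean_top_score(targets, config.topk_levels[0]),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "targets_summary.tsv", sep="\t", index=False)
    ranked = pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id,
                "gene": t.gene,
                "percentile_tool1": t.percentile_tool1,
                "percentile_tool2": t.percentile_tool2,
                "final_score": t.final_score,
                "rank": t.rank,
            }
            for m in sorted(integrated)
            for t in integrated[m]
        ]
    )
    ranked.to_csv(outdir / "targets_ranked.tsv", sep="\t", index=False)
    counts = {
        "n_score_records": {TOOL1: len(rec1), TOOL2: len(rec2)},
        "n_targets_per_mirna": {m: len(v) for m, v in sorted(integrated.items())},
        "n_excluded_mirnas": sum(1 for v in integrated.values() if not v),
    }
    return counts, topk_lists, integrated


@_stage("enrich")
def run_enrich(
    config: PipelineConfig,
    topk_lists: dict[str, tg.TopKLists],
    region_mirnas: list[str],
    gmt_path: str,
    outdir: Path,
) -> dict:
    genesets = cio.read_gmt(gmt_path)
    background = set()
    for lists in topk_lists.values():
        for genes in lists.lists.values():
            background.update(genes)
    region_lists = {m: topk_lists[m] for m in region_mirnas if m in topk_lists}
    results = en.run_enrichment(region_lists, background, genesets, config)
    consensus = en.consensus_filter(results, config)
    filtered = en.filter_genesets(
        genesets, config.geneset_min, config.geneset_max, universe=background
    )
    nodes, edges = en.enrichment_map_export(
        consensus, filtered, config.similarity_threshold
    )
    results.to_csv(outdir / "enrichment_results.tsv", sep="\t", index=False)
    consensus.to_csv(outdir / "enrichment_consensus.tsv", sep="\t", index=False)
    nodes.to_csv(outdir / "enrichmap_nodes.tsv", sep="\t", index=False)
    edges.to_csv(outdir / "enrichmap_edges.tsv", sep="\t", index=False)
    return {
        "n_genesets": len(genesets),
        "n_genesets_filtered": len(filtered),
        "n_background_genes": len(background),
        "n_tests": len(results),
        "n_consensus_sets": int(consensus["consensus"].sum()) if len(consensus) else 0,
        "n_map_nodes": len(nodes),
        "n_map_edges": len(edges),
    }


@_stage("network")
def run_network(
    config: PipelineConfig,
    edges_path: str,
    gwas_path: str,
    cnv_path: str,
    relevance_path: str,
    outdir: Path,
) -> tuple[dict, nw.DiseaseNetwork, list[tuple[str, float]], set[str]]:
    edges, ppi_nodes = cio.read_edge_list(edges_path, config.edge_weight_min)
    graph = nw.build_graph(edges)
    relevance = cio.read_relevance_table(relevance_path)
    merged, merge_stats = nw.merge_candidates(
        cio.read_id_list(gwas_path), cio.read_id_list(cnv_path)
    )
    candidates = nw.apply_relevance_filter(merged, relevance, config.candidate_criteria_min)
    others = set(relevance.index) - merged
    brain = nw.apply_relevance_filter(others, relevance, config.partner_criteria_min)
    weights = (config.score_penalty, config.score_brain, config.score_candidate)
    scores = nw.gba_score(graph, candidates, brain, weights)
    network = nw.build_network(graph, candidates, scores, config.retain_score_min)
    ranking = nw.rank_by_score(network, graph, brain, weights)

    crit = nw.criteria_met(network.nodes, relevance)
    pd.DataFrame(
        [
            {
                "gene": g,
                "role": "candidate" if g in network.candidates else "partner",
                "score": s,
                "criteria_met": crit[g],
            }
            for g, s in ranking
        ]
    ).to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    cio.write_edge_list(network.edges, outdir / "network_edges.tsv")
    counts = {
        **{f"candidates_{k}": v for k, v in merge_stats.items()},
        "n_candidates_filtered": len(candidates),
        "n_brain_genes": len(brain),
        "n_ppi_edges": len(edges),
        "n_ppi_nodes": len(ppi_nodes),
        "n_scored": len(scores),
        **nw.network_summary(network, len(candidates), len(brain)),
    }
    with open(outdir / "network_summary.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    return counts, network, ranking, ppi_nodes


@_stage("overlap")
def run_overlap(
    config: PipelineConfig,
    topk_lists: dict[str, tg.TopKLists],
    region_mirnas: list[str],
    dysregulated_path: str,
    network: nw.DiseaseNetwork,
    ranking: list[tuple[str, float]],
    universe: set[str],
    outdir: Path,
) -> dict:
    k = config.topk_levels[0]
    region_lists = {m: topk_lists[m] for m in region_mirnas if m in topk_lists}
    region_set = ov.region_target_union(region_lists, k)
    dysregulated = cio.read_id_list(dysregulated_path)
    dg_set = ov.dgcr8_set(
        topk_lists, dysregulated, config.overlap_min_mirnas, exclude=region_set, k=k
    )
    tests = [
        ov.overlap_test(mech, network.nodes, universe)
        for mech in (region_set, dg_set)
    ]
    pd.DataFrame(
        [
            {
                "mechanism": t.mechanism,
                "a": t.n_in_network,
                "b": t.n_mechanism - t.n_in_network,
                "c": t.n_network - t.n_in_network,
                "d": t.n_universe - t.n_mechanism - t.n_network + t.n_in_network,
                "p": t.p,
                "odds_ratio": t.odds_ratio,
                "n_dropped_out_of_universe": t.n_dropped_out_of_universe,
            }
            for t in tests
        ]
    ).to_csv(outdir / "overlap_tests.tsv", sep="\t", index=False)
    rows, summary = ov.annotate_top_genes(ranking, [region_set, dg_set], config.top_n_genes)
    pd.DataFrame(rows).to_csv(outdir / "top_genes.tsv", sep="\t", index=False)
    return {
        "n_region_set": len(region_set.genes),
        "n_dgcr8_set": len(dg_set.genes),
        "tests": {
            t.mechanism: {"a": t.n_in_network, "p": t.p, "odds_ratio": t.odds_ratio}
            for t in tests
        },
        "top_genes": summary,
    }


def run_all(config: PipelineConfig, paths: dict[str, str], outdir: str | Path) -> RunManifest:
    """Run every stage in dependency order and write a manifest.

    *paths* must provide: gff, scores_tool1, scores_tool2, gmt, edges,
    candidates_gwas, candidates_cnv, relevance, dysregulated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = [
        "gff", "scores_tool1", "scores_tool2", "gmt", "edges",
        "candidates_gwas", "candidates_cnv", "relevance", "dysregulated",
    ]
    stage_of = {
        "gff": "density", "scores_tool1": "targets", "scores_tool2": "targets",
        "gmt": "enrich", "edges": "network", "candidates_gwas": "network",
        "candidates_cnv": "network", "relevance": "network",
        "dysregulated": "overlap",
    }
    for key in required:
        if key not in paths:
            raise StageError(stage_of[key], FileNotFoundError(f"missing input {key!r}"))
        if not Path(paths[key]).exists():
            raise StageError(stage_of[key], FileNotFoundError(paths[key]))

    manifest = RunManifest(config=_config_dict(config))
    manifest.started = datetime.now(timezone.utc).isoformat()

    manifest.counts["density"] = run_density(config, paths["gff"], outdir)

    tcounts, topk_lists, _integrated = run_targets(
        config, paths["scores_tool1"], paths["scores_tool2"], paths["gff"], outdir
    )
    manifest.counts["targets"] = tcounts

    loci = cio.read_mirna_gff(paths["gff"])
    region_mirnas = [l.mirna_id for l in loci if config.region.contains(l.interval)]
    manifest.counts["enrich"] = run_enrich(
        config, topk_lists, region_mirnas, paths["gmt"], outdir
    )

    ncounts, network, ranking, ppi_nodes = run_network(
        config, paths["edges"], paths["candidates_gwas"], paths["candidates_cnv"],
        paths["relevance"], outdir,
    )
    manifest.counts["network"] = ncounts

    manifest.counts["overlap"] = run_overlap(
        config, topk_lists, region_mirnas, paths["dysregulated"],
        network, ranking, ppi_nodes, outdir,
    )

    manifest.outputs = {
        p.name: str(p)
        for p in sorted(outdir.iterdir())
        if p.suffix in {".tsv", ".json"} and p.name != "manifest.json"
    }
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dict(vars(config))
    r = d["region"]
    d["region"] = f"{r.chrom}:{r.start}-{r.end}"
    d["topk_levels"] = list(d["topk_levels"])
    return d
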