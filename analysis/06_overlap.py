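#!/usr/bin/env python
"""Overlap of miRNA-mechanism target sets with the disease network.

Builds the region-miRNA mechanism set (union of the region miRNAs' top-200
targets) and the microprocessor-haploinsufficiency set (genes in the
top-200 lists of >= 2 dysregulated miRNAs, excluding region targets), then
tests each for over-representation among the network's genes with the
one-sided Fisher exact test over the interaction-network universe.
"""

import json
import shutil
from pathlib import Path

import pandas as pd

from cnvmir import io as cio
from cnvmir import pipeline as pl
from cnvmir.types import PipelineConfig, parse_region

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
OUT = ROOT / "scratch" / "analysis" / "overlap"
RESULTS = ROOT / "results"
OUT.mkdir(parents=True, exist_ok=True)

manifest = json.loads((DATA / "manifest.json").read_text())
config = PipelineConfig(region=parse_region(manifest["region"]))

_c, topk_lists, _i = pl.run_targets(
    config, str(DATA / "scores_tool1.tsv"), str(DATA / "scores_tool2.tsv"),
    str(DATA / "mirnas.gff3"), OUT,
)
loci = cio.read_mirna_gff(DATA / "mirnas.gff3")
region_mirnas = [l.mirna_id for l in loci if config.region.contains(l.interval)]
_nc, network, ranking, ppi_nodes = pl.run_network(
    config, str(DATA / "edges.tsv"), str(DATA / "candidates_gwas.txt"),
    str(DATA / "candidates_cnv.txt"), str(DATA / "relevance.tsv"), OUT,
)
counts = pl.run_overlap(
    config, topk_lists, region_mirnas, str(DATA / "dysregulated_mirnas.txt"),
    network, ranking, ppi_nodes, OUT,
)

shutil.copy(OUT / "overlap_tests.tsv", RESULTS / "overlap_tests.tsv")
shutil.copy(OUT / "top_genes.tsv", RESULTS / "top_genes.tsv")

print(f"region mechanism set: {counts['n_region_set']} genes")
print(f"haploinsufficiency mechanism set: {counts['n_dgcr8_set']} genes (region targets excluded)")
for label, t in counts["tests"].items():
    print(f"  {label}: overlap a={t['a']}, one-sided p={t['p']:.4g}, OR={t['odds_ratio']:.2f}")
tg = counts["top_genes"]
print(
    f"top-{int(tg['top_n'])} network genes hit by either mechanism: "
    f"{int(tg['n_hit'])} ({100 * tg['fraction_hit']:.0f}%)"
)
print(f"tables: {RESULTS / 'overlap_tests.tsv'}, {RESULTS / 'top_genes.tsv'}")
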