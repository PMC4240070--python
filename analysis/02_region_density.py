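#!/usr/bin/env python
"""Region miRNA count and genome-wide density percentile.

Counts the loci contained in the query window and compares that count with
same-sized windows centered on every other miRNA locus genome-wide.  The
planted cluster should out-dense essentially all background windows.
"""

import json
import shutil
from pathlib import Path

from cnvmir import io as cio
from cnvmir import pipeline as pl
from cnvmir.types import PipelineConfig, parse_region

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
OUT = ROOT / "scratch" / "analysis" / "density"
RESULTS = ROOT / "results"
OUT.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(exist_ok=True)

manifest = json.loads((DATA / "manifest.json").read_text())
config = PipelineConfig(region=parse_region(manifest["region"]))

counts = pl.run_density(config, str(DATA / "mirnas.gff3"), OUT)
shutil.copy(OUT / "density_summary.tsv", RESULTS / "density_summary.tsv")

print(f"{counts['region_count']} miRNA loci contained in the query region")
print(
    f"region count exceeds {100 * counts['percentile_exceeded']:.1f}% of "
    f"same-sized windows around other miRNA loci"
)
print(f"summary table: {RESULTS / 'density_summary.tsv'}")
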