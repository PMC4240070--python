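#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the data a region-miRNA analysis starts from: a genome-wide miRNA
annotation whose planted 7-locus cluster sits in a 2.6 Mb window, two
target-prediction score tables, a gene-set collection, a weighted
interaction network with a candidate-linked core, candidate lists (35 and
107 genes sharing one), and brain-relevance flags.  One planted gene-set
enrichment is included so the downstream enrichment stage has signal to
find.  Raw files go under scratch/ (they are large); a small manifest is
echoed here.
"""

import json
from pathlib import Path

from cnvmir import synth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
SEED = 1

spec = synth.SynthSpec(
    seed=SEED,
    geneset_size_range=(100, 250),
    planted_enrichment=[("miR-R1", "GS001", 0.08)],
    core_density_boost=40.0,
)
paths = synth.write_bundle(spec, DATA)

print(f"wrote synthetic bundle to {DATA}")
print(f"region (planted cluster window): {spec.region.chrom}:{spec.region.start}-{spec.region.end}")
print(f"loci: {spec.cluster_size} region + {spec.n_background_mirnas} background")
print(f"planted enrichment: miR-R1 -> GS001 at fraction 0.08")
print(json.dumps({k: Path(v).name for k, v in paths.items()}, indent=2))
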