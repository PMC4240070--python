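import pytest

from cnvmir import synth
from cnvmir.types import GenomicInterval, MirnaLocus


def small_spec(seed: int = 0, **overrides) -> synth.SynthSpec:
    """A fast, fully-featured synthetic study for integration tests."""
    kwargs = dict(
        seed=seed,
        n_background_mirnas=20,
        n_genes=1000,
        n_genesets=20,
        geneset_size_range=(15, 80),
        targets_per_mirna=300,
        intertool_overlap=0.8,
        n_dysregulated=10,
    )
    kwargs.update(overrides)
    return synth.SynthSpec(**kwargs)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One generated fixture bundle shared across integration tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    spec = small_spec(seed=7)
    paths = synth.write_bundle(spec, outdir)
    return spec, paths


def make_locus(mirna_id, chrom, start, end, arms=("5p", "3p")) -> MirnaLocus:
    return MirnaLocus(mirna_id, GenomicInterval(chrom, start, end), frozenset(arms))


# the seven miRNA loci of the typical 22q11.2 deletion region (hg19)
REGION_LOCI = [
    ("miR-185", 20020662, 20020743),
    ("miR-649", 21388465, 21388561),
    ("miR-1286", 20236657, 20236734),
    ("miR-1306", 20073581, 20073665),
    ("miR-3618", 20073269, 20073356),
    ("miR-4761", 19951276, 19951357),
    ("miR-6816", 20102209, 20102274),
]


@pytest.fixture
def region_loci():
    return [make_locus(m, "chr22", s, e) for m, s, e in REGION_LOCI]
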