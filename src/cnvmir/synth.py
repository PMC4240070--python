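"""Seeded synthetic fixtures with planted statistical structure.

The generator emulates every external input of the pipeline at desk scale:
a genome-wide miRNA annotation with one dense planted cluster (the CNV
region analog), two target-prediction score tables with controllable
inter-tool agreement and planted gene-set enrichment, a gene-set
collection, a weighted interaction network with a dense candidate-linked
core, candidate gene lists, and per-gene brain-relevance flags.  Everything
is deterministic under the spec's seed.

Study-scale constants (7-locus cluster in a 2.6 Mb span, 35- and 107-gene
candidate lists sharing one gene, -1/+0.5/+2.5 neighbor weights downstream)
follow the study design; the remaining sizes are scaled down so a full run
takes seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .types import (
    GeneSet,
    GenomicInterval,
    InteractionEdge,
    LARGER_IS_STRONGER,
    MirnaLocus,
    ScoreRecord,
    SMALLER_IS_STRONGER,
)


class ConfigurationError(ValueError):
    """A SynthSpec combination that cannot be realized."""


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    The planted miRNA cluster has the study's size (7 loci in 2.6 Mb); the
    candidate lists have the study's sizes (35 and 107 genes, 1 shared);
    relevance-flag marginals approximate the study's genome fractions
    (brain expression ~0.46, neuronal function ~0.16, mouse neuro
    phenotype ~0.17); the interaction network's mean degree (~12.8)
    matches the study's edge/node ratio.  Gene counts, miRNA counts and
    gene-set counts are scaled down for speed.
    """

    n_chromosomes: int = 4
    chrom_length_bp: int = 60_000_000
    n_background_mirnas: int = 150
    cluster_size: int = 7
    cluster_span_bp: int = 2_600_000
    locus_length_bp: int = 80
    n_genes: int = 4000
    n_genesets: int = 60
    geneset_size_range: tuple[int, int] = (15, 250)
    planted_enrichment: list[tuple[str, str, float]] = field(default_factory=list)
    targets_per_mirna: int = 1200
    intertool_overlap: float = 0.7
    n_region_without_predictions: int = 1
    n_candidates_gwas: int = 35
    n_candidates_cnv: int = 107
    shared_candidates: int = 1
    relevance_marginals: tuple[float, float, float] = (0.46, 0.16, 0.17)
    candidate_pass_frac: float = 118 / 141
    ppi_mean_degree: float = 12.8
    core_density_boost: float = 25.0
    n_core_partners: int = 40
    frac_below_weight_min: float = 0.2
    n_dysregulated: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_span_bp > self.chrom_length_bp:
            raise ConfigurationError("cluster_span_bp exceeds chrom_length_bp")
        if self.targets_per_mirna > self.n_genes:
            raise ConfigurationError("targets_per_mirna exceeds n_genes")
        if self.shared_candidates > min(self.n_candidates_gwas, self.n_candidates_cnv):
            raise ConfigurationError("shared_candidates exceeds a candidate list size")
        if not 0.0 <= self.intertool_overlap <= 1.0:
            raise ConfigurationError("intertool_overlap must lie in [0, 1]")

    @property
    def gene_universe(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def region(self) -> GenomicInterval:
        """The planted cluster's window (centered on chromosome 1)."""
        start = (self.chrom_length_bp - self.cluster_span_bp) // 2 + 1
        return GenomicInterval("chr1", start, start + self.cluster_span_bp - 1)

    @property
    def region_mirna_ids(self) -> list[str]:
        return [f"miR-R{i}" for i in range(1, self.cluster_size + 1)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


TOOL1 = "tool1"  # smaller raw score = stronger prediction
TOOL2 = "tool2"  # larger raw score = stronger prediction
TOOL_POLARITY = {TOOL1: SMALLER_IS_STRONGER, TOOL2: LARGER_IS_STRONGER}


# ---------------------------------------------------------------------------
# miRNA annotation
# ---------------------------------------------------------------------------

def gen_mirna_annotation(spec: SynthSpec) -> list[MirnaLocus]:
    """Background loci uniform per chromosome plus one planted cluster.

    The cluster's loci fall inside ``spec.region`` on chromosome 1;
    background loci avoid that window so the region contains exactly
    ``cluster_size`` loci.
    """
    rng = np.random.default_rng(spec.seed)
    region = spec.region
    loci: list[MirnaLocus] = []

    cluster_starts = np.sort(
        rng.integers(region.start, region.end - spec.locus_length_bp + 1, spec.cluster_size)
    )
    for mirna_id, start in zip(spec.region_mirna_ids, cluster_starts):
        loci.append(_make_locus(mirna_id, "chr1", int(start), spec, rng))

    chroms = [f"chr{c}" for c in range(1, spec.n_chromosomes + 1)]
    per_chrom = np.bincount(
        rng.integers(0, spec.n_chromosomes, spec.n_background_mirnas),
        minlength=spec.n_chromosomes,
    )
    idx = 1
    for chrom, n in zip(chroms, per_chrom):
        placed = 0
        while placed < n:
            start = int(rng.integers(1, spec.chrom_length_bp - spec.locus_length_bp + 1))
            if chrom == region.chrom and region.start <= start + spec.locus_length_bp - 1 and start <= region.end:
                continue  # keep background out of the planted window
            loci.append(_make_locus(f"miR-B{idx}", chrom, start, spec, rng))
            idx += 1
            placed += 1
    return loci


def _make_locus(mirna_id: str, chrom: str, start: int, spec: SynthSpec, rng) -> MirnaLocus:
    # roughly half the loci yield both mature arms, mirroring annotation practice
    r = rng.random()
    arms = frozenset({"5p", "3p"}) if r < 0.5 else (frozenset({"5p"}) if r < 0.75 else frozenset({"3p"}))
    end = start + spec.locus_length_bp - 1
    strand = "+" if rng.random() < 0.5 else "-"
    return MirnaLocus(mirna_id, GenomicInterval(chrom, start, end, strand), arms)


# ---------------------------------------------------------------------------
# Gene-sets
# ---------------------------------------------------------------------------

def gen_genesets(spec: SynthSpec) -> list[GeneSet]:
    """Random gene-sets with sizes uniform in ``geneset_size_range``."""
    rng = np.random.default_rng(spec.seed + 1)
    universe = np.array(spec.gene_universe)
    lo, hi = spec.geneset_size_range
    sets = []
    for i in range(1, spec.n_genesets + 1):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        sets.append(GeneSet(f"GS{i:03d}", f"synthetic set {i}", frozenset(genes.tolist()), "synthetic"))
    return sets


# ---------------------------------------------------------------------------
# Prediction score tables
# ---------------------------------------------------------------------------

def gen_prediction_scores(
    spec: SynthSpec, loci: list[MirnaLocus], genesets: list[GeneSet]
) -> tuple[list[ScoreRecord], list[ScoreRecord]]:
    """Two tools' score tables with planted structure.

    Per miRNA locus, ``targets_per_mirna`` target genes are drawn for each
    tool; a fraction ``intertool_overlap`` of them is shared between the
    tools, and planted-enrichment genes are placed in the shared portion so
    they survive the downstream intersection.  Shared targets carry a common
    latent strength, giving positively correlated ranks across tools; each
    available arm of a locus reports the same genes with small arm-specific
    score noise.  Tool 1 is smaller-is-stronger, tool 2 larger-is-stronger.
    """
    rng = np.random.default_rng(spec.seed + 2)
    by_set = {gs.set_id: gs for gs in genesets}
    planted_by_mirna: dict[str, list[tuple[str, float]]] = {}
    for mirna_id, set_id, frac in spec.planted_enrichment:
        if set_id not in by_set:
            raise ConfigurationError(f"planted set {set_id!r} not in the collection")
        planted_by_mirna.setdefault(mirna_id, []).append((set_id, frac))

    universe = np.array(spec.gene_universe)
    n = spec.targets_per_mirna
    rec1: list[ScoreRecord] = []
    rec2: list[ScoreRecord] = []

    # the last region miRNAs emulate loci with no predictions from either tool
    skipped = set(
        spec.region_mirna_ids[len(spec.region_mirna_ids) - spec.n_region_without_predictions:]
    ) if spec.n_region_without_predictions else set()

    for locus in loci:
        if locus.mirna_id in skipped:
            continue
        planted_genes: list[str] = []
        taken: set[str] = set()
        for set_id, frac in planted_by_mirna.get(locus.mirna_id, []):
            n_planted = round(frac * n)
            pool = sorted(by_set[set_id].genes - taken)
            if n_planted > len(pool):
                raise ConfigurationError(
                    f"cannot draw {n_planted} planted targets from set {set_id} "
                    f"(size {len(pool)})"
                )
            chosen = rng.choice(np.array(pool), size=n_planted, replace=False).tolist()
            planted_genes.extend(chosen)
            taken.update(chosen)

        n_shared = max(round(spec.intertool_overlap * n), len(planted_genes))
        remaining = universe[~np.isin(universe, list(taken))]
        if (n_shared - len(planted_genes)) + 2 * (n - n_shared) > len(remaining):
            raise ConfigurationError(
                "gene universe too small for the requested targets_per_mirna "
                "and intertool_overlap"
            )
        order = rng.permutation(len(remaining))
        fill = remaining[order]
        shared = planted_genes + fill[: n_shared - len(planted_genes)].tolist()
        n_solo = n - n_shared
        solo1 = fill[n_shared - len(planted_genes): n_shared - len(planted_genes) + n_solo].tolist()
        solo2 = fill[
            n_shared - len(planted_genes) + n_solo: n_shared - len(planted_genes) + 2 * n_solo
        ].tolist()

        genes1 = shared + solo1
        genes2 = shared + solo2
        # latent strength in (0,1): shared genes reuse the same draw in both tools
        u_shared = rng.random(len(shared))
        u1 = np.concatenate([u_shared, rng.random(len(solo1))])
        u2 = np.concatenate([u_shared, rng.random(len(solo2))])

        for arm in sorted(locus.arms):
            mature = f"{locus.mirna_id}-{arm}"
            noise1 = rng.normal(0.0, 0.05, len(genes1))
            noise2 = rng.normal(0.0, 0.05, len(genes2))
            raw1 = (1.0 - u1) + noise1  # small = strong
            raw2 = u2 + noise2          # large = strong
            rec1.extend(
                ScoreRecord(TOOL1, mature, g, float(s)) for g, s in zip(genes1, raw1)
            )
            rec2.extend(
                ScoreRecord(TOOL2, mature, g, float(s)) for g, s in zip(genes2, raw2)
            )
    return rec1, rec2


# ---------------------------------------------------------------------------
# Interaction network, candidates, relevance flags
# ---------------------------------------------------------------------------

def gen_ppi_and_annotations(
    spec: SynthSpec,
) -> tuple[list[InteractionEdge], dict[str, list[str]], pd.DataFrame, list[str]]:
    """Interaction network plus candidate lists and relevance flags.

    Background edges follow an expected-degree (Chung-Lu style) model with
    exponential node propensities, giving an approximately geometric degree
    distribution with the requested mean.  Designated core-partner genes
    receive extra edges to candidates with probability boosted by
    ``core_density_boost``, and their three relevance flags are forced true;
    all other genes draw independent flags at the stated marginals.  Edge
    weights are drawn so that ``frac_below_weight_min`` of them fall below
    the 0.02 retention threshold.

    Returns (edges, {"gwas": [...], "cnv": [...]}, relevance table indexed
    by gene, core partner list).
    """
    rng = np.random.default_rng(spec.seed + 3)
    genes = spec.gene_universe
    n = len(genes)

    n_union = spec.n_candidates_gwas + spec.n_candidates_cnv - spec.shared_candidates
    special = rng.choice(n, size=n_union + spec.n_core_partners, replace=False)
    cand_idx, core_idx = special[:n_union], special[n_union:]
    shared = cand_idx[: spec.shared_candidates]
    gwas_only = cand_idx[spec.shared_candidates: spec.n_candidates_gwas]
    cnv_only = cand_idx[spec.n_candidates_gwas:]
    candidates = {
        "gwas": sorted(genes[i] for i in np.concatenate([shared, gwas_only])),
        "cnv": sorted(genes[i] for i in np.concatenate([shared, cnv_only])),
    }
    core_partners = sorted(genes[i] for i in core_idx)

    # background edges: endpoints drawn proportionally to exponential propensities
    propensity = rng.exponential(1.0, n)
    prob = propensity / propensity.sum()
    n_edges_target = int(round(n * spec.ppi_mean_degree / 2))
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_edges_target:
        need = int((n_edges_target - len(pairs)) * 1.3) + 8
        a = rng.choice(n, size=need, p=prob)
        b = rng.choice(n, size=need, p=prob)
        for i, j in zip(a, b):
            if i == j:
                continue
            pairs.add((min(i, j), max(i, j)))
            if len(pairs) >= n_edges_target:
                break

    # boosted core-partner <-> candidate adjacency
    p0 = spec.ppi_mean_degree / (n - 1)
    p_core = min(1.0, p0 * spec.core_density_boost)
    cand_all = np.concatenate([shared, gwas_only, cnv_only])
    for ci in core_idx:
        hits = rng.random(len(cand_all)) < p_core
        for cj in cand_all[hits]:
            pairs.add((min(int(ci), int(cj)), max(int(ci), int(cj))))

    # weights: a configurable fraction below the 0.02 retention threshold
    edges = []
    for i, j in sorted(pairs):
        if rng.random() < spec.frac_below_weight_min:
            w = rng.uniform(0.001, 0.02)
        else:
            w = rng.uniform(0.02, 0.1)
        edges.append(InteractionEdge(genes[i], genes[j], round(float(w), 6)))

    flags = rng.random((n, 3)) < np.array(spec.relevance_marginals)
    relevance = pd.DataFrame(
        flags, index=pd.Index(genes, name="gene"),
        columns=["expression", "function", "phenotype"],
    )
    relevance.loc[core_partners, :] = True
    # candidates were curated for brain relevance upstream, so they pass the
    # >=1-of-3 filter at the study's observed rate rather than the genome rate
    cand_genes = sorted(set(candidates["gwas"]) | set(candidates["cnv"]))
    passes = rng.random(len(cand_genes)) < spec.candidate_pass_frac
    for g, ok in zip(cand_genes, passes):
        if ok:
            if not relevance.loc[g].any():
                relevance.loc[g, "expression"] = True
        else:
            relevance.loc[g, :] = False
    return edges, candidates, relevance, core_partners


def gen_dysregulated(spec: SynthSpec, loci: list[MirnaLocus]) -> list[str]:
    """Sample background miRNAs as the dysregulated (DGCR8-mechanism) list."""
    rng = np.random.default_rng(spec.seed + 4)
    background = [l.mirna_id for l in loci if not l.mirna_id.startswith("miR-R")]
    k = min(spec.n_dysregulated, len(background))
    return sorted(rng.choice(np.array(background), size=k, replace=False).tolist())


# ---------------------------------------------------------------------------
# Mechanism-overlap helper (for overlap power studies)
# ---------------------------------------------------------------------------

def gen_overlap_sets(
    n_universe: int,
    n_network: int,
    n_mechanism: int,
    network_preference: float,
    seed: int,
) -> tuple[set[str], set[str], set[str]]:
    """Universe, network genes, and a mechanism set with tunable overlap.

    Mechanism genes are sampled with network members up-weighted by
    ``network_preference`` (1.0 = no preference, i.e. the null).
    """
    rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(1, n_universe + 1)]
    net_idx = rng.choice(n_universe, size=n_network, replace=False)
    in_net = np.zeros(n_universe, dtype=bool)
    in_net[net_idx] = True
    w = np.where(in_net, network_preference, 1.0)
    mech_idx = rng.choice(n_universe, size=n_mechanism, replace=False, p=w / w.sum())
    network = {universe[i] for i in net_idx}
    mechanism = {universe[i] for i in mech_idx}
    return set(universe), network, mechanism


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(spec: SynthSpec, outdir: str | Path) -> dict[str, str]:
    """Generate the full fixture bundle and write it under *outdir*.

    Files: mirnas.gff3, scores_tool1.tsv, scores_tool2.tsv, genesets.gmt,
    edges.tsv, candidates_gwas.txt, candidates_cnv.txt, relevance.tsv,
    dysregulated_mirnas.txt, manifest.json.  Deterministic under the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci = gen_mirna_annotation(spec)
    genesets = gen_genesets(spec)
    rec1, rec2 = gen_prediction_scores(spec, loci, genesets)
    edges, candidates, relevance, core = gen_ppi_and_annotations(spec)
    dysregulated = gen_dysregulated(spec, loci)

    paths = {
        "gff": str(outdir / "mirnas.gff3"),
        "scores_tool1": str(outdir / "scores_tool1.tsv"),
        "scores_tool2": str(outdir / "scores_tool2.tsv"),
        "gmt": str(outdir / "genesets.gmt"),
        "edges": str(outdir / "edges.tsv"),
        "candidates_gwas": str(outdir / "candidates_gwas.txt"),
        "candidates_cnv": str(outdir / "candidates_cnv.txt"),
        "relevance": str(outdir / "relevance.tsv"),
        "dysregulated": str(outdir / "dysregulated_mirnas.txt"),
        "manifest": str(outdir / "manifest.json"),
    }
    cio.write_mirna_gff(loci, paths["gff"])
    cio.write_score_table(rec1, paths["scores_tool1"])
    cio.write_score_table(rec2, paths["scores_tool2"])
    cio.write_gmt(genesets, paths["gmt"])
    cio.write_edge_list(edges, paths["edges"])
    cio.write_id_list(candidates["gwas"], paths["candidates_gwas"])
    cio.write_id_list(candidates["cnv"], paths["candidates_cnv"])
    rel = relevance.astype(int).reset_index()
    rel.to_csv(paths["relevance"], sep="\t", index=False)
    cio.write_id_list(dysregulated, paths["dysregulated"])
    manifest = {
        "spec": spec.to_dict(),
        "region": f"{spec.region.chrom}:{spec.region.start}-{spec.region.end}",
        "core_partners": core,
        "files": {k: Path(v).name for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
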