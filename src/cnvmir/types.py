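"""Core domain types shared across the pipeline stages.

Coordinates follow the GFF3 convention: 1-based, both endpoints inclusive.
Gene and miRNA identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ValidationError(ValueError):
    """Input violates a documented invariant (duplicate id, bad coordinate...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval (1-based, inclusive on both ends)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"strand must be one of +, -, . ; got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment: both endpoints of *other* inside self."""
        return (
            self.chrom == other.chrom
            and other.start >= self.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class MirnaLocus:
    """A miRNA primary-transcript locus with its available mature arms."""

    mirna_id: str
    interval: GenomicInterval
    arms: frozenset[str] = frozenset({"5p", "3p"})

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise ValidationError("mirna_id must be non-empty")
        arms = frozenset(self.arms)
        if not arms or not arms <= {"5p", "3p"}:
            raise ValidationError(
                f"arms must be a non-empty subset of {{5p, 3p}}, got {set(self.arms)}"
            )
        object.__setattr__(self, "arms", arms)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of genes (pathway / ontology term analog)."""

    set_id: str
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene-set {self.set_id!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected weighted interaction between two distinct genes."""

    gene_a: str
    gene_b: str
    weight: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-loop on {self.gene_a!r}")
        if self.weight < 0:
            raise ValidationError(f"negative weight {self.weight}")
        # canonical order so unordered pairs compare equal
        if self.gene_b < self.gene_a:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


#: polarity labels for raw prediction scores
LARGER_IS_STRONGER = "larger_is_stronger"
SMALLER_IS_STRONGER = "smaller_is_stronger"
POLARITIES = (LARGER_IS_STRONGER, SMALLER_IS_STRONGER)


@dataclass(frozen=True)
class ScoreRecord:
    """One tool's raw target-prediction score for a (mature miRNA, gene) pair."""

    tool: str
    mature_id: str
    gene: str
    raw_score: float


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with the published defaults.

    region
        Query CNV region (defaults to the typical 2.6 Mb 22q11.2 deletion,
        chr22:18,876,416-21,465,674).
    window_flank_bp
        Half-width of the symmetric genome-wide density window (1.3 Mb on
        either side of each locus start).
    topk_levels
        Target-list sizes used for enrichment (top 200 / 400 / 800).
    geneset_min, geneset_max
        Inclusive gene-set size bounds (15-900) applied within the target
        universe.
    nominal_p, short_list_p, consensus_min_runs
        Consensus filter: nominal p <= 0.01 in >= 2 of the 3 runs; a miRNA
        with fewer targets than the smallest k has one run judged at 0.005.
    fdr_border
        Benjamini-Hochberg FDR border used to flag results (25%).
    similarity_threshold
        Jaccard/overlap combined-coefficient cutoff for enrichment-map edges.
    edge_weight_min
        Interaction weight retention threshold (>= 0.02).
    score_penalty, score_brain, score_candidate
        Guilt-by-association neighbor weights (-1 / +0.5 / +2.5).
    retain_score_min
        Partner retention threshold (score >= 1.5).
    candidate_criteria_min, partner_criteria_min
        Brain-relevance criteria required for candidates (>= 1 of 3) and for
        other genes (>= 2 of 3).
    """

    region: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr22", 18_876_416, 21_465_674)
    )
    window_flank_bp: int = 1_300_000
    topk_levels: tuple[int, ...] = (200, 400, 800)
    geneset_min: int = 15
    geneset_max: int = 900
    nominal_p: float = 0.01
    short_list_p: float = 0.005
    consensus_min_runs: int = 2
    fdr_border: float = 0.25
    similarity_threshold: float = 0.225
    edge_weight_min: float = 0.02
    score_penalty: float = -1.0
    score_brain: float = 0.5
    score_candidate: float = 2.5
    retain_score_min: float = 1.5
    candidate_criteria_min: int = 1
    partner_criteria_min: int = 2
    overlap_min_mirnas: int = 2
    top_n_genes: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.topk_levels = tuple(int(k) for k in self.topk_levels)
        if list(self.topk_levels) != sorted(set(self.topk_levels)):
            raise ValidationError("topk_levels must be strictly increasing")
        for name in (
            "window_flank_bp", "geneset_min", "geneset_max", "nominal_p",
            "short_list_p", "fdr_border", "similarity_threshold",
            "edge_weight_min", "retain_score_min",
        ):
            v = getattr(self, name)
            if v != v or v in (float("inf"), float("-inf")):
                raise ValidationError(f"{name} must be finite")


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (YAML-friendly).

    ``region`` may be given as ``"chr22:18876416-21465674"`` or as a mapping
    with chrom/start/end keys.
    """
    d = dict(d)
    region = d.get("region")
    if isinstance(region, str):
        d["region"] = parse_region(region)
    elif isinstance(region, dict):
        d["region"] = GenomicInterval(**region)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**d)


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based inclusive; commas tolerated)."""
    try:
        chrom, rest = text.split(":", 1)
        start_s, end_s = rest.replace(",", "").split("-", 1)
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"cannot parse region {text!r}: {exc}") from exc
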