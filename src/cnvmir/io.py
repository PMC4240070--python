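"""Readers and writers for every external format the pipeline touches.

Formats: GFF3 (miRNA_primary_transcript features), GMT gene-set collections,
TSV edge lists, TSV score tables, plain-text id lists, two-column id maps,
and the YAML pipeline configuration.  All tabular outputs are TSV with a
header row.  Parse errors name the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import quote, unquote

import pandas as pd
import yaml

from .types import (
    GeneSet,
    GenomicInterval,
    InteractionEdge,
    MirnaLocus,
    ParseError,
    PipelineConfig,
    POLARITIES,
    ScoreRecord,
    ValidationError,
    config_from_dict,
)

logger = logging.getLogger("cnvmir")


# ---------------------------------------------------------------------------
# GFF3 miRNA annotation
# ---------------------------------------------------------------------------

GFF_FEATURE = "miRNA_primary_transcript"


def read_mirna_gff(path: str | Path) -> list[MirnaLocus]:
    """Read miRNA primary-transcript loci from a GFF3 file.

    Only ``miRNA_primary_transcript`` features are consumed.  The attribute
    column must carry ``ID``; an optional ``arms`` tag (comma-separated
    subset of ``5p,3p``) restricts the available mature arms, defaulting to
    both.  Coordinates are kept exactly as written (1-based inclusive) and
    record order is preserved.
    """
    loci: list[MirnaLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != GFF_FEATURE:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = _parse_gff_attributes(attrs, path, lineno)
            mirna_id = attr.get("ID") or attr.get("Name")
            if not mirna_id:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            if mirna_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate miRNA ID {mirna_id!r}")
            seen.add(mirna_id)
            arms = frozenset(attr["arms"].split(",")) if "arms" in attr else frozenset({"5p", "3p"})
            try:
                interval = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
                loci.append(MirnaLocus(mirna_id, interval, arms))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return loci


def _parse_gff_attributes(field: str, path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"{path}:{lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = unquote(value)
    return out


def write_mirna_gff(loci: Iterable[MirnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            iv = locus.interval
            arms = ",".join(sorted(locus.arms))
            attrs = f"ID={quote(locus.mirna_id)};arms={arms}"
            fh.write(
                f"{iv.chrom}\t.\t{GFF_FEATURE}\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str = "") -> list[GeneSet]:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are deduplicated; an empty set or a
    duplicate set_id is rejected.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(parts)}"
                )
            set_id, name, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene-set {set_id!r} has no genes")
            if set_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate set_id {set_id!r}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, name, frozenset(genes), source))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name or gs.set_id, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path, weight_min: float = 0.0
) -> tuple[list[InteractionEdge], set[str]]:
    """Read a TSV edge list (gene_a, gene_b, weight) with cleanup filters.

    Edges below *weight_min* are dropped (the retention threshold is an
    inclusive ``>=``), self-loops are dropped with a warning, and duplicate
    unordered pairs are collapsed keeping the maximum weight.  Returns the
    surviving edges and their node set.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "weight"])
    try:
        weights = df["weight"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric weight: {exc}") from exc

    best: dict[tuple[str, str], float] = {}
    n_loops = 0
    for a, b, w in zip(df["gene_a"], df["gene_b"], weights):
        if a == b:
            n_loops += 1
            continue
        if w < weight_min:
            continue
        pair = (a, b) if a <= b else (b, a)
        if w > best.get(pair, float("-inf")):
            best[pair] = w
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    edges = [InteractionEdge(a, b, w) for (a, b), w in sorted(best.items())]
    nodes = {g for e in edges for g in e.pair}
    return edges, nodes


def write_edge_list(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.weight:g}\n")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path, tool: str, polarity: str) -> list[ScoreRecord]:
    """Read one tool's prediction table (mature_id, gene, raw_score).

    *polarity* states whether larger or smaller raw scores are stronger;
    it is not stored per record but must accompany the table downstream.
    """
    if polarity not in POLARITIES:
        raise ValidationError(f"polarity must be one of {POLARITIES}, got {polarity!r}")
    df = _read_tsv(path, ["mature_id", "gene", "raw_score"])
    try:
        scores = df["raw_score"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric raw_score: {exc}") from exc
    if df["raw_score"].isna().any():
        raise ParseError(f"{path}: missing raw_score value")
    dup = df.duplicated(subset=["mature_id", "gene"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate record for ({first['mature_id']}, {first['gene']})"
        )
    return [
        ScoreRecord(tool, m, g, s)
        for m, g, s in zip(df["mature_id"], df["gene"], scores)
    ]


def write_score_table(records: Iterable[ScoreRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mature_id\tgene\traw_score\n")
        for r in records:
            fh.write(f"{r.mature_id}\t{r.gene}\t{r.raw_score!r}\n")


# ---------------------------------------------------------------------------
# Plain lists, id maps, config
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and #-comments skipped."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping (e.g. symbol -> stable id); later rows win."""
    df = _read_tsv(path, ["from_id", "to_id"])
    return dict(zip(df["from_id"], df["to_id"]))


def apply_id_map(genes: Iterable[str], mapping: dict[str, str]) -> tuple[list[str], int]:
    """Map identifiers, dropping (and counting) unmapped ones."""
    mapped, dropped = [], 0
    for g in genes:
        if g in mapping:
            mapped.append(mapping[g])
        else:
            dropped += 1
    if dropped:
        logger.info("id map: %d of %d identifiers unmapped and dropped", dropped, dropped + len(mapped))
    return mapped, dropped


def read_relevance_table(path: str | Path) -> pd.DataFrame:
    """Per-gene brain-relevance flags: gene, expression, function, phenotype."""
    df = _read_tsv(path, ["gene", "expression", "function", "phenotype"])
    for col in ("expression", "function", "phenotype"):
        df[col] = df[col].astype(int).astype(bool)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene {dup!r} in relevance table")
    return df.set_index("gene")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(columns))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if df[list(columns)].isna().any().any():
        bad = int(df[list(columns)].isna().any(axis=1).idxmax()) + 2  # +header +1-base
        raise ParseError(f"{path}:{bad}: missing field")
    return df


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
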