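"""Two-tool target-score integration by percentile transformation.

Each prediction tool emits raw scores on its own scale and polarity.  Scores
are mapped to percentiles over the tool's entire table (all miRNAs, all
genes): a percentile of 0.10 means the score sits in the tool's top 10%.
Percentiles for the -5p and -3p arms of the same locus are averaged, the two
tools' percentiles are averaged for genes predicted by both, and each
miRNA's targets are ranked by that final score (smaller = stronger).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .types import (
    LARGER_IS_STRONGER,
    POLARITIES,
    ScoreRecord,
    ValidationError,
)

logger = logging.getLogger("cnvmir")


@dataclass(frozen=True)
class PercentileTarget:
    mirna_id: str
    gene: str
    percentile_tool1: float
    percentile_tool2: float
    final_score: float
    rank: int


@dataclass(frozen=True)
class TopKLists:
    mirna_id: str
    k_levels: tuple[int, ...]
    lists: dict[int, tuple[str, ...]]

    @property
    def n_targets(self) -> int:
        return max((len(v) for v in self.lists.values()), default=0)


def percentile_transform(
    records: list[ScoreRecord], polarity: str
) -> dict[tuple[str, str], float]:
    """Map each record's raw score to its within-tool percentile.

    percentile(s) = (# records at least as strong as s) / (total records),
    pooling all miRNAs and arms of the tool.  Ties share the same (maximal)
    percentile, so the top-10% boundary score maps to exactly 0.10.
    """
    if polarity not in POLARITIES:
        raise ValidationError(f"polarity must be one of {POLARITIES}")
    if not records:
        raise ValidationError("cannot percentile-transform an empty table")
    sign = 1.0 if polarity == LARGER_IS_STRONGER else -1.0
    strengths = sorted(sign * r.raw_score for r in records)
    n = len(strengths)
    import bisect

    out: dict[tuple[str, str], float] = {}
    for r in records:
        s = sign * r.raw_score
        # records with strength >= s
        at_least = n - bisect.bisect_left(strengths, s)
        out[(r.mature_id, r.gene)] = at_least / n
    return out


def split_mature_id(mature_id: str) -> tuple[str, str | None]:
    """Split ``miR-185-5p`` into (``miR-185``, ``5p``); no suffix -> (id, None)."""
    for arm in ("5p", "3p"):
        suffix = f"-{arm}"
        if mature_id.endswith(suffix):
            return mature_id[: -len(suffix)], arm
    return mature_id, None


def collapse_arms(
    percentiles: dict[tuple[str, str], float],
    known_loci: set[str] | None = None,
) -> dict[tuple[str, str], float]:
    """Average -5p/-3p percentiles per (locus, gene).

    A gene predicted for one arm keeps that arm's percentile; a gene
    predicted for both arms gets the arithmetic mean.  If *known_loci* is
    given, every mature id must resolve to one of them.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for (mature_id, gene), p in percentiles.items():
        locus, _arm = split_mature_id(mature_id)
        if known_loci is not None and locus not in known_loci:
            raise ValidationError(
                f"mature id {mature_id!r} does not resolve to a known locus"
            )
        acc.setdefault((locus, gene), []).append(p)
    return {key: sum(v) / len(v) for key, v in acc.items()}


def integrate_tools(
    tool1: dict[tuple[str, str], float],
    tool2: dict[tuple[str, str], float],
    mirna_ids: list[str] | None = None,
) -> dict[str, list[PercentileTarget]]:
    """Intersect the two tools' predictions and rank by averaged percentile.

    Only (miRNA, gene) pairs predicted by BOTH tools receive a final score
    (conservative intersection).  Ranking is ascending in final score
    (smaller percentile = stronger prediction), ties broken by gene id.
    A miRNA absent from either tool yields an empty list.
    """
    by_mirna1: dict[str, dict[str, float]] = {}
    for (m, g), p in tool1.items():
        by_mirna1.setdefault(m, {})[g] = p
    by_mirna2: dict[str, dict[str, float]] = {}
    for (m, g), p in tool2.items():
        by_mirna2.setdefault(m, {})[g] = p

    if mirna_ids is None:
        mirna_ids = sorted(set(by_mirna1) | set(by_mirna2))

    out: dict[str, list[PercentileTarget]] = {}
    for m in mirna_ids:
        p1, p2 = by_mirna1.get(m), by_mirna2.get(m)
        if not p1 or not p2:
            logger.info("miRNA %s lacks predictions from both tools; excluded", m)
            out[m] = []
            continue
        shared = sorted(set(p1) & set(p2))
        scored = sorted(
            ((0.5 * (p1[g] + p2[g]), g) for g in shared),
            key=lambda t: (t[0], t[1]),
        )
        out[m] = [
            PercentileTarget(m, g, p1[g], p2[g], s, rank)
            for rank, (s, g) in enumerate(scored, start=1)
        ]
    return out


def topk(
    targets: list[PercentileTarget], k_levels: tuple[int, ...]
) -> TopKLists:
    """Prefix slices of the ranked target list at each k level.

    Lists are nested by construction; a miRNA with fewer targets than k
    contributes all of them (miR-1306-style short list).
    """
    ordered = sorted(targets, key=lambda t: t.rank)
    genes = tuple(t.gene for t in ordered)
    mirna = ordered[0].mirna_id if ordered else ""
    lists = {k: genes[:k] for k in k_levels}
    return TopKLists(mirna, tuple(k_levels), lists)


def mean_top_score(targets: list[PercentileTarget], k: int) -> float | None:
    """Mean final score of the top-k targets (Table-style summary)."""
    top = sorted(targets, key=lambda t: t.rank)[:k]
    if not top:
        return None
    return sum(t.final_score for t in top) / len(top)
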