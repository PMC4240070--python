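"""miRNA density of a query region versus locus-centered windows genome-wide.

The statistic asks: centering a window of the query region's size on every
miRNA locus in the genome, what share of those windows contain fewer loci
than the query region does?  A high share means the region is unusually
miRNA-dense.  "Contained" means full interval containment (both endpoints
inside the window); a ``start_only`` toggle counts transcript starts instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import GenomicInterval, MirnaLocus


@dataclass(frozen=True)
class DensityResult:
    region_count: int
    window_counts: dict[str, int]
    percentile_exceeded: float


def count_in_region(
    loci: list[MirnaLocus], region: GenomicInterval, start_only: bool = False
) -> int:
    """Count loci fully contained in *region* (or with start inside it)."""
    if start_only:
        return sum(
            1
            for l in loci
            if l.interval.chrom == region.chrom
            and region.start <= l.interval.start <= region.end
        )
    return sum(1 for l in loci if region.contains(l.interval))


def window_counts(
    loci: list[MirnaLocus], flank_bp: int, start_only: bool = False
) -> dict[str, int]:
    """For each locus, count loci inside the symmetric window around its start.

    The window spans ``flank_bp`` on either side of the locus transcript
    start, clipped at position 1; it never spans chromosomes.  Each locus is
    contained in its own window, so every count is >= 1.
    """
    if flank_bp <= 0:
        raise ValueError(f"flank_bp must be positive, got {flank_bp}")
    # sweep per chromosome over start-sorted loci
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.interval.chrom, []).append(l)
    counts: dict[str, int] = {}
    for chrom_loci in by_chrom.values():
        ordered = sorted(chrom_loci, key=lambda l: (l.interval.start, l.interval.end))
        starts = [l.interval.start for l in ordered]
        ends = [l.interval.end for l in ordered]
        for centre in chrom_loci:
            lo = max(1, centre.interval.start - flank_bp)
            hi = centre.interval.start + flank_bp
            if start_only:
                n = sum(1 for s in starts if lo <= s <= hi)
            else:
                n = sum(1 for s, e in zip(starts, ends) if s >= lo and e <= hi)
            counts[centre.mirna_id] = n
    return counts


def density_percentile(
    region_count: int,
    window_counts: dict[str, int],
    exclude_ids: set[str] = frozenset(),
) -> float:
    """Share of comparison windows with a count strictly below *region_count*.

    Windows centered on loci in *exclude_ids* (typically the query region's
    own loci) are left out of the comparison.
    """
    comparison = [c for m, c in window_counts.items() if m not in exclude_ids]
    if not comparison:
        raise ValueError("no comparison windows left after exclusion")
    return sum(1 for c in comparison if c < region_count) / len(comparison)


def region_density(
    loci: list[MirnaLocus],
    region: GenomicInterval,
    flank_bp: int,
    exclude_region_loci: bool = True,
    start_only: bool = False,
) -> DensityResult:
    """Full density analysis: region count, window counts, percentile."""
    rc = count_in_region(loci, region, start_only=start_only)
    wc = window_counts(loci, flank_bp, start_only=start_only)
    exclude = (
        {l.mirna_id for l in loci if region.contains(l.interval)}
        if exclude_region_loci
        else set()
    )
    pct = density_percentile(rc, wc, exclude)
    return DensityResult(rc, wc, pct)
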