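"""Overlap of miRNA-mechanism target sets with the disease network.

Two mechanism sets are built: the union of the region miRNAs' top-k targets,
and the set of genes in the top-200 lists of at least two dysregulated
miRNAs (microprocessor-haploinsufficiency mechanism) minus the region set.
Each is tested for over-representation among the network's genes with a
one-sided Fisher exact test over a configurable gene universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import fisher_exact

from .targets import TopKLists
from .types import ValidationError


@dataclass
class MechanismSet:
    label: str
    genes: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class OverlapTest:
    mechanism: str
    n_in_network: int
    n_mechanism: int
    n_network: int
    n_universe: int
    p: float
    odds_ratio: float
    n_dropped_out_of_universe: int = 0

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        a = self.n_in_network
        b = self.n_mechanism - a
        c = self.n_network - a
        d = self.n_universe - self.n_mechanism - c
        return ((a, b), (c, d))


def region_target_union(
    topk_lists: dict[str, TopKLists], k: int = 200, label: str = "region_mirna"
) -> MechanismSet:
    """Union of the region miRNAs' top-k targets with per-gene provenance."""
    provenance: dict[str, list[str]] = {}
    for mirna_id in sorted(topk_lists):
        for gene in topk_lists[mirna_id].lists.get(k, ()):
            provenance.setdefault(gene, []).append(mirna_id)
    return MechanismSet(label, set(provenance), provenance)


def dgcr8_set(
    topk_all: dict[str, TopKLists],
    dysregulated: list[str],
    min_mirnas: int = 2,
    exclude: MechanismSet | None = None,
    k: int = 200,
    label: str = "dgcr8",
) -> MechanismSet:
    """Genes in the top-k lists of >= *min_mirnas* dysregulated miRNAs.

    Genes in *exclude* (the region-miRNA target union) are removed so the
    two mechanism sets are disjoint.
    """
    unknown = [m for m in dysregulated if m not in topk_all]
    if unknown:
        raise ValidationError(f"unknown dysregulated miRNA id(s): {unknown}")
    provenance: dict[str, list[str]] = {}
    for mirna_id in sorted(set(dysregulated)):
        for gene in topk_all[mirna_id].lists.get(k, ()):
            provenance.setdefault(gene, []).append(mirna_id)
    excluded = exclude.genes if exclude is not None else set()
    provenance = {
        g: ms
        for g, ms in provenance.items()
        if len(ms) >= min_mirnas and g not in excluded
    }
    return MechanismSet(label, set(provenance), provenance)


def overlap_test(
    mechanism: MechanismSet, network_genes: set[str], universe: set[str]
) -> OverlapTest:
    """One-sided Fisher test of mechanism/network overlap within *universe*.

    Mechanism genes outside the universe are dropped (and counted) before
    testing; the network must be a subset of the universe.  The odds ratio
    is the sample (cross-product) estimate, infinite when b*c = 0.
    """
    if not network_genes <= universe:
        missing = sorted(network_genes - universe)[:5]
        raise ValidationError(f"network genes outside the universe: {missing}...")
    mech = mechanism.genes & universe
    dropped = len(mechanism.genes) - len(mech)
    a = len(mech & network_genes)
    b = len(mech - network_genes)
    c = len(network_genes - mech)
    d = len(universe) - a - b - c
    if d < 0:
        raise ValidationError("universe smaller than the union of the tested sets")
    _stat, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return OverlapTest(
        mechanism=mechanism.label,
        n_in_network=a,
        n_mechanism=len(mech),
        n_network=len(network_genes),
        n_universe=len(universe),
        p=float(p),
        odds_ratio=odds,
        n_dropped_out_of_universe=dropped,
    )


def annotate_top_genes(
    ranking: list[tuple[str, float]],
    mechanisms: list[MechanismSet],
    top_n: int = 50,
) -> tuple[list[dict], dict[str, float]]:
    """Flag each top-ranked gene's mechanism membership.

    Returns per-gene rows (gene, score, one flag per mechanism, any_mechanism)
    and a summary with the count and fraction of top-n genes hit by at least
    one mechanism.
    """
    rows = []
    n_hit = 0
    top = ranking[:top_n]
    for gene, score in top:
        flags = {m.label: gene in m.genes for m in mechanisms}
        any_hit = any(flags.values())
        n_hit += any_hit
        rows.append({"gene": gene, "score": score, **flags, "any_mechanism": any_hit})
    summary = {
        "top_n": float(len(top)),
        "n_hit": float(n_hit),
        "fraction_hit": n_hit / len(top) if top else 0.0,
    }
    return rows, summary
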