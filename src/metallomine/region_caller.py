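"""Assemble candidate BGC regions around anchor genes.

Anchor genes are the NRPS entry points of the detection rule: a gene
carrying both a condensation and an adenylation (AMP-binding) domain, or a
gene carrying one of the standalone markers (VibH_like, Cy_tandem) that
admit Type II, non-/semi-modular NRPS systems. Anchors within
``merge_distance`` of each other (transitively) share one region; the region
span is the anchor envelope extended by ``neighborhood`` on each side,
clamped to the contig. A region whose extension was truncated by a contig
boundary is flagged partial ("on a contig edge"); all downstream census
statistics stratify on this flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .io_formats import ContigRecord, GeneRecord

__all__ = ["Region", "RegionParams", "find_anchor_genes", "build_regions",
           "flag_completeness"]

#: profiles that make a single gene an NRPS anchor when co-occurring
CORE_DOMAIN_PAIR = ("Condensation", "AMP-binding")
#: profiles that anchor a region on their own (Type II NRPS entry points)
STANDALONE_ANCHORS = ("VibH_like", "Cy_tandem")


@dataclass(frozen=True)
class RegionParams:
    """Distance parameters for region assembly (nucleotides)."""

    merge_distance: int = 20_000
    neighborhood: int = 20_000

    def __post_init__(self) -> None:
        if self.merge_distance < 0 or self.neighborhood < 0:
            raise ValueError("distances must be >= 0")


@dataclass(frozen=True)
class Region:
    """A contiguous candidate BGC region.

    ``start``/``end`` are clamped to the contig; ``raw_start``/``raw_end``
    keep the pre-clamp extension so contig-edge truncation stays decidable.
    """

    region_id: str
    contig_id: str
    start: int
    end: int
    anchor_gene_ids: frozenset[str]
    member_gene_ids: frozenset[str]
    complete: bool = True
    raw_start: int = 0
    raw_end: int = 0

    def __post_init__(self) -> None:
        if not self.anchor_gene_ids:
            raise ValueError(f"region {self.region_id}: no anchor genes")
        if not self.anchor_gene_ids <= self.member_gene_ids:
            raise ValueError(f"region {self.region_id}: anchors not in members")
        if not self.start < self.end:
            raise ValueError(f"region {self.region_id}: empty span")


def find_anchor_genes(
    genes: list[GeneRecord],
    sig_hits: Mapping[str, set[str]],
    rule=None,
) -> set[str]:
    """Return gene ids that can seed a region.

    A gene is an anchor iff it carries both core NRPS domains (Condensation
    and AMP-binding), or carries a standalone marker (VibH_like/Cy_tandem).
    ``rule`` is accepted for signature compatibility but the anchor
    definition is fixed by the rule's entry points.
    """
    anchors: set[str] = set()
    for g in genes:
        profs = sig_hits.get(g.gene_id, set())
        if all(p in profs for p in CORE_DOMAIN_PAIR):
            anchors.add(g.gene_id)
        elif any(p in profs for p in STANDALONE_ANCHORS):
            anchors.add(g.gene_id)
    return anchors


def build_regions(
    contig: ContigRecord,
    anchors: set[str],
    params: RegionParams = RegionParams(),
) -> list[Region]:
    """Group anchors into disjoint regions and extend by the neighborhood.

    Anchors whose gene spans are within ``merge_distance`` of each other
    (transitively) share one region. The span is
    ``[min(anchor starts) - neighborhood, max(anchor ends) + neighborhood]``
    clamped to the contig; overlap between consecutive extended regions is
    split at its midpoint so regions on a contig stay pairwise disjoint.
    Members are all genes overlapping the final span.
    """
    gene_by_id = {g.gene_id: g for g in contig.genes}
    missing = anchors - set(gene_by_id)
    if missing:
        raise ValueError(f"anchors not on contig {contig.contig_id}: {sorted(missing)}")
    anchor_genes = sorted((gene_by_id[a] for a in anchors), key=lambda g: (g.start, g.end))
    if not anchor_genes:
        return []

    # transitive single-linkage merge along the sorted anchor list
    groups: list[list[GeneRecord]] = [[anchor_genes[0]]]
    for g in anchor_genes[1:]:
        prev_end = max(x.end for x in groups[-1])
        if g.start - prev_end <= params.merge_distance:
            groups[-1].append(g)
        else:
            groups.append([g])

    spans: list[tuple[int, int, list[GeneRecord]]] = []
    for grp in groups:
        raw_start = min(g.start for g in grp) - params.neighborhood
        raw_end = max(g.end for g in grp) + params.neighborhood
        spans.append((raw_start, raw_end, grp))

    regions: list[Region] = []
    for i, (raw_start, raw_end, grp) in enumerate(spans):
        start = max(raw_start, 0)
        end = min(raw_end, contig.length)
        # keep neighboring extended regions disjoint
        if i > 0:
            prev_end = min(spans[i - 1][1], contig.length)
            if start < prev_end:
                mid = (start + prev_end) // 2
                start = mid
                regions[-1] = replace(regions[-1], end=mid,
                                      member_gene_ids=_members(contig, regions[-1].start, mid)
                                      | regions[-1].anchor_gene_ids)
        members = _members(contig, start, end) | {g.gene_id for g in grp}
        regions.append(
            Region(
                region_id=f"{contig.contig_id}_r{i + 1}",
                contig_id=contig.contig_id,
                start=start,
                end=end,
                anchor_gene_ids=frozenset(g.gene_id for g in grp),
                member_gene_ids=frozenset(members),
                complete=(raw_start >= 0) and (raw_end <= contig.length),
                raw_start=raw_start,
                raw_end=raw_end,
            )
        )
    return regions


def _members(contig: ContigRecord, start: int, end: int) -> set[str]:
    return {g.gene_id for g in contig.genes if g.start < end and g.end > start}


def flag_completeness(region: Region, contig: ContigRecord) -> Region:
    """Set ``complete`` from pre-clamp extension vs the contig bounds.

    Complete iff the raw (pre-clamp) span fits inside ``[0, contig.length]``
    — the boundary itself is inclusive, so an anchor ending exactly one
    neighborhood before the contig end is still complete.
    """
    return replace(
        region,
        complete=(region.raw_start >= 0) and (region.raw_end <= contig.length),
    )
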