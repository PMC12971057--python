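"""End-to-end detection: hits -> cutoffs -> regions -> classification."""

from __future__ import annotations

from typing import Mapping

from .classifiers import ClassificationResult, classify_region, load_group_rules
from .io_formats import ContigRecord, DomainHit, ProfileRegistry
from .region_caller import Region, RegionParams, build_regions, find_anchor_genes
from .rule_engine import RuleExpr, apply_cutoffs, default_rule

__all__ = ["detect"]


def detect(
    contigs: list[ContigRecord],
    hits: list[DomainHit],
    registry: ProfileRegistry,
    rule: RuleExpr | None = None,
    params: RegionParams = RegionParams(),
    group_rules=None,
) -> tuple[list[Region], list[ClassificationResult]]:
    """Run the full detection pipeline on one genome.

    Applies bitscore cutoffs, finds anchor genes, assembles regions per
    contig, and classifies every region with the chelator rule, the
    transporter rule and the ensemble. Returns regions and matching
    classification results, ordered by (contig, start).
    """
    if rule is None:
        rule = default_rule()
    if group_rules is None:
        group_rules = load_group_rules()
    sig_hits = apply_cutoffs(hits, registry)
    regions: list[Region] = []
    results: list[ClassificationResult] = []
    for contig in contigs:
        anchors = find_anchor_genes(contig.genes, sig_hits, rule)
        for region in build_regions(contig, anchors, params):
            regions.append(region)
            results.append(
                classify_region(region, sig_hits, rule, registry, group_rules)
            )
    return regions, results
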