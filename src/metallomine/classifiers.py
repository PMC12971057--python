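"""Region-level metallophore classification.

Three verdicts per region:

* **chelator rule** — the boolean detection rule over chelator-biosynthesis
  profiles (the primary method), plus a chelating-group profile derived from
  the identifiers that actually fired;
* **transporter rule** — the older heuristic: at least two of the three
  siderophore-associated transporter Pfam families (TonB-dependent receptor
  PF00593, FecCD permease PF01032, periplasmic binding protein PF01497)
  present anywhere in the region;
* **either/or ensemble** — the union of the two.

The chelating-group mapping (group name -> mini rule over profile names)
ships as a JSON config in package data so new chelators can be added without
code changes. Vetoed identifiers (e.g. Orn_monoox in the presence of KtzT)
never contribute to the group profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

from .io_formats import ProfileRegistry
from .region_caller import Region
from .rule_engine import RuleExpr, evaluate, parse_rule

__all__ = [
    "TRANSPORTER_FAMILIES",
    "ChelatorProfile",
    "ClassificationResult",
    "load_group_rules",
    "classify_chelator_rule",
    "classify_transporter_rule",
    "classify_ensemble",
    "classify_region",
]

#: the three siderophore-associated transporter Pfam families
TRANSPORTER_FAMILIES = frozenset({"PF00593", "PF01032", "PF01497"})


@dataclass(frozen=True)
class ChelatorProfile:
    """Chelating groups detected in a region, with their witnessing profiles."""

    groups: frozenset[str] = frozenset()
    triggering: Mapping[str, frozenset[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class ClassificationResult:
    region_id: str
    chelator_rule: bool
    transporter_rule: bool
    ensemble: bool
    profile: ChelatorProfile
    complete: bool

    def __post_init__(self) -> None:
        if self.ensemble != (self.chelator_rule or self.transporter_rule):
            raise ValueError("ensemble must be chelator OR transporter")


def load_group_rules(path=None) -> dict[str, RuleExpr]:
    """Load the chelating-group mapping (group -> parsed rule expression)."""
    if path is None:
        text = (
            resources.files("metallomine.data")
            .joinpath("chelator_groups.json")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    return {group: parse_rule(rule_text) for group, rule_text in raw.items()}


def _restrict(sig_hits: Mapping[str, set[str]], region: Region) -> dict[str, set[str]]:
    return {
        g: set(p) for g, p in sig_hits.items() if g in region.member_gene_ids
    }


def classify_chelator_rule(
    region: Region,
    sig_hits: Mapping[str, set[str]],
    rule: RuleExpr,
    registry: ProfileRegistry,
    group_rules: Mapping[str, RuleExpr] | None = None,
) -> tuple[bool, ChelatorProfile]:
    """Apply the detection rule to a region and derive its chelator profile.

    ``sig_hits`` is the cutoff-filtered gene -> profiles map (whole genome
    or pre-restricted; it is restricted to region members here). The profile
    contains every chelating group whose own trigger rule holds on the
    region, each witnessed by the identifiers that fired; groups only appear
    when the full rule is satisfied.
    """
    if group_rules is None:
        group_rules = load_group_rules()
    region_hits = _restrict(sig_hits, region)
    verdict = evaluate(rule, region_hits)
    if not verdict.satisfied:
        return False, ChelatorProfile()
    groups: set[str] = set()
    triggering: dict[str, frozenset[str]] = {}
    for group, gexpr in group_rules.items():
        gv = evaluate(gexpr, region_hits)
        if gv.satisfied:
            groups.add(group)
            triggering[group] = gv.triggering_identifiers
    # The marker class means "detected by metallophore-specific NRPS domains
    # rather than chelator biosynthesis": it stands only when no chelator
    # group is witnessed in the region.
    if "NRPS-domain-marker" in groups and len(groups) > 1:
        groups.discard("NRPS-domain-marker")
        triggering.pop("NRPS-domain-marker", None)
    return True, ChelatorProfile(frozenset(groups), triggering)


def classify_transporter_rule(
    region: Region, sig_hits: Mapping[str, set[str]]
) -> bool:
    """True iff >= 2 distinct transporter families occur on region genes.

    Counting is by distinct family, not by gene: three genes all hitting
    PF01497 is still one family.
    """
    families: set[str] = set()
    for gene_id, profs in sig_hits.items():
        if gene_id in region.member_gene_ids:
            families |= profs & TRANSPORTER_FAMILIES
    return len(families) >= 2


def classify_ensemble(chelator: bool, transporter: bool) -> bool:
    """Either/or ensemble: positive if either method fires."""
    return chelator or transporter


def classify_region(
    region: Region,
    sig_hits: Mapping[str, set[str]],
    rule: RuleExpr,
    registry: ProfileRegistry,
    group_rules: Mapping[str, RuleExpr] | None = None,
) -> ClassificationResult:
    """Run all three methods on one region."""
    chel, profile = classify_chelator_rule(region, sig_hits, rule, registry, group_rules)
    trans = classify_transporter_rule(region, sig_hits)
    return ClassificationResult(
        region_id=region.region_id,
        chelator_rule=chel,
        transporter_rule=trans,
        ensemble=classify_ensemble(chel, trans),
        profile=profile,
        complete=region.complete,
    )
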