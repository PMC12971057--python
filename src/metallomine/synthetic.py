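"""Deterministic synthetic genomes with planted metallophore clusters.

The generator emits the three inputs every other module consumes — a
GenBank genome, a matching domain-hit table, and a truth table — from
cluster templates that instantiate the archetypes a detector must handle:

* clean producers (enterobactin-like catechol, pyoverdine-like three-group
  hybrid, hydroxamate, salicylate, graminine, Dmaq clusters);
* a standalone Type II trigger (VibH_like without a modular NRPS gene);
* a "cheater" locus that kept the transporter genes and an NRPS gene but no
  chelator biosynthesis — transporter-positive, chelator-negative by design;
* veto cases (ornithine monooxygenase next to KtzT; IBH_Asp next to
  SBH_Asp) that the negative constraints must reject;
* plain NRPS and sub-threshold decoys.

Hit bitscores are placed deterministically at ``cutoff x 1.5`` for planted
significant hits and ``cutoff x 0.5`` for planted sub-threshold hits; the
offsets are configurable per template slot to probe the inclusive cutoff
boundary. Every template's expected verdicts are validated against the
canonical rule at generation time, so the emitted truth table is consistent
with the rule semantics by construction. Output bytes are a pure function
of the spec and seed.

What this emulates — and what it does not: gene order, spacing, contig
truncation and hit-score/threshold relations are realistic in shape, but
sequences are filler text, scores carry no noise beyond the stated offsets,
and no homologous decoy families are simulated. Perfect recovery on these
fixtures demonstrates the engine's logic, not detector performance on real
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .classifiers import load_group_rules
from .io_formats import (
    ContigRecord,
    DomainHit,
    GeneRecord,
    ProfileRegistry,
    read_profile_registry,
)
from .pipeline import detect
from .region_caller import RegionParams
from .rule_engine import RuleExpr, default_rule

__all__ = [
    "GeneSlot",
    "ClusterTemplate",
    "ContigSpec",
    "GenomeSpec",
    "GeneratedDataset",
    "TEMPLATES",
    "default_registry",
    "generate",
    "benchmark_set",
    "write_dataset",
]

GENE_LEN = 900  # nt per synthetic CDS
INTERGENIC = 150  # nt between CDSs inside a cluster
EDGE_MARGIN = 25_000  # nt margin that keeps an interior cluster "complete"
ABOVE = 1.5  # planted-significant score = cutoff * ABOVE
BELOW = 0.5  # planted-sub-threshold score = cutoff * BELOW


@dataclass(frozen=True)
class GeneSlot:
    """One gene of a template: profiles planted on it with score factors."""

    slot: str
    profiles: tuple[tuple[str, float], ...]  # (profile, cutoff multiplier)


@dataclass(frozen=True)
class ClusterTemplate:
    name: str
    genes: tuple[GeneSlot, ...]
    expected_chelator: bool
    expected_transporter: bool
    expected_groups: frozenset[str]


def _slot(slot: str, *profiles: str, factor: float = ABOVE) -> GeneSlot:
    return GeneSlot(slot, tuple((p, factor) for p in profiles))


_NRPS = _slot("nrps", "Condensation", "AMP-binding")

TEMPLATES: dict[str, ClusterTemplate] = {
    t.name: t
    for t in [
        ClusterTemplate(
            "enterobactin",
            (
                _slot("entC", "EntC"),
                _slot("entA", "EntA"),
                _NRPS,
                _slot("fepA", "PF00593"),
                _slot("fepB", "PF01497"),
            ),
            True,
            True,
            frozenset({"catechol"}),
        ),
        ClusterTemplate(
            "pyoverdine",
            (
                _slot("pvdP", "PvdP"),
                _slot("pvdA", "Orn_monoox"),
                _slot("pvdH", "TBH_Asp"),
                _NRPS,
                _slot("fpvA", "PF00593"),
                _slot("fpvD", "PF01032"),
            ),
            True,
            True,
            frozenset({"pyoverdine-chromophore", "hydroxamate", "beta-OHAsp"}),
        ),
        ClusterTemplate(
            "hydroxamate",
            (
                _slot("mbtG", "Orn_monoox"),
                _NRPS,
                _slot("irtA", "PF01032"),
                _slot("irtB", "PF01497"),
            ),
            True,
            True,
            frozenset({"hydroxamate"}),
        ),
        ClusterTemplate(
            "salicylate",
            (_slot("pchB", "IPL"), _NRPS),
            True,
            False,
            frozenset({"salicylate"}),
        ),
        ClusterTemplate(
            "graminine",
            (
                _slot("grbD", "GrbD"),
                _slot("grbE", "GrbE"),
                _NRPS,
                _slot("gvgT", "PF00593"),
                _slot("gvgP", "PF01497"),
            ),
            True,
            True,
            frozenset({"graminine"}),
        ),
        ClusterTemplate(
            "dmaq",
            (_slot("fbnL", "FbnL"), _slot("fbnM", "FbnM"), _NRPS),
            True,
            False,
            frozenset({"Dmaq"}),
        ),
        ClusterTemplate(
            "type2_vibh",
            (_slot("vibH", "VibH_like"),),
            True,
            False,
            frozenset({"NRPS-domain-marker"}),
        ),
        # kept transporters + NRPS gene, lost chelator biosynthesis
        ClusterTemplate(
            "cheater",
            (_NRPS, _slot("tonB", "PF00593"), _slot("fecCD", "PF01032")),
            False,
            True,
            frozenset(),
        ),
        # hydroxamate branch vetoed by the piperazate marker
        ClusterTemplate(
            "himastatin_veto",
            (_slot("hmtOrn", "Orn_monoox"), _slot("ktzT", "KtzT"), _NRPS),
            False,
            False,
            frozenset(),
        ),
        # IBH_Asp suppressed by the competing syringomycin-family profile
        ClusterTemplate(
            "syringomycin_excluded",
            (_slot("syrP", "IBH_Asp"), _slot("syrB", "SBH_Asp"), _NRPS),
            False,
            False,
            frozenset(),
        ),
        ClusterTemplate(
            "nrps_decoy",
            (_NRPS,),
            False,
            False,
            frozenset(),
        ),
        # chelator genes present but every hit below its cutoff
        ClusterTemplate(
            "subthreshold_decoy",
            (
                GeneSlot("entA_lo", (("EntA", BELOW),)),
                GeneSlot("entC_lo", (("EntC", BELOW),)),
                _NRPS,
            ),
            False,
            False,
            frozenset(),
        ),
    ]
}

#: templates whose truth verdicts are all clean positives or negatives under
#: both methods (no planted disagreement)
CLEAN_TEMPLATES = (
    "enterobactin",
    "pyoverdine",
    "hydroxamate",
    "salicylate",
    "graminine",
    "dmaq",
    "type2_vibh",
    "nrps_decoy",
)


@dataclass(frozen=True)
class ContigSpec:
    """Clusters to place on one contig, in order."""

    templates: tuple[str, ...]
    truncate_at_edge: tuple[bool, ...] = ()
    n_decoy_genes: int = 3

    def __post_init__(self) -> None:
        if self.truncate_at_edge and len(self.truncate_at_edge) != len(self.templates):
            raise ValueError("truncate_at_edge length must match templates")


@dataclass(frozen=True)
class GenomeSpec:
    seed: int
    contigs: tuple[ContigSpec, ...]
    genome_id: str = "synthetic"


@dataclass
class GeneratedDataset:
    """In-memory product of :func:`generate`."""

    contigs: list[ContigRecord]
    hits: list[DomainHit]
    truth: list[dict]  # one row per expected region
    records: list[SeqRecord] = field(default_factory=list)


def default_registry() -> ProfileRegistry:
    """The bundled toy registry used by the generator and the CLI default."""
    from importlib import resources

    with resources.as_file(
        resources.files("metallomine.data").joinpath("default_registry.tsv")
    ) as p:
        return read_profile_registry(p)


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


def _translation(rng: np.random.Generator, n_aa: int) -> str:
    return "M" + "".join(rng.choice(_AA, size=n_aa - 1))


def generate(
    spec: GenomeSpec,
    registry: ProfileRegistry | None = None,
    rule: RuleExpr | None = None,
) -> GeneratedDataset:
    """Instantiate a genome spec into contigs, hits and truth rows.

    Deterministic given ``spec`` (including its seed). The expected verdicts
    carried by each template are re-validated against the rule and registry
    by actually running the pipeline on the generated data; a mismatch is a
    bug in the template and raises immediately.
    """
    if registry is None:
        registry = default_registry()
    if rule is None:
        rule = default_rule()
    for t in {name for c in spec.contigs for name in c.templates}:
        if t not in TEMPLATES:
            raise ValueError(f"unknown template: {t}")

    rng = np.random.default_rng(spec.seed)
    contigs: list[ContigRecord] = []
    records: list[SeqRecord] = []
    hits: list[DomainHit] = []
    truth: list[dict] = []

    for ci, cspec in enumerate(spec.contigs):
        contig_id = f"{spec.genome_id}_c{ci + 1}"
        truncate = cspec.truncate_at_edge or (False,) * len(cspec.templates)
        genes: list[GeneRecord] = []
        features: list[SeqFeature] = []
        cursor = 0
        cluster_spans: list[tuple[int, int]] = []
        for ki, tname in enumerate(cspec.templates):
            template = TEMPLATES[tname]
            if truncate[ki]:
                if ki != 0:
                    raise ValueError("truncate_at_edge only supported for the "
                                     "first cluster on a contig")
                start = int(rng.integers(200, 2_000))
            else:
                gap = EDGE_MARGIN + int(rng.integers(20_000, 30_000))
                start = cursor + gap
            pos = start
            first, last = pos, pos
            for gi, gslot in enumerate(template.genes):
                gene_id = f"{contig_id}_k{ki + 1}_{gslot.slot}"
                strand = "+" if rng.random() < 0.7 else "-"
                gene = GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    start=pos,
                    end=pos + GENE_LEN,
                    strand=strand,
                    translation=_translation(rng, GENE_LEN // 3),
                )
                genes.append(gene)
                features.append(_cds_feature(gene))
                for profile, factor in gslot.profiles:
                    cutoff = registry.cutoff(profile)
                    hits.append(
                        DomainHit(
                            gene_id=gene_id,
                            profile=profile,
                            bitscore=round(cutoff * factor, 1),
                            evalue=1e-30,
                            ali_start=0,
                            ali_end=GENE_LEN // 3,
                        )
                    )
                last = pos + GENE_LEN
                pos = last + INTERGENIC
            cluster_spans.append((first, last))
            cursor = last
            truth.append(
                {
                    "contig_id": contig_id,
                    "region_index": ki + 1,
                    "template": tname,
                    "chelator": template.expected_chelator,
                    "transporter": template.expected_transporter,
                    "ensemble": template.expected_chelator
                    or template.expected_transporter,
                    "groups": ";".join(sorted(template.expected_groups)),
                    "complete": not truncate[ki],
                }
            )
        length = cursor + EDGE_MARGIN + int(rng.integers(1_000, 5_000))
        # intergenic decoy genes with no hits, placed outside cluster spans
        for di in range(cspec.n_decoy_genes):
            for _ in range(50):
                s = int(rng.integers(0, length - GENE_LEN))
                span = (s, s + GENE_LEN)
                if all(
                    span[1] + 200 <= a or span[0] >= b + 200
                    for a, b in cluster_spans
                ) and all(
                    span[1] <= g.start or span[0] >= g.end for g in genes
                ):
                    gene = GeneRecord(
                        gene_id=f"{contig_id}_decoy{di + 1}",
                        contig_id=contig_id,
                        start=span[0],
                        end=span[1],
                        strand="+" if rng.random() < 0.5 else "-",
                        translation=_translation(rng, GENE_LEN // 3),
                    )
                    genes.append(gene)
                    features.append(_cds_feature(gene))
                    break
        contig = ContigRecord(contig_id=contig_id, length=length, genes=genes)
        contigs.append(contig)
        seq = Seq("".join(rng.choice(_NT, size=length)))
        rec = SeqRecord(
            seq,
            id=contig_id,
            name=contig_id[:16],
            description="synthetic contig with planted clusters",
            annotations={"molecule_type": "DNA", "date": "01-JAN-2000"},
        )
        rec.features = sorted(features, key=lambda f: int(f.location.start))
        records.append(rec)

    dataset = GeneratedDataset(contigs=contigs, hits=hits, truth=truth,
                               records=records)
    _validate(dataset, registry, rule)
    return dataset


def _cds_feature(gene: GeneRecord) -> SeqFeature:
    return SeqFeature(
        FeatureLocation(gene.start, gene.end, strand=1 if gene.strand == "+" else -1),
        type="CDS",
        qualifiers={
            "locus_tag": [gene.gene_id],
            "translation": [gene.translation],
        },
    )


def _validate(dataset: GeneratedDataset, registry: ProfileRegistry,
              rule: RuleExpr) -> None:
    """Check emitted truth against the pipeline run on the generated data."""
    regions, results = detect(dataset.contigs, dataset.hits, registry, rule)
    by_key = {}
    counters: dict[str, int] = {}
    for region, res in zip(regions, results):
        counters[region.contig_id] = counters.get(region.contig_id, 0) + 1
        by_key[(region.contig_id, counters[region.contig_id])] = (region, res)
    if len(by_key) != len(dataset.truth):
        raise AssertionError(
            f"template placement error: {len(by_key)} regions called, "
            f"{len(dataset.truth)} planted"
        )
    for row in dataset.truth:
        key = (row["contig_id"], row["region_index"])
        region, res = by_key[key]
        expected_groups = set(row["groups"].split(";")) if row["groups"] else set()
        if (
            res.chelator_rule != row["chelator"]
            or res.transporter_rule != row["transporter"]
            or set(res.profile.groups) != expected_groups
            or region.complete != row["complete"]
        ):
            raise AssertionError(
                f"template {row['template']} at {key}: generated data does "
                f"not reproduce its expected verdicts"
            )


# ---------------------------------------------------------------------------
# Serialization


def write_dataset(dataset: GeneratedDataset, dest: str | Path) -> dict[str, Path]:
    """Write genome.gbk, hits.tsv and truth.tsv into ``dest``."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    gbk = dest / "genome.gbk"
    with open(gbk, "w") as fh:
        SeqIO.write(dataset.records, fh, "genbank")
    hits_path = dest / "hits.tsv"
    from .io_formats import write_domain_hits

    write_domain_hits(dataset.hits, hits_path)
    truth_path = dest / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "# contig_id\tregion_index\tchelator\ttransporter\tensemble\t"
            "groups\tcomplete\ttemplate\n"
        )
        for row in dataset.truth:
            fh.write(
                "\t".join(
                    [
                        row["contig_id"],
                        str(row["region_index"]),
                        str(row["chelator"]).lower(),
                        str(row["transporter"]).lower(),
                        str(row["ensemble"]).lower(),
                        row["groups"],
                        str(row["complete"]).lower(),
                        row["template"],
                    ]
                )
                + "\n"
            )
    return {"genbank": gbk, "hits": hits_path, "truth": truth_path}


# ---------------------------------------------------------------------------
# Benchmarks


def benchmark_set(
    n_clusters: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    clusters_per_contig: int = 1,
) -> GeneratedDataset:
    """A labeled multi-contig benchmark with a stated template mix.

    ``mix`` maps template name to proportion (must sum to 1); counts are
    assigned by largest remainder so exactly ``n_clusters`` clusters are
    planted. Default mix is uniform over the clean templates.
    """
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    if mix is None:
        mix = {t: 1 / len(CLEAN_TEMPLATES) for t in CLEAN_TEMPLATES}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mix proportions must sum to 1 (got {total})")
    names = sorted(mix)
    exact = {t: n_clusters * mix[t] for t in names}
    counts = {t: int(exact[t]) for t in names}
    remainder = n_clusters - sum(counts.values())
    for t in sorted(names, key=lambda t: (exact[t] - counts[t]), reverse=True)[:remainder]:
        counts[t] += 1

    rng = np.random.default_rng(seed)
    roster = [t for t in names for _ in range(counts[t])]
    rng.shuffle(roster)
    contig_specs = tuple(
        ContigSpec(templates=tuple(roster[i : i + clusters_per_contig]))
        for i in range(0, len(roster), clusters_per_contig)
    )
    spec = GenomeSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        contigs=contig_specs,
        genome_id=f"bench{seed}",
    )
    return generate(spec)
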