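"""Input/output for genomes, domain-hit tables, profile registries and results.

Internal coordinates are 0-based half-open throughout; GenBank and GFF3 use
1-based inclusive coordinates and are converted exactly once, at the parse or
write boundary. All domain hits are retained at read time — significance
filtering against per-profile bitscore cutoffs is a separate, explicit step
(:func:`metallomine.rule_engine.apply_cutoffs`), so one hit table can be
re-evaluated under different registries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "ContigRecord",
    "DomainHit",
    "RegistryEntry",
    "ProfileRegistry",
    "TruthLabel",
    "FormatError",
    "read_genbank",
    "read_domain_hits",
    "write_domain_hits",
    "read_profile_registry",
    "read_truth_labels",
    "write_outputs",
]

#: categories a registry entry may carry; chelator categories double as the
#: chelating-group vocabulary used in classification output.
VALID_CATEGORIES = frozenset(
    {
        "catechol",
        "salicylate",
        "hydroxamate",
        "beta-OHAsp",
        "beta-OHHis",
        "graminine",
        "Dmaq",
        "pyoverdine-chromophore",
        "NRPS-core",
        "negative-constraint",
        "transporter",
        "other",
    }
)

VALID_ROLES = frozenset({"marker", "core", "negative", "transporter"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneRecord:
    """A single CDS on a contig (0-based, half-open coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    translation: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class ContigRecord:
    """One contig with its CDS records, sorted by start coordinate."""

    contig_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"contig {self.contig_id}: duplicate gene ids")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} extends past contig {self.contig_id} "
                    f"end ({g.end} > {self.length})"
                )


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match on one gene — the atom of all classification.

    ``ali_start``/``ali_end`` are stored 0-based half-open (converted from
    HMMER's 1-based inclusive alignment coordinates on read).
    """

    gene_id: str
    profile: str
    bitscore: float
    evalue: float = 0.0
    ali_start: int | None = None
    ali_end: int | None = None

    def __post_init__(self) -> None:
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError(f"hit {self.gene_id}/{self.profile}: bitscore not finite")
        if self.evalue < 0:
            raise ValueError(f"hit {self.gene_id}/{self.profile}: negative e-value")
        if self.ali_start is not None and self.ali_end is not None:
            if not self.ali_start < self.ali_end:
                raise ValueError(
                    f"hit {self.gene_id}/{self.profile}: empty alignment span"
                )


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    cutoff: float
    category: str
    role: str

    def __post_init__(self) -> None:
        if self.cutoff < 0:
            raise ValueError(f"profile {self.name}: cutoff must be >= 0")
        if self.category not in VALID_CATEGORIES:
            raise ValueError(
                f"profile {self.name}: unknown category {self.category!r}"
            )
        if self.role not in VALID_ROLES:
            raise ValueError(f"profile {self.name}: unknown role {self.role!r}")


class ProfileRegistry:
    """Map from profile name to bitscore cutoff, chelator category and role."""

    def __init__(self, entries: Iterable[RegistryEntry]):
        self._entries: dict[str, RegistryEntry] = {}
        for e in entries:
            if e.name in self._entries:
                raise FormatError(f"duplicate profile name: {e.name}")
            self._entries[e.name] = e

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> RegistryEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"profile not in registry: {name}") from None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def names(self) -> set[str]:
        return set(self._entries)

    def cutoff(self, name: str) -> float:
        return self[name].cutoff

    def by_role(self, role: str) -> set[str]:
        return {e.name for e in self if e.role == role}

    def by_category(self, category: str) -> set[str]:
        return {e.name for e in self if e.category == category}


@dataclass(frozen=True)
class TruthLabel:
    """A curated verdict for one region, keyed by contig and ordinal."""

    contig_id: str
    region_index: int
    is_metallophore: bool
    note: str = ""

    @property
    def region_key(self) -> tuple[str, int]:
        return (self.contig_id, self.region_index)


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path: str | Path) -> list[ContigRecord]:
    """Parse a (possibly multi-record) GenBank flat file into contigs.

    CDS features become :class:`GeneRecord` objects; GenBank 1-based inclusive
    locations are converted to 0-based half-open; compound (``join``)
    locations collapse to their outermost bounds. A CDS lacking both
    ``locus_tag`` and ``protein_id`` gets a synthesized id ``<contig>_cdsN``
    (logged as a warning).
    """
    path = Path(path)
    contigs: list[ContigRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"unparseable GenBank file {path.name}: {exc}") from exc
    for rec in records:
        genes: list[GeneRecord] = []
        n_anon = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            loc = feat.location
            if loc is None:
                raise FormatError(
                    f"record {rec.id}: CDS feature without a location"
                )
            quals = feat.qualifiers
            ids = quals.get("locus_tag") or quals.get("protein_id")
            if ids:
                gene_id = ids[0]
            else:
                n_anon += 1
                gene_id = f"{rec.id}_cds{n_anon}"
                logger.warning(
                    "CDS without locus_tag/protein_id in %s; using %s",
                    rec.id,
                    gene_id,
                )
            translation = quals.get("translation", [None])[0]
            # Biopython already reports 0-based half-open outermost bounds.
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=int(loc.start),
                    end=int(loc.end),
                    strand="-" if loc.strand == -1 else "+",
                    translation=translation,
                )
            )
        contigs.append(ContigRecord(contig_id=rec.id, length=len(rec.seq), genes=genes))
    return contigs


# ---------------------------------------------------------------------------
# Domain-hit tables

#: column order of HMMER3 --domtblout (22 fixed columns + free-text description)
_DOMTBL_MIN_COLS = 23


def _parse_domtblout(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >= {_DOMTBL_MIN_COLS} "
                    f"columns, got {len(fields)}"
                )
            try:
                # target name = col 0, query (profile) name = col 3,
                # full-seq e-value = col 6, this-domain bitscore = col 13,
                # ali coords = cols 17,18 (1-based inclusive).
                gene_id = fields[0]
                profile = fields[3]
                evalue = float(fields[6])
                bitscore = float(fields[13])
                ali_from = int(fields[17])
                ali_to = int(fields[18])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
            hits.append(
                DomainHit(
                    gene_id=gene_id,
                    profile=profile,
                    bitscore=bitscore,
                    evalue=evalue,
                    ali_start=ali_from - 1,
                    ali_end=ali_to,
                )
            )
    return hits


def _parse_hits_tsv(path: Path) -> list[DomainHit]:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["gene_id", "profile", "bitscore", "evalue"],
            dtype={"gene_id": str, "profile": str},
        )
    except pd.errors.EmptyDataError:
        return []
    hits = []
    for row in df.itertuples(index=False):
        try:
            hits.append(
                DomainHit(
                    gene_id=row.gene_id,
                    profile=row.profile,
                    bitscore=float(row.bitscore),
                    evalue=float(row.evalue),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}: bad row {tuple(row)}: {exc}") from exc
    return hits


def read_domain_hits(path: str | Path, dialect: str = "tsv") -> list[DomainHit]:
    """Read a domain-hit table.

    ``dialect="domtblout"`` reads HMMER3 per-domain tabular output;
    ``dialect="tsv"`` reads a 4-column table (gene_id, profile, bitscore,
    evalue). No cutoff filtering happens here.
    """
    path = Path(path)
    if dialect == "domtblout":
        return _parse_domtblout(path)
    if dialect == "tsv":
        return _parse_hits_tsv(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the 4-column TSV dialect (round-trips with read)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.profile}\t{h.bitscore:g}\t{h.evalue:g}\n")


# ---------------------------------------------------------------------------
# Registries and truth labels


def read_profile_registry(path: str | Path) -> ProfileRegistry:
    """Read a profile registry from TSV (name, cutoff, category, role) or JSON."""
    path = Path(path)
    entries: list[RegistryEntry] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for name, spec in data.items():
            entries.append(
                RegistryEntry(
                    name=name,
                    cutoff=float(spec["cutoff"]),
                    category=spec["category"],
                    role=spec["role"],
                )
            )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split("\t")]
                if len(parts) != 4:
                    raise FormatError(
                        f"{path.name}:{lineno}: expected 4 tab-separated "
                        f"fields, got {len(parts)}"
                    )
                name, cutoff, category, role = parts
                try:
                    entries.append(
                        RegistryEntry(name, float(cutoff), category, role)
                    )
                except ValueError as exc:
                    raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
    return ProfileRegistry(entries)


def read_truth_labels(path: str | Path) -> list[TruthLabel]:
    """Read curated truth labels: TSV with contig_id, region_index,
    is_metallophore (true/false or 1/0), optional note."""
    path = Path(path)
    labels: list[TruthLabel] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >= 3 fields"
                )
            contig_id, idx_s, flag_s = parts[0], parts[1], parts[2]
            note = parts[3] if len(parts) > 3 else ""
            flag = flag_s.strip().lower() in ("1", "true", "yes")
            label = TruthLabel(contig_id, int(idx_s), flag, note)
            if label.region_key in seen:
                raise FormatError(
                    f"{path.name}:{lineno}: duplicate region key {label.region_key}"
                )
            seen.add(label.region_key)
            labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# Result output


def write_outputs(results, regions, dest: str | Path) -> dict[str, Path]:
    """Write regions as GFF3, a per-region TSV and a JSON dump of results.

    Regions and results must share region ids. Output is byte-stable for
    identical inputs: regions sorted by (contig, start), JSON keys sorted.
    Returns the paths written, keyed ``gff``, ``tsv``, ``json``.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    by_id = {r.region_id: r for r in regions}
    res_ids = {r.region_id for r in results}
    if res_ids != set(by_id):
        missing = res_ids.symmetric_difference(by_id)
        raise ValueError(f"results/regions region_id mismatch: {sorted(missing)}")

    order = sorted(results, key=lambda r: (by_id[r.region_id].contig_id,
                                           by_id[r.region_id].start))

    gff_path = dest / "regions.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for res in order:
            reg = by_id[res.region_id]
            product = "NRP-metallophore" if res.chelator_rule else "NRPS"
            chel = ";".join(sorted(res.profile.groups)) if res.profile.groups else "."
            attrs = (
                f"ID={reg.region_id};product={product};"
                f"completeness={'complete' if reg.complete else 'partial'};"
                f"chelators={chel}"
            )
            fh.write(
                "\t".join(
                    [
                        reg.contig_id,
                        "metallomine",
                        "region",
                        str(reg.start + 1),  # 1-based inclusive
                        str(reg.end),
                        ".",
                        ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )

    tsv_path = dest / "regions.tsv"
    with open(tsv_path, "w") as fh:
        fh.write(
            "region_id\tcontig_id\tstart\tend\tcomplete\t"
            "chelator_rule\ttransporter_rule\tensemble\tchelators\n"
        )
        for res in order:
            reg = by_id[res.region_id]
            fh.write(
                "\t".join(
                    [
                        reg.region_id,
                        reg.contig_id,
                        str(reg.start),
                        str(reg.end),
                        str(reg.complete).lower(),
                        str(res.chelator_rule).lower(),
                        str(res.transporter_rule).lower(),
                        str(res.ensemble).lower(),
                        ";".join(sorted(res.profile.groups)),
                    ]
                )
                + "\n"
            )

    json_path = dest / "results.json"
    payload = []
    for res in order:
        reg = by_id[res.region_id]
        payload.append(
            {
                "region_id": reg.region_id,
                "contig_id": reg.contig_id,
                "start": reg.start,
                "end": reg.end,
                "complete": reg.complete,
                "anchor_genes": sorted(reg.anchor_gene_ids),
                "member_genes": sorted(reg.member_gene_ids),
                "chelator_rule": res.chelator_rule,
                "transporter_rule": res.transporter_rule,
                "ensemble": res.ensemble,
                "chelator_groups": sorted(res.profile.groups),
                "triggering": {
                    g: sorted(p) for g, p in sorted(res.profile.triggering.items())
                },
            }
        )
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"gff": gff_path, "tsv": tsv_path, "json": json_path}
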