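# Methods

## Model and procedure

The detector treats metallophore identification as deterministic boolean
classification over profile-HMM evidence. The pipeline is:

1. **Inputs.** An annotated genome (GenBank; CDS features become gene
   records with 0-based half-open coordinates) and a domain-hit table
   (HMMER3 `--domtblout` or a 4-column TSV) produced by scanning CDS
   translations against a profile set. A *profile registry* maps each
   profile name to a bitscore cutoff, a chelator category, and a role
   (marker / core / negative / transporter).
2. **Significance filtering.** A hit is significant iff its bitscore is
   ≥ the profile's cutoff (inclusive boundary). Filtering is a separate,
   explicit step so one hit table can be re-evaluated under different
   registries. Hits to profiles absent from the registry are an error,
   never silently dropped.
3. **Region assembly.** Anchor genes are single genes carrying both core
   NRPS domains (Condensation + AMP-binding) or a standalone marker
   (VibH_like / Cy_tandem). Anchors within `merge_distance` of each other
   (transitively, by gene-span gap) share a region; the span is the anchor
   envelope extended by `neighborhood` on both sides, clamped to the
   contig. A region is **complete** iff its pre-clamp extension fits the
   contig — truncation at either end marks it partial, the proxy for "on a
   contig edge".
4. **Classification.** The chelator rule (see README) is evaluated with
   region-scoped identifiers and gene-scoped `cds()`; the transporter rule
   requires ≥ 2 distinct families among PF00593/PF01032/PF01497 on region
   genes; the ensemble is their logical OR.
5. **Evaluation / census.** Confusion counts against curated labels yield
   precision = tp/(tp+fp), recall = tp/(tp+fn) and the harmonic-mean F1;
   census summaries stratify positives by completeness and tally
   chelating-group combinations (upset-plot input).

## Rule-language semantics and design choices

* Grammar: identifiers (letters, digits, `_`, `-`), `and`/`or`/`not`
  (precedence `not` > `and` > `or`, left-associative), parentheses,
  `cds(...)` (non-nestable). Parsing is a small recursive-descent parser
  with position-carrying errors; `pretty()` re-renders an AST so that
  `parse(pretty(parse(s))) == parse(s)`.
* The canonical rule text bundled in `data/nrp_metallophore.rule` includes
  an `or` between the ornithine-monooxygenase branch and `Lys_monoox`
  which some circulating renderings of the rule omit; without it the
  expression does not parse, and the surrounding branch structure
  (ornithine *or* lysine monooxygenase as alternative hydroxamate markers)
  fixes the repair unambiguously.
* **Negative constraints are region-scoped**: a KtzT hit anywhere in the
  region vetoes the ornithine branch, with no intra-region distance
  window. This reproduces the known behavior that false positives survive
  only when the constraint gene falls *outside* the detected region (the
  himastatin-type caveat); a windowed veto would be a different classifier.
* Identifier truth ignores hit multiplicity — one significant hit
  suffices; "at least one condensation and one adenylation domain" is a
  presence test.
* Triggering identifiers are collected along satisfied paths only, which
  makes the chelator-group profile sound: a vetoed branch contributes no
  witnesses even when another branch rescues the group.

## Chelating-group profile

The group mapping lives in `data/chelator_groups.json` as mini rule
strings (e.g. `"catechol": "EntA and EntC"`), not in code, so new
chelators can be added by editing the config. The
`NRPS-domain-marker` pseudo-group records regions detected only via
VibH_like/Cy_tandem; it is suppressed whenever a true chelator group is
witnessed, so it marks "detected by metallophore-specific NRPS domains
rather than chelator biosynthesis" and forms its own census class.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `merge_distance` | 20 000 | nt | max gap between anchor spans sharing a region; NRPS-scale convention |
| `neighborhood` | 20 000 | nt | extension on each side of the anchor envelope |
| bitscore cutoffs | per profile | bits | from the registry; toy defaults ship in `data/default_registry.tsv` |

The bundled registry's cutoffs are illustrative values for synthetic data,
not calibrated thresholds for any published profile set; all benchmark
quantities reported by `scripts/acceptance.py` are independent of the two
distance defaults. When regions closer than `2 × neighborhood` but farther
than `merge_distance` would overlap after extension, the overlap is split
at its midpoint so regions stay disjoint; completeness is decided before
clamping and is unaffected.

## Cutoff calibration

`calibration.choose_cutoff` reduces cutoff selection to a deterministic
rule: with no negative scores, cutoff = min(positive)/2; with a clean gap
(min positive > max negative), the gap midpoint; otherwise the profile is
flagged inseparable and no cutoff is emitted. The midpoint rule replaces
manual judgment with a symmetric-margin criterion and perfectly separates
the training scores by construction. The iterative remedy for inseparable
profiles — enriching the seed alignment with low-scoring true hits and
rebuilding the HMM — is inherently human-in-the-loop and is exposed only
as the `separable=False` flag.

## Synthetic data: what it emulates, what it does not

The generator plants cluster templates (catechol, three-group
pyoverdine-like hybrid, hydroxamate, salicylate, graminine, Dmaq,
standalone Type II marker, transporter-only "cheater", KtzT-vetoed and
SBH_Asp-excluded negatives, plain NRPS and sub-threshold decoys) on
contigs with realistic gene spacing, optional contig-edge truncation, and
intergenic decoy genes. Planted hits score `cutoff × 1.5` (significant) or
`cutoff × 0.5` (sub-threshold); offsets are configurable to probe the
inclusive boundary. Every template's expected verdicts are re-validated at
generation time by running the full pipeline on the generated data, so
emitted truth tables cannot drift from the rule semantics. Output bytes
are a pure function of spec + seed.

Deliberately absent: biological sequence content (translations are filler
peptide text; hit tables carry the signal), score noise, homologous decoy
families near cutoffs, overlapping clusters, and multi-locus pathways
(e.g. split pyoverdine loci). Perfect precision/recall on these fixtures
therefore certifies the engine's logic — parsing, scoping, vetoes, region
assembly, completeness — not detector performance on real genomes, where
cutoff quality and annotation noise dominate.

## Numerics and reporting conventions

* Rounding is half-up to match conventional reporting: precision/recall to
  two decimals or whole percent, F1 to two decimals; census percentages to
  whole percent, keeping one decimal below 10%.
* Degenerate confusion tables (zero denominators) yield metric 0 with a
  `degenerate` flag rather than NaN.
* All outputs are byte-stable: regions sorted by (contig, start), JSON
  keys sorted.
* Benchmark sizes in `scripts/acceptance.py`: five 24-cluster clean
  benchmarks (120 planted clusters) plus one 12-cluster mix with three
  planted cheaters — large enough that every template class occurs many
  times while the whole script completes in seconds.

## Known limitations

* The region builder is a simplified re-implementation of cluster-calling
  conventions; partial-region *counts* on real assemblies depend on the
  annotating tool's internals and are out of scope (only the percentage
  arithmetic over given counts is reproduced).
* The rule cannot see chelator genes encoded outside the detected region —
  the dominant source of false negatives in curated benchmarks — nor
  chelators with unknown biosynthesis; this is a property of the method,
  not of this implementation.
* Distinguishing siderophores from zincophores and other metallophore
  classes would require regulatory-element evidence and is out of scope.
* Truth labels key regions by (contig, ordinal in coordinate order); a
  coordinate-span keying would be needed if region calls and labels came
  from different region definitions.
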