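# metallomine

Rule-based detection of **non-ribosomal peptide (NRP) metallophore**
biosynthetic gene clusters (BGCs) in bacterial genomes.

Metallophores — siderophores and their relatives — are secreted small
molecules that chelate environmental metal ions. Their NRP members are
assembled by non-ribosomal peptide synthetases (NRPS), and until recently
telling a metallophore NRPS cluster apart from any other NRPS cluster
required expert manual inspection. This package implements the automated
alternative: a boolean detection rule over profile-HMM hits to
chelator-biosynthesis enzymes, each hit gated by a per-profile bitscore
significance cutoff, evaluated with gene-scoped and region-scoped
semantics. It is aimed at genome miners and comparative genomicists who
have annotated genomes plus HMMER search results and want classified
candidate regions with chelating-group assignments.

## The detection rule

A candidate NRPS region is called an NRP metallophore when

```
VibH_like or Cy_tandem or
(cds(Condensation and AMP-binding) and (
   (IBH_Asp and not SBH_Asp) or IBH_His or TBH_Asp or
   CyanoBH_Asp1 or CyanoBH_Asp2 or
   IPL or SalSyn or (EntA and EntC) or
   (GrbD and GrbE) or (FbnL and FbnM) or PvdO or PvdP or
   (Orn_monoox and not (KtzT or MetRS-like)) or
   Lys_monoox or VbsL))
```

where an identifier is true iff some gene in the region has a hit with
bitscore ≥ that profile's cutoff, and `cds(...)` requires its condition to
hold on a *single* gene. The branches map onto chelating groups: catechol
(EntA∧EntC), salicylate (IPL∨SalSyn), hydroxamate (ornithine/lysine
monooxygenases, vetoed by the piperazate/hydrazine markers KtzT and
MetRS-like), β-hydroxyaspartate and β-hydroxyhistidine hydroxylases (with
the syringomycin-family profile SBH_Asp as a competing negative
constraint), graminine (GrbD∧GrbE), Dmaq (FbnL∧FbnM), and the pyoverdine
chromophore (PvdO∨PvdP). `VibH_like`/`Cy_tandem` are metallophore-specific
NRPS domain subtypes that trigger standalone, admitting Type II
(non-/semi-modular) systems.

Alongside the chelator rule the package provides the transporter-based
classifier (≥ 2 of the siderophore-associated Pfam families PF00593,
PF01032, PF01497 in a region), the either/or ensemble of the two, region
assembly with contig-edge completeness flags, precision/recall/F1
evaluation against curated labels, census and chelator-combination
summaries, a bitscore-cutoff calibration helper, and a deterministic
synthetic-genome generator for end-to-end testing.

## Worked example

Simulate a genome with three planted loci — an enterobactin-like catechol
cluster, a "cheater" that kept transporters but lost chelator biosynthesis,
and a hydroxamate locus carrying the KtzT veto — then detect and score:

```sh
$ metallomine simulate --templates enterobactin,cheater,himastatin_veto \
      --seed 7 --out sim
planted 3 cluster(s) on 3 contig(s)

$ metallomine detect --genome sim/genome.gbk --hits sim/hits.tsv --out out
3 region(s) called; 1 metallophore-positive by the chelator rule

$ metallomine evaluate --truth sim/truth.tsv --pred out/results.json \
      --method chelator
method=chelator n=3 tp=1 fp=0 fn=0 tn=2
precision=1.00 (100%) recall=1.00 (100%) f1=1.00
```

`out/regions.tsv` shows the per-region verdicts — the enterobactin region
is positive under both methods with the `catechol` group, the cheater is
transporter-positive only (the documented disagreement between the
methods), and the vetoed hydroxamate locus is negative under both:

```
region_id   contig_id  start  end    complete  chelator_rule  transporter_rule  ensemble  chelators
sim7_c1_r1  sim7_c1    36549  77449  true      true           true              true      catechol
sim7_c2_r1  sim7_c2    34481  75381  true      false          true              true
sim7_c3_r1  sim7_c3    27455  68355  true      false          false             false
```

The same objects are available as a library:

```python
from metallomine import detect, read_genbank, read_domain_hits, default_registry

contigs = read_genbank("sim/genome.gbk")
hits = read_domain_hits("sim/hits.tsv", dialect="tsv")
regions, results = detect(contigs, hits, default_registry())
```

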