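# Methods

This note documents the model behind `irdprio`, the parameter defaults and
why they were chosen, the design decisions taken where the procedure was
genuinely open, what the synthetic cohorts do and do not emulate, and the
known limitations.

## Scope and model

`irdprio` is a tertiary-analysis tool: it consumes already-called,
already-annotated variants (a multi-sample VCF with gene symbol, population
MAF, population homozygote count, ClinVar significance/phenotypes,
predictor calls and ACMG class in INFO keys) and never performs alignment,
calling, annotation, or in-silico score computation.  The genetic model is
autosomal recessive with possible oligogenic modifiers: disease in an
affected member is explained by a biallelic configuration in one panel gene
— two different alleles in trans (compound heterozygosity) or one allele in
homozygosis — while additional candidate alleles in other genes are
surfaced as possible modifiers, never scored for causality.

## Filter cascade

Order: ClinVar rescue (bookkeeping) → recurrence → frequency → gene panel →
pedigree.  Each step is a pure, idempotent contraction of the variant
table; a per-step trace records input/output counts and the removed ids, so
every discarded variant is attributable to exactly one step.

Parameters (all in `FilterConfig`, overridable via YAML):

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | population MAF above which a variant is discarded |
| `treat_missing_maf_as_pass` | true | novel alleles (no population entry) survive |
| `max_control_carriers` | 0 | pseudo-control samples allowed to carry the alt |
| `flank_bp` | 10 bp | exon flank counted as near-splice (inclusive bound) |
| `phenotype_terms` | retinitis pigmentosa, retinal dystrophy, usher syndrome | rescue phenotype match terms |
| `splice_thresholds` | MaxEnt (2, 15%), HSF (70, 10%), NNSPLICE (0.4, 10%) | per-tool (min score, min variation) |
| `splice_quorum` | 2 of 3 | predictors required to admit a deep-intronic variant |

Design decisions where the procedure was open:

* **Recurrence semantics.** "Exclusive of the family" and "absent in
  homozygosis in the controls" overlap: strict exclusivity makes the
  homozygosity clause redundant.  The default is the strict reading
  (`max_control_carriers = 0`) with the control-homozygote guard kept as an
  independent, always-on clause, and the carrier tolerance exposed as a
  knob for the lenient reading.
* **Rescue scope.** Rescue exempts a variant from the recurrence and
  frequency filters only.  It does not bypass the gene filter (a pathogenic
  allele for an unrelated phenotype is out of scope) nor the pedigree
  filter (an allele homozygous in an unaffected relative is incompatible
  with the model regardless of its ClinVar status).
* **Phenotype matching** is case-insensitive substring containment between
  the configured disease terms and the ClinVar phenotype list; ClinVar
  condition strings are free text, so exact matching would be brittle.
* **Missing genotypes** at a site absent from one input VCF default to
  `missing`, not `hom_ref` (single-sample VCFs do not assert reference
  calls); a `missing_as_ref` flag covers all-sites sources.
* **Zygosity model.** Multiallelic sites are split into biallelic records
  with per-allele zygosity from the GT allele indices; haploid calls count
  as homozygous (no heterozygote on a single allele).  Genotype quality and
  depth are not consulted.

## Region triage and splice thresholds

Positions are classified against 0-based half-open exon models converted to
1-based inclusive bounds at the boundary: `coding_exonic` inside an exon;
`near_splice` within `flank_bp` of an exon boundary, inclusive, so a
position exactly 10 bp from an exon still qualifies; `deep_intronic` inside
the gene span otherwise; `other` outside every span.  The four classes
partition the axis (verified by exhaustive scan in the tests).

The per-tool splice rule applies the score floor to the *stronger* of the
wild-type and mutant site scores, `max(|w|, |m|) ≥ s_min`, so both site-loss
(strong wild type) and site-gain (strong mutant) events qualify; the score
variation is relative to the wild type, `|w − m| / max(|w|, ε) × 100` with
`ε = 1e-9` guarding a zero wild-type score, and must *strictly* exceed the
minimum.  A quorum of 2 of 3 tools admits a deep-intronic variant: the
three predictors were calibrated jointly and a majority rule is the neutral
combination; it is configurable.  HSF scores are interpreted on the 0–100
consensus-value scale.

## Pairing, phase, segregation

Pairs are enumerated per gene from affected carriers (double-het, or
self-pair for a homozygote, which is trivially trans).  Phase inference
uses one informative meiosis at a time under a rare-allele assumption (an
allele seen in one parent is not independently carried by the other; a
meiosis is skipped when the other parent demonstrably carries either
allele):

* double-het parent → child carries **both** ⇒ cis; **exactly one** ⇒
  trans; **neither** ⇒ uninformative (equally consistent with transmission
  of the variant-free haplotype of a cis carrier, so a single both-absent
  observation is never called);
* double-het child with a typed parent carrying exactly one allele ⇒ trans
  (distinct parental origins);
* conflicting observations ⇒ `unknown` with a logged conflict (possible
  genotyping error) — never silently resolved.

Segregation evaluates a configuration over the *genotyped* members of a
scope (family-wide plus each branch — the children of one parent couple
and their descendants).  Unaffected single-allele carriers are consistent
(recessive model); only the full biallelic configuration in an unaffected
member demotes a verdict to `partial`; members missing any configuration
call are `untyped` and excluded from the verdict.  Verdicts are strict
within a scope: one typed affected member lacking the configuration
excludes it there.  In families with several causal combinations no pair
segregates family-wide, which is why the report gives per-branch verdicts
alongside the family-wide one.  The oligogenic flag (an affected member
carrying candidate alleles in ≥ 2 genes, counting only alleles of non-cis
pairs and lone candidates in genes without pairs) is reporting-only.

## Synthetic cohorts

**Reconstructed family.**  The bundled fixture encodes the published
summary of the motivating study family: the 19-member genotyped pedigree
(5 affected, 3 sequenced), the six candidate alleles with their published
annotations, and exactly the genotypes asserted in the running text;
members whose genotypes were only shown graphically are left untyped
rather than guessed.  Genomic coordinates are synthetic placements inside
toy exon models, since only HGVS labels are published.  The unaffected
son's per-variant WGS calls are reconstructed as het for M2 only — the
minimal configuration consistent with the published trans phase of the
index patient's pair and with its non-exclusion.  Optional decoys (n per
class, deterministic placement) exercise each cascade step.

**Simulator.**  A fixed seven-member family (two carrier parents, two
affected siblings, one carrier sibling, a spouse, and an unaffected
grandchild) plus unrelated controls on a toy diploid genome: two ~100 kb
contigs, a 12-gene panel of three-exon genes.  Founders carry two phased
haplotypes with gene-scale linkage (no recombination within a gene), so
cis/trans is exact and every child genotype is Mendelian by construction
(verified by an exhaustive trio validator).  Defaults mirror the study
conditions: 3 sequenced family members (the affected-sib / affected-sib /
unaffected-child configuration) and 6 pseudo-controls.  The planted pair
sits in trans by construction; each decoy class is constructed to violate
exactly one filter (common polymorphism → frequency; control-shared
artefact → recurrence; homozygous-in-unaffected → pedigree; off-panel →
gene filter), and cis decoy pairs ride a single founder haplotype so the
grandchild observes their co-transmission.  Default 40 decoys per cohort
in proportions 0.25/0.25/0.20/0.20/0.10; all randomness (positions,
alleles, frequencies, gene assignment) derives from a single seed, and a
fixed seed yields byte-identical output files.

What the simulator does **not** emulate: genotyping error, missingness,
de-novo mutation, recombination within genes, linkage disequilibrium or
any population-genetic structure, X-linked or dominant inheritance, and
read-level artefacts.  Passing tests therefore demonstrate the logical
correctness of the filters, phasing and verdicts under clean calls — not
robustness to noisy real-world data, where the conflict-handling paths
(phase conflicts, untyped members) become important.

## Numerical choices and degenerate inputs

MAF values are serialized with 6 significant digits and re-quantized on
read, so tables survive htslib's float32 INFO storage and VCF writing is a
byte-stable fixed point (the simulator's determinism contract).  Records
are sorted by natural chromosome order, position, ref, alt; candidate
output by (tier, gene, position); pair keys are sorted variant-id tuples —
all ties are broken deterministically.  Empty tables flow through the whole
pipeline (empty candidate list, empty report).  Symbolic/breakend alternate
alleles are skipped with a warning.  Male X hemizygosity is not modelled
(haploid calls read as homozygous); all fixture genes are autosomal.

## Limitations

* No statistical linkage or LOD computation, no penetrance model, no
  read-backed phasing: phase comes from pedigree transmission only, and an
  isolated double-het with no informative relatives stays `unknown`
  (reported, not excluded).
* The strict segregation verdict assumes full penetrance within a scope;
  late-onset or unexamined members should be encoded as untyped/unknown
  rather than unaffected.
* The cascade trusts its input annotations; a variant mis-annotated with
  the wrong gene symbol can enter through the symbol clause of the gene
  filter even when its coordinates lie elsewhere.
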