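# irdprio

Variant prioritization for families with inherited retinal dystrophy (IRD)
sequenced by whole-genome sequencing.  `irdprio` implements the tertiary
half of a WGS diagnostic workflow: it takes an annotated multi-sample VCF, a
PED pedigree and a disease gene panel, and reduces millions of called
variants to a short, auditable list of candidate alleles, compound-
heterozygous pairs with cis/trans phase, and per-branch segregation
verdicts.  It is aimed at diagnostic labs and researchers analysing
"unsolved" retinitis pigmentosa families — in particular pseudo-dominant
pedigrees where recessive alleles in genes such as *USH2A*, *ADGRV1* and
*PDZD7* segregate in different biallelic combinations across family
branches, sometimes with oligogenic configurations in single patients.

## The algorithm

Five filters are applied in sequence, each a pure contraction of the
variant table with a logged trace:

1. **ClinVar rescue** (bookkeeping, applied first): variants with
   significance ∈ {P, LP, conflicting P/VUS} *and* a ClinVar phenotype
   matching the disease terms (case-insensitive substring, e.g.
   "retinitis pigmentosa", "usher syndrome") are exempted from the two
   following filters.
2. **Recurrence**: keep variants exclusive of the family — carried by ≥ 1
   family sample, carried by ≤ `max_control_carriers` (default 0)
   pseudo-control samples, and never homozygous in a pseudo-control.  The
   pseudo-control cohort is a set of unaffected individuals from unrelated
   families sequenced under similar conditions; this step subtracts
   platform artefacts and shared polymorphisms.
3. **Frequency**: discard variants with gnomAD MAF > 0.01; variants with no
   population entry (novel alleles) pass.
4. **Gene panel**: keep variants inside the body of a panel gene (introns
   included, regardless of splice-site distance) or annotated with a panel
   gene symbol.
5. **Pedigree**: keep variants carried (het or hom) by ≥ 1 sequenced
   affected member and not homozygous in any sequenced unaffected member
   (the recessive-compatible rule).

Survivors are triaged against the panel's exon models: exonic and
near-splice positions (± 10 bp of an exon boundary, inclusive) form tier 1;
deep-intronic variants enter tier 2 only when ≥ 2 of 3 splice predictors
flag an impact.  Per tool, a wild-type/mutant score pair (w, m) passes when

    max(|w|, |m|) ≥ s_min   and   |w − m| / max(|w|, ε) × 100 > v_min

with (s_min, v_min) = (2, 15%) for MaxEntScan, (70, 10%) for HSF and
(0.4, 10%) for NNSPLICE.  Population-homozygote counts are surfaced as a
per-candidate flag (every reportable allele should have 0 homozygotes);
SIFT/PolyPhen-2/MutationTaster calls and ACMG classes are carried through
but never filter.

Within each gene, candidate alleles are paired whenever an affected member
is heterozygous for both (or homozygous for one).  Phase is inferred from
informative meioses: a double-het parent transmitting both alleles to a
child implies **cis** (the pair is excluded — only trans pairs can explain
recessive disease), transmitting exactly one implies **trans**, and
distinct parental origins imply trans; conflicting meioses leave the phase
unknown with a logged conflict.  Finally, each non-cis pair is segregated
over the genotyped extended pedigree, family-wide and per branch:
*segregates* (every typed affected carries the full configuration, no typed
unaffected does), *partial* (an unaffected member shares the full
configuration) or *excluded*.

## Worked example

The package ships a reconstruction of a four-generation pseudo-dominant RP
family: 19 genotyped members (5 affected), WGS for the index patient III:3,
her affected cousin III:23 and her unaffected son IV:1, six pseudo-controls,
and six clinically relevant heterozygous variants — four in *USH2A* (M1–M4),
one in *PDZD7* (M5), one in *ADGRV1* (M6) — with their published
MAF/ClinVar/predictor annotations (genomic coordinates are synthetic
placeholders inside toy exon models).

```sh
irdprio fixture --out-dir demo --n-decoys-per-class 2
irdprio run --vcf demo/family.vcf --ped demo/family.ped \
            --panel demo/panel.bed --genotypes demo/genotypes.tsv \
            --out-dir demo_out
```

The cascade log shows each step's contraction (14 input variants: the six
real alleles plus eight planted decoys, two per filter class):

```
clinvar_rescue     14 ->     14
recurrence         14 ->     12
frequency          12 ->     10
gene_panel         10 ->      8
pedigree            8 ->      6
```

and `demo_out/report.txt` reads:

```
Family RP-FAM

Biallelic pairs:
  USH2A: chr1:10100:A:AGCCA + chr1:12100:G:T  phase=unknown
      family-wide: excluded  (affected carriers: III:17, III:23)
      branch II:5+II:6: segregates
  USH2A: chr1:10200:C:T + chr1:12100:G:T  phase=unknown
      family-wide: excluded  (affected carriers: III:20)
  USH2A: chr1:10200:C:T + chr1:15300:G:A  phase=trans
      family-wide: excluded  (affected carriers: III:3)
      branch II:1+II:2: partial

Per-member candidate alleles:
  II:1 (affected): chr1:10200:C:T
  III:3 (affected): chr5:30100:G:GTGGAACTCCAGGAGGG, chr10:20500:C:T, chr1:10200:C:T, chr1:15300:G:A  [possible oligogenic configuration]
  ...
```

Reading the output: no single pair segregates family-wide — the family's
disease is explained by *different* biallelic combinations per branch.  The
frameshift+missense pair M1+M3 segregates in the third branch (III:17 and
III:23); M2+M3 explains III:20; the index patient's pair M2+M4 is phased
trans through her son IV:1 but demoted to *partial* because her unaffected
sister III:4 shares both alleles; and III:3 carries four clinically
relevant alleles across three genes, flagged as a possible oligogenic
configuration.  `candidates.tsv` lists the six tier-1 candidates (all
exonic, all with zero population homozygotes); `trace.json` attributes
every removed decoy to exactly one filter step.

There is also a seeded simulator for end-to-end validation with planted
truth (`irdprio simulate --out-dir sim --seed 3`): it writes a toy-genome
cohort (VCF/PED/BED/TSV + truth JSON) in which one compound-het pair is
planted in trans and decoy variants are constructed to be removed by
specific filter steps or excluded as cis pairs.

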