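"""Synthetic cohorts: the reconstructed study family and a seeded simulator.

``build_reference_fixture`` re-creates, from published summary data, the
large pseudo-dominant retinitis pigmentosa family that motivates this
pipeline: 19 genotyped members across four generations (5 affected, 3 with
WGS: the index patient III:3, her affected cousin III:23 and her unaffected
son IV:1), six clinically relevant heterozygous variants (four in USH2A, one
in PDZD7, one in ADGRV1) with their published MAF/ClinVar/predictor
annotations, and six unrelated pseudo-control samples.  Genomic coordinates
are synthetic placeholders inside toy exon models (the source reports
HGVS labels, not genomic positions, and the underlying data are not
deposited); genotypes are restricted to those asserted in the running text —
everything else is left untyped rather than guessed.  IV:1's per-variant
WGS calls are likewise not stated individually and are reconstructed as
het for M2 only, the minimal configuration consistent with the published
phase and segregation statements.

``simulate_cohort`` generates family + pseudo-control cohorts with planted
truth on a toy diploid genome (two ~100 kb contigs, a 12-gene panel).  Each
founder carries two phased haplotypes with gene-scale linkage (no
recombination within a gene), so cis/trans is well defined.  One causal
compound-heterozygous pair is planted in trans in the affected siblings;
decoy variants are drawn per class so that each is removed by exactly one
cascade step (common polymorphism → frequency; control-shared artifact →
recurrence; homozygous-in-unaffected → pedigree; off-panel → gene filter)
and cis decoy pairs survive the cascade but are excluded by trio phasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import write_gene_panel, write_genotype_table, write_pedigree, write_vcf
from .model import (
    Affection,
    ClinVarSignificance,
    GeneModel,
    GenePanel,
    Pedigree,
    PedigreeMember,
    Sex,
    ValidationError,
    VariantRecord,
    VariantTable,
    Zygosity,
)

# ---------------------------------------------------------------------------
# Reconstructed study-family fixture
# ---------------------------------------------------------------------------

_IRD_PHENOTYPES = frozenset({"Retinitis pigmentosa", "Usher syndrome type 2A"})


def reference_panel() -> GenePanel:
    """Toy exon models for the three candidate genes plus two decoy-host
    panel genes (synthetic coordinates)."""
    return GenePanel(
        [
            GeneModel(
                "USH2A", "chr1", (10000, 16000),
                [(10000, 10800), (12000, 12800), (14000, 14800), (15200, 16000)],
            ),
            GeneModel("CRB1", "chr1", (40000, 44000), [(40000, 40600), (43400, 44000)]),
            GeneModel("ADGRV1", "chr5", (30000, 36000), [(30000, 30800), (35200, 36000)]),
            GeneModel("EYS", "chr6", (50000, 56000), [(50000, 50600), (55400, 56000)]),
            GeneModel("PDZD7", "chr10", (20000, 23000), [(20000, 20600), (22400, 23000)]),
        ],
        name="IRD-panel-subset",
    )


def _reference_records() -> Dict[str, VariantRecord]:
    """The six clinically relevant variants (published annotations; synthetic
    genomic placement inside the toy USH2A/PDZD7/ADGRV1 exon models)."""
    P = ClinVarSignificance.PATHOGENIC
    LP = ClinVarSignificance.LIKELY_PATHOGENIC
    recs = {
        "M1": VariantRecord(
            "chr1", 10100, "A", "AGCCA", gene="USH2A",
            maf=0.0000568, hom_count=0, clinvar_significance=P,
            clinvar_phenotypes=_IRD_PHENOTYPES, acmg_class=5,
            label="USH2A:c.923_924dupGCCA:p.(His308Glnfs*16)",
        ),
        "M2": VariantRecord(
            "chr1", 10200, "C", "T", gene="USH2A",
            maf=0.0000531, hom_count=0, clinvar_significance=LP,
            clinvar_phenotypes=_IRD_PHENOTYPES, acmg_class=5,
            label="USH2A:c.1000C>T:p.(Arg334Trp)",
        ),
        "M3": VariantRecord(
            "chr1", 12100, "G", "T", gene="USH2A",
            maf=0.0009677, hom_count=0, clinvar_significance=LP,
            clinvar_phenotypes=_IRD_PHENOTYPES, acmg_class=4,
            label="USH2A:c.2276G>T:p.(Cys759Phe)",
        ),
        "M4": VariantRecord(
            "chr1", 15300, "G", "A", gene="USH2A",
            maf=0.0000213, hom_count=0,
            predictor_calls={"sift": "D(100%)", "polyphen2": "B(0.066)", "mutationtaster": "SNP"},
            acmg_class=3, label="USH2A:c.12560G>A:p.(Arg4187His)",
        ),
        "M5": VariantRecord(
            "chr10", 20500, "C", "T", gene="PDZD7",
            maf=0.0000134, hom_count=0,
            predictor_calls={"sift": "D(100%)", "mutationtaster": "DC"},
            acmg_class=5, label="PDZD7:c.1543C>T:p.(Gln515*)",
        ),
        "M6": VariantRecord(
            "chr5", 30100, "G", "GTGGAACTCCAGGAGGG", gene="ADGRV1",
            predictor_calls={"polyphen2": "PD(0.999)", "mutationtaster": "DC"},
            acmg_class=4, label="ADGRV1:c.13165_13166insTGGAACTCCAGGAGGG:p.(Gly4360Glufs*10)",
        ),
    }
    return recs


_GENOTYPED_19 = [
    "II:1", "III:3", "III:4", "III:5", "III:7", "III:8", "III:10", "III:11",
    "III:15", "III:17", "III:18", "III:20", "III:21", "III:23", "IV:1",
    "IV:2", "IV:3", "IV:4", "IV:35",
]
_AFFECTED_5 = ["II:1", "III:3", "III:17", "III:20", "III:23"]
_SEQUENCED_3 = ["III:3", "III:23", "IV:1"]


def reference_pedigree() -> Pedigree:
    """Four-generation pedigree: 19 genotyped members in three gen-III
    branches, 5 affected, 3 sequenced; ungenotyped spouses/founders complete
    the graph."""

    def m(mid, father=None, mother=None, sex=Sex.UNKNOWN):
        return PedigreeMember(
            member_id=mid,
            father_id=father,
            mother_id=mother,
            sex=sex,
            affected=(
                Affection.AFFECTED
                if mid in _AFFECTED_5
                else Affection.UNAFFECTED
                if mid in _GENOTYPED_19
                else Affection.UNKNOWN
            ),
            sequenced=mid in _SEQUENCED_3,
            genotyped=mid in _GENOTYPED_19,
        )

    members = [
        m("I:1", sex=Sex.MALE), m("I:2", sex=Sex.FEMALE),
        m("II:1", "I:1", "I:2", Sex.MALE), m("II:2", sex=Sex.FEMALE),
        m("II:3", "I:1", "I:2", Sex.MALE), m("II:4", sex=Sex.FEMALE),
        m("II:5", "I:1", "I:2", Sex.MALE), m("II:6", sex=Sex.FEMALE),
        # first branch
        m("III:3", "II:1", "II:2", Sex.FEMALE), m("III:4", "II:1", "II:2", Sex.FEMALE),
        m("III:5", "II:1", "II:2", Sex.MALE), m("III:7", "II:1", "II:2", Sex.FEMALE),
        m("III:8", "II:1", "II:2", Sex.MALE),
        # second branch
        m("III:10", "II:3", "II:4", Sex.MALE), m("III:11", "II:3", "II:4", Sex.FEMALE),
        m("III:15", "II:3", "II:4", Sex.MALE),
        # third branch
        m("III:17", "II:5", "II:6", Sex.MALE), m("III:18", "II:5", "II:6", Sex.FEMALE),
        m("III:20", "II:5", "II:6", Sex.FEMALE), m("III:21", "II:5", "II:6", Sex.MALE),
        m("III:23", "II:5", "II:6", Sex.MALE),
        # spouses and generation IV
        m("III:2", sex=Sex.MALE), m("III:6", sex=Sex.FEMALE), m("III:24", sex=Sex.FEMALE),
        m("IV:1", "III:2", "III:3", Sex.MALE), m("IV:2", "III:2", "III:3", Sex.FEMALE),
        m("IV:3", "III:5", "III:6", Sex.MALE), m("IV:4", "III:5", "III:6", Sex.FEMALE),
        m("IV:35", "III:23", "III:24", Sex.MALE),
    ]
    return Pedigree(members, family_id="RP-FAM")


#: Sanger/WGS genotypes asserted by the published segregation statements;
#: members absent from this map are untyped for the variant in question.
_TEXT_GENOTYPES = {
    "II:1": {"M2": Zygosity.HET},
    "III:3": {
        "M1": Zygosity.HOM_REF, "M2": Zygosity.HET, "M3": Zygosity.HOM_REF,
        "M4": Zygosity.HET, "M5": Zygosity.HET, "M6": Zygosity.HET,
    },
    "III:4": {"M2": Zygosity.HET, "M4": Zygosity.HET},
    "III:17": {"M1": Zygosity.HET, "M3": Zygosity.HET},
    "III:20": {"M2": Zygosity.HET, "M3": Zygosity.HET},
    "III:23": {
        "M1": Zygosity.HET, "M2": Zygosity.HOM_REF, "M3": Zygosity.HET,
        "M4": Zygosity.HOM_REF, "M5": Zygosity.HOM_REF, "M6": Zygosity.HOM_REF,
    },
    # reconstructed minimal WGS configuration (see module docstring)
    "IV:1": {
        "M1": Zygosity.HOM_REF, "M2": Zygosity.HET, "M3": Zygosity.HOM_REF,
        "M4": Zygosity.HOM_REF, "M5": Zygosity.HOM_REF, "M6": Zygosity.HOM_REF,
    },
}

_CONTROLS_6 = [f"PC{i}" for i in range(1, 7)]

_DECOY_CLASSES = (
    "common_polymorphism",
    "control_shared_artifact",
    "hom_in_unaffected",
    "off_panel",
)

#: cascade step expected to remove each decoy class
DECOY_REMOVAL_STEP = {
    "common_polymorphism": "frequency",
    "control_shared_artifact": "recurrence",
    "hom_in_unaffected": "pedigree",
    "off_panel": "gene_panel",
}


@dataclass
class ReferenceFixture:
    """The reconstructed family bundle used by the worked example and tests."""

    wgs: VariantTable  # 3 sequenced members + 6 pseudo-controls
    genotypes: VariantTable  # all 19 genotyped members (Sanger + WGS calls)
    pedigree: Pedigree
    panel: GenePanel
    family_samples: List[str]
    control_samples: List[str]
    variant_ids: Dict[str, str]  # M1..M6 → chrom:pos:ref:alt
    decoy_classes: Dict[str, str] = field(default_factory=dict)  # decoy vid → class


def build_reference_fixture(n_decoys_per_class: int = 0) -> ReferenceFixture:
    """Assemble the study-family fixture, optionally salted with decoys.

    Decoys are deterministic (no RNG): each instance of a class is placed at
    a fixed offset inside a decoy-host gene (CRB1/EYS) or in the intergenic
    region, carried het by the index patient and configured so that exactly
    one cascade step removes it.
    """
    panel = reference_panel()
    pedigree = reference_pedigree()
    recs = _reference_records()
    vids = {name: rec.variant_id for name, rec in recs.items()}

    wgs_samples = _SEQUENCED_3 + _CONTROLS_6
    wgs = VariantTable(samples=wgs_samples)
    for rec in recs.values():
        wgs.add_record(rec)
    for name, rec in recs.items():
        for sample in _SEQUENCED_3:
            zyg = _TEXT_GENOTYPES[sample].get(name, Zygosity.HOM_REF)
            wgs.set_call(rec.variant_id, sample, zyg)
        for ctrl in _CONTROLS_6:
            wgs.set_call(rec.variant_id, ctrl, Zygosity.HOM_REF)

    decoy_classes: Dict[str, str] = {}
    for i in range(n_decoys_per_class):
        specs = [
            # class, chrom, pos (1-based), maf
            ("common_polymorphism", "chr1", 40010 + i, round(0.05 + 0.01 * i, 6)),  # CRB1 exon 1
            ("control_shared_artifact", "chr6", 50010 + i, None),  # EYS exon 1
            ("hom_in_unaffected", "chr1", 43410 + i, None),  # CRB1 exon 2
            ("off_panel", "chr1", 90000 + i, None),  # intergenic
        ]
        for cls, chrom, pos, maf in specs:
            gene = ""
            hosts = panel.genes_at(chrom, pos)
            if hosts:
                gene = hosts[0].name
            rec = VariantRecord(chrom, pos, "A", "C", gene=gene, maf=maf)
            wgs.add_record(rec)
            decoy_classes[rec.variant_id] = cls
            for sample in wgs_samples:
                wgs.set_call(rec.variant_id, sample, Zygosity.HOM_REF)
            wgs.set_call(rec.variant_id, "III:3", Zygosity.HET)
            if cls == "control_shared_artifact":
                wgs.set_call(rec.variant_id, _CONTROLS_6[i % 6], Zygosity.HOM_ALT)
            elif cls == "hom_in_unaffected":
                wgs.set_call(rec.variant_id, "IV:1", Zygosity.HOM_ALT)

    genotypes = VariantTable(samples=_GENOTYPED_19)
    for rec in recs.values():
        genotypes.add_record(rec)
    for member, calls in _TEXT_GENOTYPES.items():
        for name, zyg in calls.items():
            genotypes.set_call(vids[name], member, zyg)

    return ReferenceFixture(
        wgs=wgs,
        genotypes=genotypes,
        pedigree=pedigree,
        panel=panel,
        family_samples=list(_SEQUENCED_3),
        control_samples=list(_CONTROLS_6),
        variant_ids=vids,
        decoy_classes=decoy_classes,
    )


# ---------------------------------------------------------------------------
# Seeded cohort simulator
# ---------------------------------------------------------------------------

_SIM_CLASSES = _DECOY_CLASSES + ("cis_pair",)

DEFAULT_DECOY_MIX = {
    "common_polymorphism": 0.25,
    "control_shared_artifact": 0.25,
    "hom_in_unaffected": 0.20,
    "off_panel": 0.20,
    "cis_pair": 0.10,
}

#: fixed simulated family: two unaffected parents, two affected siblings
#: carrying the planted pair in trans, one unaffected carrier sibling, and an
#: unaffected child of an affected member (the trio used for cis exclusion)
_FAMILY_SEQUENCING_ORDER = ["S1", "K1", "S2", "FA", "MO", "S3", "SP"]


@dataclass
class PlantedPair:
    gene: str
    carriers: Tuple[str, ...] = ("S1", "S2")


@dataclass
class SimulationParams:
    n_family_sequenced: int = 3
    n_controls: int = 6
    n_decoy_variants: int = 40
    decoy_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DECOY_MIX))
    planted: List[PlantedPair] = field(default_factory=lambda: [PlantedPair("G01")])
    seed: int = 0

    def __post_init__(self) -> None:
        if not (3 <= self.n_family_sequenced <= len(_FAMILY_SEQUENCING_ORDER)):
            raise ValidationError(
                f"n_family_sequenced must be in [3, {len(_FAMILY_SEQUENCING_ORDER)}]"
            )
        if self.n_controls < 1:
            raise ValidationError("n_controls must be >= 1")
        if self.n_decoy_variants < 0:
            raise ValidationError("n_decoy_variants must be >= 0")
        unknown = set(self.decoy_mix) - set(_SIM_CLASSES)
        if unknown:
            raise ValidationError(f"unknown decoy class(es): {sorted(unknown)}")
        total = sum(self.decoy_mix.values())
        if self.decoy_mix and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"decoy_mix proportions must sum to 1, got {total}")
        if not self.planted:
            raise ValidationError("at least one planted configuration is required")


@dataclass
class TruthTable:
    """Planted ground truth: per-variant and per-pair labels."""

    variant_labels: Dict[str, str] = field(default_factory=dict)  # causal | decoy:<class>
    pair_labels: Dict[Tuple[str, str], str] = field(default_factory=dict)
    removal_step: Dict[str, Optional[str]] = field(default_factory=dict)

    def variants_of_class(self, cls: str) -> List[str]:
        tag = f"decoy:{cls}"
        return sorted(v for v, lab in self.variant_labels.items() if lab == tag)

    def as_dict(self) -> dict:
        return {
            "variant_labels": dict(sorted(self.variant_labels.items())),
            "pair_labels": {f"{a}|{b}": lab for (a, b), lab in sorted(self.pair_labels.items())},
            "removal_step": dict(sorted(self.removal_step.items())),
        }


@dataclass
class SimulatedCohort:
    table: VariantTable  # sequenced family + controls (the joint "VCF")
    pedigree: Pedigree
    panel: GenePanel
    truth: TruthTable
    genotypes: VariantTable  # all 7 family members (segregation ground truth)
    family_samples: List[str] = field(default_factory=list)
    control_samples: List[str] = field(default_factory=list)


def toy_panel(n_genes: int = 12) -> GenePanel:
    """Deterministic toy panel: ``n_genes`` three-exon genes on two ~100 kb
    contigs; intergenic space past 90 kb hosts off-panel variants."""
    if not (2 <= n_genes <= 12):
        raise ValidationError("toy panel supports 2-12 genes")
    genes = []
    for i in range(n_genes):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        start = 5000 + (i // 2) * 15000
        genes.append(
            GeneModel(
                f"G{i + 1:02d}",
                chrom,
                (start, start + 9000),
                [(start, start + 900), (start + 4000, start + 4900),
                 (start + 8100, start + 9000)],
            )
        )
    return GenePanel(genes, name="toy-panel")


def _simulated_pedigree() -> Pedigree:
    A, U = Affection.AFFECTED, Affection.UNAFFECTED
    members = [
        PedigreeMember("FA", sex=Sex.MALE, affected=U),
        PedigreeMember("MO", sex=Sex.FEMALE, affected=U),
        PedigreeMember("SP", sex=Sex.MALE, affected=U),
        PedigreeMember("S1", "FA", "MO", Sex.FEMALE, A),
        PedigreeMember("S2", "FA", "MO", Sex.MALE, A),
        PedigreeMember("S3", "FA", "MO", Sex.MALE, U),
        PedigreeMember("K1", "SP", "S1", Sex.MALE, U),
    ]
    return Pedigree(members, family_id="SIM-FAM")


def _decoy_counts(params: SimulationParams) -> Dict[str, int]:
    counts = {}
    n = params.n_decoy_variants
    classes = [c for c in _SIM_CLASSES if params.decoy_mix.get(c, 0) > 0]
    acc = 0
    for cls in classes:
        counts[cls] = int(np.floor(params.decoy_mix[cls] * n))
        acc += counts[cls]
    for cls in classes[: n - acc]:
        counts[cls] += 1
    # cis pairs need an even variant count
    if counts.get("cis_pair", 0) % 2 == 1:
        counts["cis_pair"] -= 1
        counts["common_polymorphism"] = counts.get("common_polymorphism", 0) + 1
    return counts


_BASES = ("A", "C", "G", "T")


def simulate_cohort(params: Optional[SimulationParams] = None) -> SimulatedCohort:
    """Generate a family + pseudo-control cohort with planted truth.

    Founder haplotype layout (per gene block, ``A``/``B`` haplotypes):
    the paternal ``A`` haplotype carries one planted allele and every genic
    decoy; the maternal ``B`` haplotype carries the other planted allele.
    Affected siblings inherit (FA.A, MO.B) — compound heterozygous in trans;
    the unaffected sibling inherits (FA.A, MO.A); the grandchild K1 inherits
    S1's paternal haplotype plus SP.A, giving one informative meiosis per
    pair.  Homozygous-in-unaffected decoys additionally sit on SP.A so that
    K1 is homozygous; cis decoy pairs sit together on FA.A in dedicated
    genes, so K1 observes their co-transmission.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    panel = toy_panel()
    pedigree = _simulated_pedigree()
    for member_id in _FAMILY_SEQUENCING_ORDER[: params.n_family_sequenced]:
        pedigree.member(member_id).sequenced = True

    planted_genes = [p.gene for p in params.planted]
    if len(set(planted_genes)) != len(planted_genes):
        raise ValidationError("planted genes must be distinct")
    affected = set(pedigree.affected_ids)
    for p in params.planted:
        if p.gene not in panel:
            raise ValidationError(f"planted gene {p.gene} not in panel")
        for carrier in p.carriers:
            if carrier not in pedigree:
                raise ValidationError(f"planted carrier {carrier} not in pedigree")
            if carrier not in affected:
                raise ValidationError(f"planted carrier {carrier} is not affected")

    free_genes = [g for g in panel.genes if g not in planted_genes]
    if len(free_genes) < 3:
        raise ValidationError("not enough panel genes left for decoys")
    cis_genes = free_genes[-2:]
    genic_genes = free_genes[:-2]

    # per-gene bags of unused exonic positions (1-based), shuffled once
    position_bags: Dict[str, List[int]] = {}
    for gname, gene in panel.genes.items():
        positions = [p for s, e in gene.exons for p in range(s + 1, e + 1)]
        position_bags[gname] = list(rng.permutation(positions))
    used_offpanel: set = set()

    def draw_site(gene_name: Optional[str]) -> Tuple[str, int]:
        if gene_name is not None:
            bag = position_bags[gene_name]
            if not bag:
                raise ValidationError(f"gene {gene_name} exhausted of exonic positions")
            return panel.genes[gene_name].chrom, bag.pop()
        while True:
            chrom = "chr1" if rng.integers(2) == 0 else "chr2"
            pos = int(rng.integers(92000, 99000))
            if (chrom, pos) not in used_offpanel:
                used_offpanel.add((chrom, pos))
                return chrom, pos

    def draw_alleles() -> Tuple[str, str]:
        ref = _BASES[rng.integers(4)]
        alt = _BASES[rng.integers(4)]
        while alt == ref:
            alt = _BASES[rng.integers(4)]
        return ref, alt

    # haplotype content: founder hap name → set of variant ids
    haps: Dict[str, set] = {h: set() for h in ("FA.A", "FA.B", "MO.A", "MO.B", "SP.A", "SP.B")}
    controls = [f"PC{i}" for i in range(1, params.n_controls + 1)]
    control_haps: Dict[str, set] = {f"{c}.{h}": set() for c in controls for h in "AB"}

    records: Dict[str, VariantRecord] = {}
    truth = TruthTable()

    def add_record(rec: VariantRecord, label: str, removal: Optional[str]) -> str:
        if rec.variant_id in records:
            raise ValidationError(f"simulated variant collision at {rec.variant_id}")
        records[rec.variant_id] = rec
        truth.variant_labels[rec.variant_id] = label
        truth.removal_step[rec.variant_id] = removal
        return rec.variant_id

    for p in params.planted:
        chrom, pos = draw_site(p.gene)
        ref, alt = draw_alleles()
        v1 = add_record(
            VariantRecord(chrom, pos, ref, alt, gene=p.gene, maf=1e-4, hom_count=0),
            "causal", None,
        )
        chrom, pos = draw_site(p.gene)
        ref, alt = draw_alleles()
        v2 = add_record(
            VariantRecord(chrom, pos, ref, alt, gene=p.gene, hom_count=0),
            "causal", None,
        )
        haps["FA.A"].add(v1)
        haps["MO.B"].add(v2)
        truth.pair_labels[tuple(sorted((v1, v2)))] = "trans_causal"

    counts = _decoy_counts(params)
    for cls in _DECOY_CLASSES:
        for i in range(counts.get(cls, 0)):
            if cls == "off_panel":
                gene_name = None
            else:
                gene_name = genic_genes[int(rng.integers(len(genic_genes)))]
            chrom, pos = draw_site(gene_name)
            ref, alt = draw_alleles()
            maf: Optional[float] = None
            if cls == "common_polymorphism":
                maf = float(f"{rng.uniform(0.02, 0.4):.6g}")
            elif rng.uniform() < 0.5:
                maf = float(f"{rng.uniform(0, 0.005):.6g}")
            rec = VariantRecord(
                chrom, pos, ref, alt, gene=gene_name or "", maf=maf
            )
            vid = add_record(rec, f"decoy:{cls}", DECOY_REMOVAL_STEP[cls])
            haps["FA.A"].add(vid)
            if cls == "control_shared_artifact":
                ctrl = controls[i % len(controls)]
                control_haps[f"{ctrl}.A"].add(vid)
                control_haps[f"{ctrl}.B"].add(vid)
            elif cls == "hom_in_unaffected":
                haps["SP.A"].add(vid)

    n_cis_pairs = counts.get("cis_pair", 0) // 2
    for i in range(n_cis_pairs):
        gene_name = cis_genes[i % len(cis_genes)]
        pair_vids = []
        for _ in range(2):
            chrom, pos = draw_site(gene_name)
            ref, alt = draw_alleles()
            rec = VariantRecord(chrom, pos, ref, alt, gene=gene_name)
            pair_vids.append(add_record(rec, "decoy:cis_pair", None))
        haps["FA.A"].update(pair_vids)
        truth.pair_labels[tuple(sorted(pair_vids))] = "cis_decoy"

    # transmissions (uniform across gene blocks; see docstring)
    member_haps = {
        "FA": (haps["FA.A"], haps["FA.B"]),
        "MO": (haps["MO.A"], haps["MO.B"]),
        "SP": (haps["SP.A"], haps["SP.B"]),
        "S1": (haps["FA.A"], haps["MO.B"]),
        "S2": (haps["FA.A"], haps["MO.B"]),
        "S3": (haps["FA.A"], haps["MO.A"]),
        "K1": (haps["FA.A"], haps["SP.A"]),  # S1's paternal haplotype + SP.A
    }

    def zygosity(hap_pair: Tuple[set, set], vid: str) -> Zygosity:
        n = (vid in hap_pair[0]) + (vid in hap_pair[1])
        return (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[n]

    family_sequenced = _FAMILY_SEQUENCING_ORDER[: params.n_family_sequenced]
    table = VariantTable(samples=family_sequenced + controls)
    genotypes = VariantTable(samples=list(member_haps))
    for vid, rec in records.items():
        table.add_record(rec)
        genotypes.add_record(rec)
        for member, hap_pair in member_haps.items():
            zyg = zygosity(hap_pair, vid)
            genotypes.set_call(vid, member, zyg)
            if member in family_sequenced:
                table.set_call(vid, member, zyg)
        for ctrl in controls:
            pair = (control_haps[f"{ctrl}.A"], control_haps[f"{ctrl}.B"])
            table.set_call(vid, ctrl, zygosity(pair, vid))

    return SimulatedCohort(
        table=table,
        pedigree=pedigree,
        panel=panel,
        truth=truth,
        genotypes=genotypes,
        family_samples=family_sequenced,
        control_samples=controls,
    )


def mendelian_violations(table: VariantTable, pedigree: Pedigree) -> List[str]:
    """Trio-consistency check over called genotypes.

    Flags, per variant and child with both parents called: an alt allele in
    the child absent from both parents, a homozygous child with a
    non-carrier parent, and a homozygous parent with a non-carrier child.
    """
    violations = []
    for child in pedigree:
        f, m = child.father_id, child.mother_id
        if f is None or m is None:
            continue
        if child.member_id not in table.samples:
            continue
        if f not in table.samples or m not in table.samples:
            continue
        for vid in table.records:
            cz = table.call(vid, child.member_id)
            fz = table.call(vid, f)
            mz = table.call(vid, m)
            if Zygosity.MISSING in (cz, fz, mz):
                continue
            if cz.carries_alt and not (fz.carries_alt or mz.carries_alt):
                violations.append(f"{vid}: child {child.member_id} alt absent in parents")
            if cz is Zygosity.HOM_ALT and not (fz.carries_alt and mz.carries_alt):
                violations.append(f"{vid}: child {child.member_id} hom_alt needs both parents")
            if (fz is Zygosity.HOM_ALT or mz is Zygosity.HOM_ALT) and not cz.carries_alt:
                violations.append(f"{vid}: homozygous parent but child {child.member_id} ref")
    return violations


def write_cohort(cohort: SimulatedCohort, out_dir: str) -> Dict[str, str]:
    """Write VCF + PED + BED + genotype TSV + truth JSON into a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "ped": os.path.join(out_dir, "family.ped"),
        "bed": os.path.join(out_dir, "panel.bed"),
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(cohort.table, paths["vcf"])
    write_pedigree(cohort.pedigree, paths["ped"])
    write_gene_panel(cohort.panel, paths["bed"])
    write_genotype_table(cohort.genotypes, paths["genotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


__all__ = [
    "ReferenceFixture",
    "build_reference_fixture",
    "reference_panel",
    "reference_pedigree",
    "PlantedPair",
    "SimulationParams",
    "TruthTable",
    "SimulatedCohort",
    "toy_panel",
    "simulate_cohort",
    "mendelian_violations",
    "write_cohort",
    "DECOY_REMOVAL_STEP",
    "DEFAULT_DECOY_MIX",
]
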