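"""Domain types for family-based WGS variant prioritization.

The central container is :class:`VariantTable`: an ordered set of normalized
biallelic variant records together with per-sample zygosity calls.  Pedigrees
carry affection status plus two acquisition flags (``sequenced`` for WGS,
``genotyped`` for targeted Sanger typing of candidate variants), because the
filter cascade only consults sequenced members while segregation analysis
consults every genotyped member.  Gene panels store exon models in 0-based
half-open coordinates (the BED convention); VCF positions are 1-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence


class ValidationError(ValueError):
    """Raised when an input file or argument violates a structural invariant."""


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        """True if at least one alternate allele is called."""
        return self in (Zygosity.HET, Zygosity.HOM_ALT)


class ClinVarSignificance(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    CONFLICTING_PATH_VUS = "conflicting_path_vus"
    VUS = "vus"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    NOT_REPORTED = "not_reported"


#: significance levels eligible for the phenotype-driven rescue step
RESCUABLE_SIGNIFICANCE = frozenset(
    {
        ClinVarSignificance.PATHOGENIC,
        ClinVarSignificance.LIKELY_PATHOGENIC,
        ClinVarSignificance.CONFLICTING_PATH_VUS,
    }
)


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key ordering chr2 before chr10 and autosomes before X/Y/MT."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


@dataclass
class VariantRecord:
    """One normalized biallelic variant with carried annotations.

    Annotations (gene symbol, population MAF, population homozygote count,
    ClinVar status and phenotype list, per-tool predictor calls, ACMG class)
    are transported from the input VCF; the pipeline never computes them.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str = ""
    maf: Optional[float] = None
    hom_count: Optional[int] = None
    clinvar_significance: ClinVarSignificance = ClinVarSignificance.NOT_REPORTED
    clinvar_phenotypes: frozenset = frozenset()
    predictor_calls: dict = field(default_factory=dict)
    acmg_class: Optional[int] = None
    label: str = ""  # optional display label (e.g. HGVS-like), passed through

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValidationError(
                f"multiallelic alt {self.alt!r} at {self.chrom}:{self.pos}; split first"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValidationError(f"MAF out of [0,1]: {self.maf}")
        if self.hom_count is not None and self.hom_count < 0:
            raise ValidationError(f"negative homozygote count: {self.hom_count}")
        if self.acmg_class is not None and self.acmg_class not in (1, 2, 3, 4, 5):
            raise ValidationError(f"ACMG class must be 1-5, got {self.acmg_class}")
        self.clinvar_phenotypes = frozenset(self.clinvar_phenotypes)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def sort_key(self) -> tuple:
        return (natural_chrom_key(self.chrom), self.pos, self.ref, self.alt)


def parse_variant_id(variant_id: str) -> VariantRecord:
    """Reconstruct a minimal record from a ``chrom:pos:ref:alt`` key."""
    parts = variant_id.split(":")
    if len(parts) != 4:
        raise ValidationError(f"malformed variant id {variant_id!r}")
    chrom, pos, ref, alt = parts
    try:
        return VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt)
    except ValueError as exc:
        raise ValidationError(f"malformed variant id {variant_id!r}: {exc}") from exc


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("empty sample id in genotype call")


class VariantTable:
    """Ordered variant records plus a (variant_id, sample_id) → zygosity map.

    The genotype map may be sparse: any pair it does not hold resolves to
    :attr:`Zygosity.MISSING`.
    """

    def __init__(
        self,
        samples: Sequence[str],
        records: Iterable[VariantRecord] = (),
        genotypes: Optional[Mapping[tuple, Zygosity]] = None,
    ) -> None:
        self.samples: list[str] = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in table")
        self.records: dict[str, VariantRecord] = {}
        for rec in records:
            self.add_record(rec)
        self.genotypes: dict[tuple, Zygosity] = {}
        if genotypes:
            for (vid, sid), zyg in genotypes.items():
                self.set_call(vid, sid, zyg)

    def add_record(self, rec: VariantRecord) -> None:
        if rec.variant_id in self.records:
            raise ValidationError(f"duplicate variant id {rec.variant_id}")
        self.records[rec.variant_id] = rec

    def set_call(self, variant_id: str, sample_id: str, zygosity: Zygosity) -> None:
        if variant_id not in self.records:
            raise ValidationError(f"genotype for unknown variant {variant_id}")
        if sample_id not in self.samples:
            raise ValidationError(f"genotype for unknown sample {sample_id}")
        self.genotypes[(variant_id, sample_id)] = Zygosity(zygosity)

    def call(self, variant_id: str, sample_id: str) -> Zygosity:
        if variant_id not in self.records:
            raise ValidationError(f"unknown variant {variant_id}")
        if sample_id not in self.samples:
            raise ValidationError(f"unknown sample {sample_id}")
        return self.genotypes.get((variant_id, sample_id), Zygosity.MISSING)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def sorted_records(self) -> list[VariantRecord]:
        return sorted(self.records.values(), key=VariantRecord.sort_key)

    def subset(self, variant_ids: Iterable[str]) -> "VariantTable":
        """New table restricted to ``variant_ids`` (input order preserved)."""
        keep = set(variant_ids)
        out = VariantTable(self.samples)
        for vid, rec in self.records.items():
            if vid in keep:
                out.records[vid] = rec
        for (vid, sid), zyg in self.genotypes.items():
            if vid in keep:
                out.genotypes[(vid, sid)] = zyg
        return out

    def carriers(self, variant_id: str, samples: Optional[Iterable[str]] = None) -> list[str]:
        pool = self.samples if samples is None else samples
        return [s for s in pool if self.call(variant_id, s).carries_alt]

    def content_equal(self, other: "VariantTable") -> bool:
        """Equality up to record/sample ordering and sparse-vs-explicit missing."""
        if set(self.samples) != set(other.samples):
            return False
        if self.records != other.records:
            return False
        def dense(t: "VariantTable") -> dict:
            return {
                (v, s): t.call(v, s) for v in t.records for s in t.samples
            }
        return dense(self) == dense(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"VariantTable({len(self.records)} records x {len(self.samples)} samples)"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass
class PedigreeMember:
    member_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    sequenced: bool = False  # WGS performed
    genotyped: bool = True  # targeted (Sanger) typing of candidate variants

    def __post_init__(self) -> None:
        if not self.member_id:
            raise ValidationError("empty pedigree member id")
        self.sex = Sex(self.sex)
        self.affected = Affection(self.affected)


class Pedigree:
    """Family graph keyed by member id; parent links must resolve and be acyclic."""

    def __init__(self, members: Iterable[PedigreeMember], family_id: str = "FAM") -> None:
        self.family_id = family_id
        self.members: dict[str, PedigreeMember] = {}
        for m in members:
            if m.member_id in self.members:
                raise ValidationError(f"duplicate pedigree member {m.member_id}")
            self.members[m.member_id] = m
        self._validate()

    def _validate(self) -> None:
        for m in self.members.values():
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self.members:
                    raise ValidationError(
                        f"member {m.member_id} references unknown parent {pid}"
                    )
        # acyclicity: walk ancestors from each member
        for start in self.members:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                m = self.members[cur]
                for pid in (m.father_id, m.mother_id):
                    if pid is None:
                        continue
                    if pid == start:
                        raise ValidationError(f"cyclic parentage involving {start}")
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self.members

    def __iter__(self) -> Iterator[PedigreeMember]:
        return iter(self.members.values())

    def member(self, member_id: str) -> PedigreeMember:
        try:
            return self.members[member_id]
        except KeyError:
            raise ValidationError(f"unknown pedigree member {member_id}") from None

    def ids(self, **flags) -> list[str]:
        """Member ids matching keyword filters, e.g. affected=Affection.AFFECTED."""
        out = []
        for m in self.members.values():
            ok = True
            for key, want in flags.items():
                if getattr(m, key) != want:
                    ok = False
                    break
            if ok:
                out.append(m.member_id)
        return out

    @property
    def affected_ids(self) -> list[str]:
        return self.ids(affected=Affection.AFFECTED)

    @property
    def unaffected_ids(self) -> list[str]:
        return self.ids(affected=Affection.UNAFFECTED)

    @property
    def sequenced_ids(self) -> list[str]:
        return self.ids(sequenced=True)

    @property
    def genotyped_ids(self) -> list[str]:
        return self.ids(genotyped=True)

    def children_of(self, member_id: str) -> list[str]:
        return [
            m.member_id
            for m in self.members.values()
            if member_id in (m.father_id, m.mother_id)
        ]

    def couples(self) -> list[tuple]:
        """(father_id, mother_id) pairs that have at least one child, sorted."""
        seen = set()
        for m in self.members.values():
            if m.father_id is not None or m.mother_id is not None:
                seen.add((m.father_id, m.mother_id))
        return sorted(seen, key=lambda c: (c[0] or "", c[1] or ""))

    def branch_members(self, couple: tuple) -> list[str]:
        """Children of a couple plus all their descendants (the couple excluded)."""
        father, mother = couple
        frontier = [
            m.member_id
            for m in self.members.values()
            if m.father_id == father and m.mother_id == mother
        ]
        out: list[str] = []
        seen: set = set()
        while frontier:
            cur = frontier.pop(0)
            if cur in seen:
                continue
            seen.add(cur)
            out.append(cur)
            frontier.extend(self.children_of(cur))
        return out


@dataclass
class GeneModel:
    """Exon model of one gene; intervals are 0-based half-open on ``chrom``."""

    name: str
    chrom: str
    span: tuple
    exons: list

    def __post_init__(self) -> None:
        s, e = self.span
        if e <= s:
            raise ValidationError(f"gene {self.name}: span end <= start")
        merged = merge_intervals(self.exons)
        for xs, xe in merged:
            if xe <= xs:
                raise ValidationError(f"gene {self.name}: exon end <= start")
            if xs < s or xe > e:
                raise ValidationError(f"gene {self.name}: exon outside span")
        self.exons = merged

    def contains(self, pos: int) -> bool:
        """True if a 1-based position lies inside the gene span."""
        return self.span[0] < pos <= self.span[1]

    def in_exon(self, pos: int) -> bool:
        return any(s < pos <= e for s, e in self.exons)


def merge_intervals(intervals: Iterable[tuple]) -> list:
    """Union of 0-based half-open intervals, sorted; adjacent runs merge."""
    ivs = sorted(intervals)
    out: list = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class GenePanel:
    """Disease gene panel: symbol → exon model, used by the gene filter and
    by region classification (exonic / near-splice / deep-intronic)."""

    def __init__(self, genes: Iterable[GeneModel], name: str = "panel") -> None:
        self.name = name
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.name in self.genes:
                raise ValidationError(f"duplicate gene {g.name} in panel")
            self.genes[g.name] = g
        if not self.genes:
            raise ValidationError("empty gene panel")
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        """Panel genes whose span contains the 1-based position."""
        return [g for g in self.genes_on(chrom) if g.contains(pos)]


@dataclass(frozen=True)
class SpliceScorePair:
    """Wild-type vs mutant score from one splice predictor for one variant."""

    variant_id: str
    tool: str
    wt_score: float
    mut_score: float

    VALID_TOOLS = ("maxent", "hsf", "nnsplice")

    def __post_init__(self) -> None:
        if self.tool not in self.VALID_TOOLS:
            raise ValidationError(
                f"unknown splice tool {self.tool!r}; expected one of {self.VALID_TOOLS}"
            )


__all__ = [
    "ValidationError",
    "Zygosity",
    "ClinVarSignificance",
    "RESCUABLE_SIGNIFICANCE",
    "VariantRecord",
    "parse_variant_id",
    "GenotypeCall",
    "VariantTable",
    "Sex",
    "Affection",
    "PedigreeMember",
    "Pedigree",
    "GeneModel",
    "GenePanel",
    "SpliceScorePair",
    "merge_intervals",
    "natural_chrom_key",
]
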