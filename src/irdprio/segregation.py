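"""Compound-heterozygote pairing, trio-based phase inference and pedigree
segregation verdicts.

Only *trans* pairs (one allele per parental haplotype) can explain recessive
disease, so candidate pairs within a gene are phased from informative
meioses: a parent heterozygous for both alleles transmitting both to a child
implies *cis* (the pair is then excluded from causal reporting), transmitting
exactly one implies *trans*.  A child carrying neither allele is recorded as
uninformative — that observation is equally consistent with transmission of
the variant-free haplotype of a cis carrier, and a single genotype cannot
distinguish the two.  When the double heterozygote's parents are typed and
exactly one of them carries exactly one allele of the pair, the alleles have
different parental origins and the pair is *trans* (rare-allele assumption:
an allele seen in one parent is not independently carried by the other).
Conflicting meioses leave the phase unknown with a logged conflict.

Segregation verdicts evaluate a genotype configuration (a variant pair, or a
single doubled allele for homozygotes) over the genotyped members of a
pedigree scope: ``segregates`` when every typed affected member carries the
full configuration and no typed unaffected member does; ``partial`` when an
unaffected member shares the full configuration; ``excluded`` when an
affected member lacks it (or nobody carries it).  Unaffected single-allele
carriers are consistent — the model is recessive.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .model import (
    Affection,
    Pedigree,
    ValidationError,
    VariantTable,
    Zygosity,
)

log = logging.getLogger(__name__)


@dataclass
class BiallelicPair:
    """Two candidate alleles of one gene carried by an affected member.

    ``variant_a == variant_b`` encodes a homozygous configuration, which is
    trivially trans (one copy per homologous chromosome).
    """

    gene: str
    variant_a: str
    variant_b: str
    phase: str = "unknown"  # trans | cis | unknown
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.phase not in ("trans", "cis", "unknown"):
            raise ValidationError(f"bad phase {self.phase!r}")
        a, b = sorted((self.variant_a, self.variant_b))
        self.variant_a, self.variant_b = a, b

    @property
    def is_homozygous(self) -> bool:
        return self.variant_a == self.variant_b

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.gene, self.variant_a, self.variant_b)

    def configuration(self) -> Tuple[str, ...]:
        return (self.variant_a, self.variant_b)


@dataclass
class SegregationResult:
    configuration: Tuple[str, ...]
    per_member: Dict[str, str] = field(default_factory=dict)  # consistent|inconsistent|untyped
    verdict: str = "excluded"  # segregates | partial | excluded


def _carries(table: VariantTable, sample: str, vid: str) -> Optional[bool]:
    """True/False carrier status, or None when the call is missing."""
    if sample not in table.samples:
        return None
    zyg = table.call(vid, sample)
    if zyg is Zygosity.MISSING:
        return None
    return zyg.carries_alt


def enumerate_pairs(
    candidates: Iterable,
    table: VariantTable,
    pedigree: Pedigree,
) -> List[BiallelicPair]:
    """All within-gene candidate pairs supported by an affected carrier.

    An unordered pair (a, b) is emitted when at least one affected member is
    heterozygous for both alleles; a self-pair (a, a) is emitted when an
    affected member is homozygous for the alternate allele.
    """
    by_gene: Dict[str, list] = {}
    for cand in candidates:
        gene = cand.record.gene or "?"
        by_gene.setdefault(gene, []).append(cand)
    affected = [m for m in pedigree.affected_ids if m in table.samples]
    pairs: List[BiallelicPair] = []
    seen = set()
    for gene, cands in by_gene.items():
        for cand in cands:
            vid = cand.variant_id
            if any(table.call(vid, m) is Zygosity.HOM_ALT for m in affected):
                pair = BiallelicPair(gene, vid, vid, phase="trans", evidence="homozygous carrier")
                if pair.key not in seen:
                    seen.add(pair.key)
                    pairs.append(pair)
        for ca, cb in itertools.combinations(cands, 2):
            a, b = ca.variant_id, cb.variant_id
            both_het = [
                m
                for m in affected
                if table.call(a, m) is Zygosity.HET and table.call(b, m) is Zygosity.HET
            ]
            if both_het:
                pair = BiallelicPair(gene, a, b)
                if pair.key not in seen:
                    seen.add(pair.key)
                    pairs.append(pair)
    pairs.sort(key=lambda p: p.key)
    return pairs


def _meiosis_evidence(
    pair: BiallelicPair, table: VariantTable, pedigree: Pedigree
) -> List[Tuple[str, str]]:
    """Collect (verdict, description) phase observations from the pedigree."""
    a, b = pair.variant_a, pair.variant_b
    observations: List[Tuple[str, str]] = []
    double_hets = [
        m.member_id
        for m in pedigree
        if m.member_id in table.samples
        and table.call(a, m.member_id) is Zygosity.HET
        and table.call(b, m.member_id) is Zygosity.HET
    ]
    for carrier in double_hets:
        # transmissions to genotyped children
        for child in pedigree.children_of(carrier):
            child_a = _carries(table, child, a)
            child_b = _carries(table, child, b)
            if child_a is None or child_b is None:
                continue
            cm = pedigree.member(child)
            other_parent = cm.father_id if cm.mother_id == carrier else cm.mother_id
            if other_parent is not None and (
                _carries(table, other_parent, a) or _carries(table, other_parent, b)
            ):
                continue  # the other parent could have contributed; uninformative
            if child_a and child_b:
                observations.append(("cis", f"child {child} of {carrier} carries both"))
            elif child_a != child_b:
                observations.append(
                    ("trans", f"child {child} of {carrier} carries exactly one")
                )
            # carries neither: cis-or-untransmitted, uninformative on its own
        # parental origin of the carrier's two alleles
        member = pedigree.member(carrier)
        for parent_id in (member.father_id, member.mother_id):
            if parent_id is None:
                continue
            pa = _carries(table, parent_id, a)
            pb = _carries(table, parent_id, b)
            if pa is None or pb is None:
                continue
            if pa and pb:
                continue  # double-het parent handled as its own meiosis
            if pa != pb:
                carried = a if pa else b
                other_id = member.mother_id if parent_id == member.father_id else member.father_id
                if other_id is not None and _carries(table, other_id, carried):
                    continue  # both parents carry it; origin ambiguous
                observations.append(
                    ("trans", f"parent {parent_id} of {carrier} carries exactly one")
                )
    return observations


def infer_phase(
    pair: BiallelicPair, table: VariantTable, pedigree: Pedigree
) -> BiallelicPair:
    """Return the pair with its phase set from pedigree transmission evidence."""
    if pair.is_homozygous:
        pair.phase = "trans"
        pair.evidence = pair.evidence or "homozygous configuration"
        return pair
    observations = _meiosis_evidence(pair, table, pedigree)
    verdicts = {v for v, _ in observations}
    if "cis" in verdicts and "trans" in verdicts:
        pair.phase = "unknown"
        pair.evidence = "conflicting meioses (possible genotyping error): " + "; ".join(
            d for _, d in observations
        )
        log.warning("phase conflict for %s/%s: %s", pair.variant_a, pair.variant_b, pair.evidence)
    elif "trans" in verdicts:
        pair.phase = "trans"
        pair.evidence = "; ".join(d for v, d in observations if v == "trans")
    elif "cis" in verdicts:
        pair.phase = "cis"
        pair.evidence = "; ".join(d for v, d in observations if v == "cis")
    else:
        pair.phase = "unknown"
        pair.evidence = "no informative meiosis"
    return pair


def _carries_configuration(
    table: VariantTable, member: str, configuration: Tuple[str, ...]
) -> Optional[bool]:
    """Full-configuration carrier status; None when any call is missing."""
    counts: Dict[str, int] = {}
    for vid in configuration:
        counts[vid] = counts.get(vid, 0) + 1
    verdict = True
    for vid, need in counts.items():
        if vid not in table.records:
            raise ValidationError(f"configuration variant {vid} absent from genotype table")
        if member not in table.samples:
            return None
        zyg = table.call(vid, member)
        if zyg is Zygosity.MISSING:
            return None
        if need >= 2:
            verdict = verdict and zyg is Zygosity.HOM_ALT
        else:
            verdict = verdict and zyg.carries_alt
    return verdict


def segregate(
    configuration: Iterable[str],
    genotype_table: VariantTable,
    pedigree: Pedigree,
    members: Optional[Iterable[str]] = None,
) -> SegregationResult:
    """Per-member concordance and a verdict for a genotype configuration.

    ``members`` restricts the scope (e.g. one family branch); it defaults to
    every genotyped pedigree member.  Members with a missing call at any
    configuration variant are ``untyped`` and excluded from the verdict.
    """
    config = tuple(configuration)
    if not config:
        raise ValidationError("empty configuration")
    scope = list(members) if members is not None else pedigree.genotyped_ids
    result = SegregationResult(configuration=config)
    affected_consistent = []
    affected_inconsistent = []
    unaffected_carrying = []
    for member_id in scope:
        m = pedigree.member(member_id)
        carrying = _carries_configuration(genotype_table, member_id, config)
        if carrying is None or m.affected is Affection.UNKNOWN:
            result.per_member[member_id] = "untyped"
            continue
        if m.affected is Affection.AFFECTED:
            if carrying:
                result.per_member[member_id] = "consistent"
                affected_consistent.append(member_id)
            else:
                result.per_member[member_id] = "inconsistent"
                affected_inconsistent.append(member_id)
        else:
            if carrying:
                result.per_member[member_id] = "inconsistent"
                unaffected_carrying.append(member_id)
            else:
                result.per_member[member_id] = "consistent"
    if affected_inconsistent or not affected_consistent:
        result.verdict = "excluded"
    elif unaffected_carrying:
        result.verdict = "partial"
    else:
        result.verdict = "segregates"
    return result


def family_report(
    pairs: Iterable[BiallelicPair],
    candidates: Iterable,
    genotype_table: VariantTable,
    pedigree: Pedigree,
) -> dict:
    """Assemble the per-branch and per-member clinical summary.

    Cis pairs are excluded from causal consideration.  For every remaining
    pair, segregation is evaluated family-wide and within each branch (the
    children of one parent couple plus their descendants).  Per member, the
    report lists carried candidate alleles across all genes and raises an
    oligogenic flag when an affected member carries candidate alleles in two
    or more genes.
    """
    candidates = list(candidates)
    pairs = list(pairs)
    branch_defs = {}
    for couple in pedigree.couples():
        label = f"{couple[0] or '?'}+{couple[1] or '?'}"
        branch_defs[label] = pedigree.branch_members(couple)
    pair_entries = []
    noncis_supported_vids = set()
    for pair in pairs:
        entry = {
            "gene": pair.gene,
            "variant_a": pair.variant_a,
            "variant_b": pair.variant_b,
            "phase": pair.phase,
            "evidence": pair.evidence,
            "excluded_cis": pair.phase == "cis",
        }
        if pair.phase == "cis":
            entry["family_verdict"] = "excluded"
            entry["branch_verdicts"] = {}
            entry["supporting_affected"] = []
        else:
            family_res = segregate(pair.configuration(), genotype_table, pedigree)
            branch_verdicts = {}
            for label, branch in branch_defs.items():
                scoped = [m for m in branch if pedigree.member(m).genotyped]
                if not scoped:
                    continue
                res = segregate(pair.configuration(), genotype_table, pedigree, members=scoped)
                if any(v != "untyped" for v in res.per_member.values()):
                    branch_verdicts[label] = res.verdict
            supporting = [
                m
                for m in pedigree.affected_ids
                if _carries_configuration(genotype_table, m, pair.configuration())
            ]
            entry["family_verdict"] = family_res.verdict
            entry["branch_verdicts"] = branch_verdicts
            entry["supporting_affected"] = supporting
            if supporting:
                noncis_supported_vids.update(pair.configuration())
        pair_entries.append(entry)
    members_out = {}
    gene_of = {c.variant_id: (c.record.gene or "?") for c in candidates}
    # clinically relevant alleles: members of a non-excluded pair, plus lone
    # candidates in genes without any pair; variants whose only pairing is
    # cis-excluded are not reported as relevant
    genes_with_pairs = {p.gene for p in pairs}
    relevant_vids = [
        vid
        for c in candidates
        for vid in [c.variant_id]
        if vid in noncis_supported_vids or gene_of[vid] not in genes_with_pairs
    ]
    for member_id in pedigree.genotyped_ids:
        alleles = [
            vid
            for vid in relevant_vids
            if member_id in genotype_table.samples
            and genotype_table.call(vid, member_id).carries_alt
        ]
        genes = sorted({gene_of[v] for v in alleles})
        m = pedigree.member(member_id)
        members_out[member_id] = {
            "alleles": alleles,
            "genes": genes,
            "affected": m.affected.value,
            "oligogenic_flag": m.affected is Affection.AFFECTED and len(genes) >= 2,
        }
    return {
        "family_id": pedigree.family_id,
        "pairs": pair_entries,
        "members": members_out,
        "clinically_relevant_variants": sorted(noncis_supported_vids),
    }


__all__ = [
    "BiallelicPair",
    "SegregationResult",
    "enumerate_pairs",
    "infer_phase",
    "segregate",
    "family_report",
]
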