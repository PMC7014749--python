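"""Candidate assembly after the filter cascade.

Surviving variants are classified against the panel's exon models:

* ``coding_exonic`` — position inside an exon,
* ``near_splice``  — within ``flank_bp`` (default ±10 bp, inclusive) of an
  exon boundary but outside the exon,
* ``deep_intronic`` — inside the gene span but farther than the flank from
  every exon,
* ``other``        — outside every panel gene span.

Exonic and near-splice variants form tier 1.  Deep-intronic variants are
admitted to tier 2 only on splice-prediction evidence: a per-tool wild-type /
mutant score pair passes when the stronger of the two site scores reaches the
tool's floor (MaxEnt 2, HSF 70, NNSPLICE 0.4) and the relative score change
exceeds the tool's minimum variation (15% / 10% / 10%); a quorum of passing
tools (default 2 of 3) admits the variant.  Population-homozygote flags are
attached so that the "0 Hom" check is visible per candidate; pathogenicity
predictor calls and ACMG classes are carried through but never filter.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import pandas as pd

from .filters import FilterConfig
from .model import (
    GenePanel,
    SpliceScorePair,
    ValidationError,
    VariantRecord,
    VariantTable,
)

log = logging.getLogger(__name__)

_EPS = 1e-9


class RegionClass(str, enum.Enum):
    CODING_EXONIC = "coding_exonic"
    NEAR_SPLICE = "near_splice"
    DEEP_INTRONIC = "deep_intronic"
    OTHER = "other"


@dataclass
class CandidateVariant:
    record: VariantRecord
    region: RegionClass
    splice_verdicts: Dict[str, bool] = field(default_factory=dict)
    hom_flag: bool = False  # population homozygotes exist (needs manual review)
    tier: int = 1

    def __post_init__(self) -> None:
        if self.tier == 2:
            if self.region is not RegionClass.DEEP_INTRONIC:
                raise ValidationError("tier 2 requires a deep-intronic region class")
            if not any(self.splice_verdicts.values()):
                raise ValidationError("tier 2 requires >= 1 passing splice verdict")

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


def classify_region(record: VariantRecord, panel: GenePanel, flank_bp: int = 10) -> RegionClass:
    """Four-way region class of a variant position against the panel exon models.

    Distances are measured in 1-based coordinates from the closest exonic
    base; a position exactly ``flank_bp`` away is still ``near_splice``
    (the flank bound is inclusive).
    """
    pos = record.pos
    genes = panel.genes_on(record.chrom)
    in_span = False
    min_dist: Optional[int] = None
    for gene in genes:
        for xs, xe in gene.exons:
            first, last = xs + 1, xe  # 1-based inclusive exon bounds
            if first <= pos <= last:
                return RegionClass.CODING_EXONIC
            dist = first - pos if pos < first else pos - last
            if min_dist is None or dist < min_dist:
                min_dist = dist
        if gene.contains(pos):
            in_span = True
    if min_dist is not None and min_dist <= flank_bp:
        return RegionClass.NEAR_SPLICE
    if in_span:
        return RegionClass.DEEP_INTRONIC
    return RegionClass.OTHER


def splice_impact(pair: SpliceScorePair, config: Optional[FilterConfig] = None) -> bool:
    """Does one predictor's wild-type/mutant score pair indicate splice impact?

    Pass requires ``max(|wt|, |mut|) >= min_score`` (so both site-loss and
    site-gain events qualify) and a relative score change
    ``|wt - mut| / max(|wt|, eps) * 100`` strictly above the tool's minimum
    variation percentage.
    """
    config = config or FilterConfig()
    thresholds = config.splice_thresholds.get(pair.tool)
    if thresholds is None:
        raise ValidationError(f"no thresholds configured for splice tool {pair.tool!r}")
    wt, mut = abs(pair.wt_score), abs(pair.mut_score)
    if max(wt, mut) < thresholds["min_score"]:
        return False
    variation_pct = abs(pair.wt_score - pair.mut_score) / max(wt, _EPS) * 100.0
    return variation_pct > thresholds["min_variation_pct"]


def assemble_candidates(
    table: VariantTable,
    panel: GenePanel,
    scores: Iterable[SpliceScorePair] = (),
    config: Optional[FilterConfig] = None,
    exclusions: Optional[Dict[str, str]] = None,
) -> list:
    """Rank cascade survivors into tiered candidates.

    Tier 1 collects exonic and near-splice variants; tier 2 collects
    deep-intronic variants meeting the splice-predictor quorum.  Everything
    else is dropped with a reason (collected into ``exclusions`` when a dict
    is supplied, and logged).  Output is sorted by (tier, gene, position).
    """
    config = config or FilterConfig()
    by_variant: Dict[str, Dict[str, bool]] = {}
    for pair in scores:
        by_variant.setdefault(pair.variant_id, {})[pair.tool] = splice_impact(pair, config)
    candidates = []
    for vid, rec in table.records.items():
        region = classify_region(rec, panel, config.flank_bp)
        verdicts = by_variant.get(vid, {})
        hom_flag = bool(rec.hom_count and rec.hom_count > 0)
        if region in (RegionClass.CODING_EXONIC, RegionClass.NEAR_SPLICE):
            candidates.append(
                CandidateVariant(rec, region, verdicts, hom_flag=hom_flag, tier=1)
            )
        elif region is RegionClass.DEEP_INTRONIC:
            n_pass = sum(1 for ok in verdicts.values() if ok)
            if verdicts and n_pass >= config.splice_quorum:
                candidates.append(
                    CandidateVariant(rec, region, verdicts, hom_flag=hom_flag, tier=2)
                )
            else:
                reason = "splice quorum" if verdicts else "no splice scores"
                if exclusions is not None:
                    exclusions[vid] = reason
                log.info("dropping deep-intronic %s: %s", vid, reason)
        else:
            if exclusions is not None:
                exclusions[vid] = "outside gene regions"
            log.info("dropping %s: outside gene regions", vid)
    candidates.sort(
        key=lambda c: (c.tier, c.record.gene, c.record.sort_key())
    )
    return candidates


def candidates_frame(candidates: Iterable[CandidateVariant]) -> pd.DataFrame:
    """Tabular candidate report mirroring a clinical summary table."""
    rows = []
    for c in candidates:
        r = c.record
        rows.append(
            {
                "gene": r.gene,
                "variant_id": r.variant_id,
                "label": r.label,
                "maf": r.maf,
                "hom_count": r.hom_count,
                "hom_flag": c.hom_flag,
                "clinvar": r.clinvar_significance.value,
                "sift": r.predictor_calls.get("sift", ""),
                "polyphen2": r.predictor_calls.get("polyphen2", ""),
                "mutationtaster": r.predictor_calls.get("mutationtaster", ""),
                "acmg_class": r.acmg_class,
                "region": c.region.value,
                "tier": c.tier,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "variant_id", "label", "maf", "hom_count", "hom_flag",
            "clinvar", "sift", "polyphen2", "mutationtaster", "acmg_class",
            "region", "tier",
        ],
    )


def write_candidates(candidates: Iterable[CandidateVariant], path: str) -> None:
    candidates_frame(candidates).to_csv(path, sep="\t", index=False)


__all__ = [
    "RegionClass",
    "CandidateVariant",
    "classify_region",
    "splice_impact",
    "assemble_candidates",
    "candidates_frame",
    "write_candidates",
]
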