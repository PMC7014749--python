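"""The variant filter cascade for family WGS data.

Order of operations, mirroring the optimized tertiary-analysis algorithm:

1. **ClinVar rescue** — before any destructive filter, collect variants whose
   clinical significance is pathogenic / likely pathogenic / conflicting
   (pathogenic vs VUS) *and* whose ClinVar phenotype list matches the disease
   terms.  Rescued ids are exempt from the recurrence and frequency steps
   (but not from the gene and pedigree steps).
2. **Recurrence filter** — keep variants exclusive of the family under study:
   carried by at least one family sample, carried by at most
   ``max_control_carriers`` pseudo-control samples (default 0), and never
   homozygous in a pseudo-control.
3. **Frequency filter** — discard variants with population MAF above
   ``maf_threshold`` (default 0.01); variants with no frequency entry pass by
   default (novel alleles must survive).
4. **Gene filter** — keep variants inside a panel gene span (introns
   included, regardless of distance from splice sites) or annotated with a
   panel gene symbol.
5. **Pedigree filter** — keep variants carried (het or hom) by at least one
   sequenced affected member and not homozygous in any sequenced unaffected
   member.

Every step is a pure contraction on the table and reports a
:class:`FilterTrace` with input/output counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Set

import yaml

from .model import (
    Affection,
    GenePanel,
    Pedigree,
    RESCUABLE_SIGNIFICANCE,
    ValidationError,
    VariantTable,
    Zygosity,
)

#: disease phenotype terms matched (case-insensitive substring) against the
#: ClinVar phenotype list during the rescue step
DEFAULT_PHENOTYPE_TERMS = frozenset(
    {"retinitis pigmentosa", "retinal dystrophy", "usher syndrome"}
)

#: per-tool splice thresholds: minimum site score and minimum percent change
DEFAULT_SPLICE_THRESHOLDS = {
    "maxent": {"min_score": 2.0, "min_variation_pct": 15.0},
    "hsf": {"min_score": 70.0, "min_variation_pct": 10.0},
    "nnsplice": {"min_score": 0.4, "min_variation_pct": 10.0},
}


@dataclass
class FilterConfig:
    """Tunable thresholds of the cascade and of splice-impact assessment."""

    maf_threshold: float = 0.01
    flank_bp: int = 10
    phenotype_terms: frozenset = DEFAULT_PHENOTYPE_TERMS
    splice_thresholds: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SPLICE_THRESHOLDS.items()}
    )
    treat_missing_maf_as_pass: bool = True
    max_control_carriers: int = 0
    splice_quorum: int = 2  # predictors that must pass to admit a deep-intronic variant
    missing_as_ref: bool = False  # combine-time default for absent union calls

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValidationError("maf_threshold must be in (0, 1]")
        if self.flank_bp < 0:
            raise ValidationError("flank_bp must be >= 0")
        if self.max_control_carriers < 0:
            raise ValidationError("max_control_carriers must be >= 0")
        for tool, thr in self.splice_thresholds.items():
            if thr["min_score"] < 0 or thr["min_variation_pct"] < 0:
                raise ValidationError(f"negative splice threshold for {tool}")
        self.phenotype_terms = frozenset(t.lower() for t in self.phenotype_terms)

    @classmethod
    def from_yaml(cls, path: str) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a mapping")
        kwargs = {}
        for key in (
            "maf_threshold",
            "flank_bp",
            "treat_missing_maf_as_pass",
            "max_control_carriers",
            "splice_quorum",
            "missing_as_ref",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "phenotype_terms" in raw:
            kwargs["phenotype_terms"] = frozenset(raw["phenotype_terms"])
        if "splice_thresholds" in raw:
            merged = {k: dict(v) for k, v in DEFAULT_SPLICE_THRESHOLDS.items()}
            for tool, thr in raw["splice_thresholds"].items():
                if tool not in merged:
                    raise ValidationError(f"unknown splice tool {tool!r} in config")
                merged[tool].update(thr)
            kwargs["splice_thresholds"] = merged
        return cls(**kwargs)


@dataclass
class FilterTrace:
    """Per-step audit record: counts in/out and the ids the step removed."""

    step_name: str
    n_in: int
    n_out: int
    rescued_ids: Set[str] = field(default_factory=set)
    removed_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.n_out <= self.n_in):
            raise ValidationError(
                f"trace {self.step_name}: n_out {self.n_out} outside [0, {self.n_in}]"
            )

    def as_dict(self) -> dict:
        return {
            "step": self.step_name,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "rescued_ids": sorted(self.rescued_ids),
            "removed_ids": sorted(self.removed_ids),
        }


def clinvar_rescue(table: VariantTable, config: FilterConfig) -> Set[str]:
    """Ids of variants with a rescuable ClinVar status and a matching phenotype.

    Both clauses must hold: significance in {pathogenic, likely pathogenic,
    conflicting pathogenic/VUS} and at least one ClinVar phenotype containing
    one of the configured disease terms (case-insensitive substring).
    """
    rescued: Set[str] = set()
    for vid, rec in table.records.items():
        if rec.clinvar_significance not in RESCUABLE_SIGNIFICANCE:
            continue
        phenotypes = [p.lower() for p in rec.clinvar_phenotypes]
        if any(term in phen for term in config.phenotype_terms for phen in phenotypes):
            rescued.add(vid)
    return rescued


def _check_samples(table: VariantTable, samples: Iterable[str], what: str) -> list:
    out = list(samples)
    unknown = [s for s in out if s not in table.samples]
    if unknown:
        raise ValidationError(f"unknown {what} sample id(s): {', '.join(unknown)}")
    return out


def recurrence_filter(
    table: VariantTable,
    family_samples: Iterable[str],
    control_samples: Iterable[str],
    rescued: Optional[Set[str]] = None,
    max_control_carriers: int = 0,
) -> VariantTable:
    """Keep variants exclusive of the family and never homozygous in controls."""
    rescued = rescued or set()
    family = _check_samples(table, family_samples, "family")
    controls = _check_samples(table, control_samples, "control")
    if set(family) & set(controls):
        raise ValidationError("family and control sample sets overlap")
    keep = []
    for vid in table.records:
        if vid in rescued:
            keep.append(vid)
            continue
        control_calls = [table.call(vid, s) for s in controls]
        if any(c is Zygosity.HOM_ALT for c in control_calls):
            continue
        if sum(1 for c in control_calls if c.carries_alt) > max_control_carriers:
            continue
        if not any(table.call(vid, s).carries_alt for s in family):
            continue
        keep.append(vid)
    return table.subset(keep)


def frequency_filter(
    table: VariantTable, config: FilterConfig, rescued: Optional[Set[str]] = None
) -> VariantTable:
    """Discard variants with population MAF above the threshold."""
    rescued = rescued or set()
    keep = []
    for vid, rec in table.records.items():
        if vid in rescued:
            keep.append(vid)
        elif rec.maf is None:
            if config.treat_missing_maf_as_pass:
                keep.append(vid)
        elif rec.maf <= config.maf_threshold:
            keep.append(vid)
    return table.subset(keep)


def gene_filter(table: VariantTable, panel: GenePanel) -> VariantTable:
    """Keep variants inside a panel gene span or annotated with a panel gene.

    The whole gene body counts: intronic positions pass regardless of their
    distance from splice sites (deep-intronic candidates are triaged later).
    """
    keep = []
    for vid, rec in table.records.items():
        if rec.gene and rec.gene in panel:
            keep.append(vid)
        elif panel.genes_at(rec.chrom, rec.pos):
            keep.append(vid)
    return table.subset(keep)


def pedigree_filter(
    table: VariantTable,
    pedigree: Pedigree,
    samples: Optional[Iterable[str]] = None,
) -> VariantTable:
    """Keep variants carried by a sequenced affected member and not homozygous
    in any sequenced unaffected member.

    ``samples`` restricts the calls consulted (the cascade passes the family
    samples so that pseudo-control columns are ignored); it defaults to every
    table sample that is a sequenced pedigree member.
    """
    pool = list(samples) if samples is not None else list(table.samples)
    pool = _check_samples(table, pool, "pedigree")
    affected = [
        s for s in pool
        if s in pedigree and pedigree.member(s).sequenced
        and pedigree.member(s).affected is Affection.AFFECTED
    ]
    unaffected = [
        s for s in pool
        if s in pedigree and pedigree.member(s).sequenced
        and pedigree.member(s).affected is Affection.UNAFFECTED
    ]
    if not affected:
        raise ValidationError("pedigree filter requires >= 1 sequenced affected member")
    keep = []
    for vid in table.records:
        if not any(table.call(vid, s).carries_alt for s in affected):
            continue
        if any(table.call(vid, s) is Zygosity.HOM_ALT for s in unaffected):
            continue
        keep.append(vid)
    return table.subset(keep)


def run_cascade(
    table: VariantTable,
    pedigree: Pedigree,
    panel: GenePanel,
    family_samples: Iterable[str],
    control_samples: Iterable[str],
    config: Optional[FilterConfig] = None,
) -> tuple:
    """Apply rescue → recurrence → frequency → gene → pedigree in order.

    Returns ``(filtered_table, traces)`` where ``traces`` holds one
    :class:`FilterTrace` per step (the rescue step is a non-contracting
    bookkeeping entry recording which ids gained exemption).
    """
    config = config or FilterConfig()
    family = list(family_samples)
    controls = list(control_samples)
    rescued = clinvar_rescue(table, config)
    traces = [
        FilterTrace(
            step_name="clinvar_rescue",
            n_in=table.n_records,
            n_out=table.n_records,
            rescued_ids=set(rescued),
        )
    ]
    current = table

    def step(name, result, rescue_aware):
        nonlocal current
        removed = set(current.records) - set(result.records)
        traces.append(
            FilterTrace(
                step_name=name,
                n_in=current.n_records,
                n_out=result.n_records,
                rescued_ids=rescued & set(result.records) if rescue_aware else set(),
                removed_ids=removed,
            )
        )
        current = result

    step(
        "recurrence",
        recurrence_filter(
            current, family, controls, rescued, config.max_control_carriers
        ),
        True,
    )
    step("frequency", frequency_filter(current, config, rescued), True)
    step("gene_panel", gene_filter(current, panel), False)
    step("pedigree", pedigree_filter(current, pedigree, samples=family), False)
    return current, traces


__all__ = [
    "FilterConfig",
    "FilterTrace",
    "DEFAULT_PHENOTYPE_TERMS",
    "DEFAULT_SPLICE_THRESHOLDS",
    "clinvar_rescue",
    "recurrence_filter",
    "frequency_filter",
    "gene_filter",
    "pedigree_filter",
    "run_cascade",
]
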