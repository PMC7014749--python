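"""Independent oracles and random-input builders for the test suite.

The brute-force cascade oracle evaluates the keep/remove decision for every
record as one conjunctive predicate written directly from the filtering
rules, independently of the pipeline's step-wise implementation.
"""

from __future__ import annotations

import numpy as np

from irdprio.model import (
    Affection,
    ClinVarSignificance,
    GeneModel,
    GenePanel,
    Pedigree,
    PedigreeMember,
    RESCUABLE_SIGNIFICANCE,
    VariantRecord,
    VariantTable,
    Zygosity,
)


def brute_force_cascade(table, pedigree, panel, family, controls, config):
    """Set of variant ids the cascade must keep, per direct predicate."""
    kept = set()
    affected = [
        s for s in family
        if s in pedigree
        and pedigree.member(s).sequenced
        and pedigree.member(s).affected is Affection.AFFECTED
    ]
    unaffected = [
        s for s in family
        if s in pedigree
        and pedigree.member(s).sequenced
        and pedigree.member(s).affected is Affection.UNAFFECTED
    ]
    for vid, rec in table.records.items():
        rescued = rec.clinvar_significance in RESCUABLE_SIGNIFICANCE and any(
            term in phen.lower()
            for term in config.phenotype_terms
            for phen in rec.clinvar_phenotypes
        )
        control_calls = [table.call(vid, s) for s in controls]
        recurrence_ok = (
            not any(c is Zygosity.HOM_ALT for c in control_calls)
            and sum(c.carries_alt for c in control_calls) <= config.max_control_carriers
            and any(table.call(vid, s).carries_alt for s in family)
        )
        if rec.maf is None:
            frequency_ok = config.treat_missing_maf_as_pass
        else:
            frequency_ok = rec.maf <= config.maf_threshold
        gene_ok = (rec.gene and rec.gene in panel.genes) or any(
            g.contains(rec.pos) for g in panel.genes_on(rec.chrom)
        )
        pedigree_ok = any(
            table.call(vid, s).carries_alt for s in affected
        ) and not any(table.call(vid, s) is Zygosity.HOM_ALT for s in unaffected)
        if (rescued or (recurrence_ok and frequency_ok)) and gene_ok and pedigree_ok:
            kept.add(vid)
    return kept


def brute_force_region(pos, gene_span, exons, flank_bp):
    """Region class of a 1-based position by exhaustive distance scan."""
    for s, e in exons:
        if s + 1 <= pos <= e:
            return "coding_exonic"
    dists = []
    for s, e in exons:
        first, last = s + 1, e
        dists.append(first - pos if pos < first else pos - last)
    if dists and min(dists) <= flank_bp:
        return "near_splice"
    if gene_span[0] < pos <= gene_span[1]:
        return "deep_intronic"
    return "other"


def small_pedigree():
    """Trio-plus-sib family: one sequenced affected, one sequenced unaffected."""
    A, U = Affection.AFFECTED, Affection.UNAFFECTED
    return Pedigree(
        [
            PedigreeMember("F1", affected=A, sequenced=True),
            PedigreeMember("F2", affected=U, sequenced=True),
            PedigreeMember("F3", affected=A, sequenced=False),
        ],
        family_id="T",
    )


def small_panel():
    return GenePanel(
        [
            GeneModel("GA", "chr1", (100, 1000), [(100, 300), (700, 1000)]),
            GeneModel("GB", "chr2", (500, 2000), [(500, 800), (1500, 2000)]),
        ]
    )


_SIGNIFICANCES = list(ClinVarSignificance)


def random_table(seed, n_records=30, family=("F1", "F2"), controls=("C1", "C2", "C3")):
    """Random annotated table over the small panel's chromosomes."""
    rng = np.random.default_rng(seed)
    samples = list(family) + list(controls)
    table = VariantTable(samples=samples)
    zygs = [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT, Zygosity.MISSING]
    genes = ["GA", "GB", "GX", ""]
    used = set()
    while len(table.records) < n_records:
        chrom = "chr1" if rng.integers(2) == 0 else "chr2"
        pos = int(rng.integers(1, 3000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        maf = None if rng.uniform() < 0.3 else float(f"{rng.uniform(0, 0.1):.6g}")
        sig = _SIGNIFICANCES[rng.integers(len(_SIGNIFICANCES))]
        phen = (
            frozenset({"Retinitis pigmentosa"})
            if rng.uniform() < 0.3
            else frozenset({"Hearing loss"})
        )
        rec = VariantRecord(
            chrom, pos, "A", "G",
            gene=genes[rng.integers(len(genes))],
            maf=maf,
            clinvar_significance=sig,
            clinvar_phenotypes=phen,
        )
        table.add_record(rec)
        for s in samples:
            table.set_call(rec.variant_id, s, zygs[rng.integers(4)])
    return table
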