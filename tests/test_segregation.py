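"""Pair enumeration, cis/trans phase inference and segregation verdicts."""

import itertools

import pytest

from irdprio.cohort import simulate_cohort, SimulationParams
from irdprio.filters import run_cascade
from irdprio.model import (
    Affection,
    Pedigree,
    PedigreeMember,
    ValidationError,
    VariantRecord,
    VariantTable,
    Zygosity,
)
from irdprio.prioritize import assemble_candidates
from irdprio.segregation import (
    BiallelicPair,
    enumerate_pairs,
    family_report,
    infer_phase,
    segregate,
)


class _FakeCandidate:
    def __init__(self, record):
        self.record = record
        self.variant_id = record.variant_id


def _trio_pedigree():
    A, U = Affection.AFFECTED, Affection.UNAFFECTED
    return Pedigree(
        [
            PedigreeMember("dad", sex="male", affected=A, sequenced=True),
            PedigreeMember("mum", sex="female", affected=U, sequenced=True),
            PedigreeMember("kid", "dad", "mum", "male", U, sequenced=True),
        ]
    )


def _gene_table(zygs):
    """Two variants in gene G; zygs: {sample: (zyg_a, zyg_b)}."""
    ra = VariantRecord("chr1", 100, "A", "G", gene="G")
    rb = VariantRecord("chr1", 200, "C", "T", gene="G")
    t = VariantTable(samples=list(zygs))
    t.add_record(ra)
    t.add_record(rb)
    for s, (za, zb) in zygs.items():
        t.set_call(ra.variant_id, s, za)
        t.set_call(rb.variant_id, s, zb)
    return t, ra, rb


HET, REF, HOM, MISS = Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_ALT, Zygosity.MISSING


# ---------------------------------------------------------------- enumeration

def test_reference_pairs(reference):
    """Three biallelic USH2A combinations, one per carrier configuration."""
    filtered, _ = run_cascade(
        reference.wgs, reference.pedigree, reference.panel,
        reference.family_samples, reference.control_samples,
    )
    cands = assemble_candidates(filtered, reference.panel)
    pairs = enumerate_pairs(cands, reference.genotypes, reference.pedigree)
    v = reference.variant_ids
    got = {(p.variant_a, p.variant_b) for p in pairs}
    want = {
        tuple(sorted((v["M1"], v["M3"]))),  # III:17 and III:23
        tuple(sorted((v["M2"], v["M3"]))),  # III:20
        tuple(sorted((v["M2"], v["M4"]))),  # III:3
    }
    assert got == want
    assert all(p.gene == "USH2A" for p in pairs)
    assert all(p.phase == "unknown" for p in pairs)


def test_single_candidate_gene_yields_no_pairs():
    t, ra, _ = _gene_table({"dad": (HET, REF), "mum": (REF, REF), "kid": (REF, REF)})
    pairs = enumerate_pairs([_FakeCandidate(ra)], t, _trio_pedigree())
    assert pairs == []


def test_homozygous_affected_yields_self_pair():
    t, ra, rb = _gene_table({"dad": (HOM, REF), "mum": (REF, REF), "kid": (HET, REF)})
    pairs = enumerate_pairs([_FakeCandidate(ra), _FakeCandidate(rb)], t, _trio_pedigree())
    assert len(pairs) == 1
    assert pairs[0].is_homozygous
    assert infer_phase(pairs[0], t, _trio_pedigree()).phase == "trans"


@pytest.mark.parametrize("seed", range(5))
def test_pairs_match_double_loop_oracle(seed):
    cohort = simulate_cohort(SimulationParams(seed=seed, n_decoy_variants=30))
    filtered, _ = run_cascade(
        cohort.table, cohort.pedigree, cohort.panel,
        cohort.family_samples, cohort.control_samples,
    )
    cands = assemble_candidates(filtered, cohort.panel)
    pairs = enumerate_pairs(cands, cohort.table, cohort.pedigree)
    affected = [m for m in cohort.pedigree.affected_ids if m in cohort.table.samples]
    expected = set()
    by_gene = {}
    for c in cands:
        by_gene.setdefault(c.record.gene, []).append(c.variant_id)
    for gene, vids in by_gene.items():
        for a, b in itertools.combinations(sorted(vids), 2):
            for m in affected:
                if cohort.table.call(a, m) is HET and cohort.table.call(b, m) is HET:
                    expected.add((a, b))
                    break
        for a in vids:
            if any(cohort.table.call(a, m) is HOM for m in affected):
                expected.add((a, a))
    assert {(p.variant_a, p.variant_b) for p in pairs} == expected


# -------------------------------------------------------------------- phasing

def test_phase_child_with_one_allele_is_trans():
    t, ra, rb = _gene_table({"dad": (HET, HET), "mum": (REF, REF), "kid": (HET, REF)})
    pair = BiallelicPair("G", ra.variant_id, rb.variant_id)
    assert infer_phase(pair, t, _trio_pedigree()).phase == "trans"


def test_phase_child_with_both_alleles_is_cis():
    t, ra, rb = _gene_table({"dad": (HET, HET), "mum": (REF, REF), "kid": (HET, HET)})
    pair = BiallelicPair("G", ra.variant_id, rb.variant_id)
    out = infer_phase(pair, t, _trio_pedigree())
    assert out.phase == "cis"


def test_phase_child_with_neither_allele_is_uninformative():
    t, ra, rb = _gene_table({"dad": (HET, HET), "mum": (REF, REF), "kid": (REF, REF)})
    pair = BiallelicPair("G", ra.variant_id, rb.variant_id)
    assert infer_phase(pair, t, _trio_pedigree()).phase == "unknown"


def test_phase_no_informative_relatives():
    t, ra, rb = _gene_table({"dad": (HET, HET), "mum": (MISS, MISS), "kid": (MISS, MISS)})
    pair = BiallelicPair("G", ra.variant_id, rb.variant_id)
    out = infer_phase(pair, t, _trio_pedigree())
    assert out.phase == "unknown"
    assert "no informative" in out.evidence


def test_phase_parental_origin_is_trans():
    """Child double-het; father carries exactly one allele, mother typed ref."""
    A = Affection.AFFECTED
    ped = Pedigree(
        [
            PedigreeMember("dad", sex="male", affected="unaffected"),
            PedigreeMember("mum", sex="female", affected="unaffected"),
            PedigreeMember("kid", "dad", "mum", "female", A),
        ]
    )
    t, ra, rb = _gene_table({"dad": (HET, REF), "mum": (REF, HET), "kid": (HET, HET)})
    pair = BiallelicPair("G", ra.variant_id, rb.variant_id)
    assert infer_phase(pair, t, ped).phase == "trans"


def test_phase_conflict_stays_unknown():
    """Two children disagreeing (one co-inherits, one gets a single allele)
    leave the phase unknown with the conflict recorded."""
    A, U = Affection.AFFECTED, Affection.UNAFFECTED
    ped = Pedigree(
        [
            PedigreeMember("dad", sex="male", affected=A),
            PedigreeMember("mum", sex="female", affected=U),
            PedigreeMember("k1", "dad", "mum", "male", U),
            PedigreeMember("k2", "dad", "mum", "male", U),
        ]
    )
    ra = VariantRecord("chr1", 100, "A", "G", gene="G")
    rb = VariantRecord("chr1", 200, "C", "T", gene="G")
    t = VariantTable(samples=["dad", "mum", "k1", "k2"])
    t.add_record(ra)
    t.add_record(rb)
    for s, (za, zb) in {
        "dad": (HET, HET), "mum": (REF, REF), "k1": (HET, HET), "k2": (HET, REF)
    }.items():
        t.set_call(ra.variant_id, s, za)
        t.set_call(rb.variant_id, s, zb)
    pair = BiallelicPair("G", ra.variant_id, rb.variant_id)
    out = infer_phase(pair, t, ped)
    assert out.phase == "unknown"
    assert "conflicting" in out.evidence


def test_reference_m2_m4_phase_trans(reference):
    v = reference.variant_ids
    pair = BiallelicPair("USH2A", v["M2"], v["M4"])
    out = infer_phase(pair, reference.genotypes, reference.pedigree)
    assert out.phase == "trans"
    assert "IV:1" in out.evidence


# ---------------------------------------------------------------- segregation

def test_reference_segregation_verdicts(reference):
    v = reference.variant_ids
    ped = reference.pedigree
    branch3 = [m for m in ped.branch_members(("II:5", "II:6")) if ped.member(m).genotyped]
    res = segregate((v["M1"], v["M3"]), reference.genotypes, ped, members=branch3)
    assert res.verdict == "segregates"
    assert res.per_member["III:17"] == "consistent"
    assert res.per_member["III:23"] == "consistent"

    branch1 = [m for m in ped.branch_members(("II:1", "II:2")) if ped.member(m).genotyped]
    res = segregate((v["M2"], v["M4"]), reference.genotypes, ped, members=branch1)
    assert res.verdict == "partial"
    assert res.per_member["III:4"] == "inconsistent"  # unaffected double carrier
    assert res.per_member["III:3"] == "consistent"


def test_configuration_absent_everywhere_is_excluded(reference):
    v = reference.variant_ids
    # nobody carries M1 together with M4
    res = segregate((v["M1"], v["M4"]), reference.genotypes, reference.pedigree)
    assert res.verdict == "excluded"


def test_unknown_configuration_variant_raises(reference):
    with pytest.raises(ValidationError):
        segregate(("chrZ:1:A:G",), reference.genotypes, reference.pedigree)


def test_segregate_invariant_to_member_order_and_untyped_additions(reference):
    v = reference.variant_ids
    ped = reference.pedigree
    branch3 = [m for m in ped.branch_members(("II:5", "II:6")) if ped.member(m).genotyped]
    base = segregate((v["M1"], v["M3"]), reference.genotypes, ped, members=branch3)
    flipped = segregate((v["M1"], v["M3"]), reference.genotypes, ped, members=branch3[::-1])
    assert flipped.verdict == base.verdict and flipped.per_member == base.per_member
    # adding members with no calls at the configuration cannot change the verdict
    extended = branch3 + ["III:10", "III:11", "III:15"]
    res = segregate((v["M1"], v["M3"]), reference.genotypes, ped, members=extended)
    assert res.verdict == base.verdict
    assert res.per_member["III:10"] == "untyped"


def test_homozygous_configuration_requires_hom():
    A, U = Affection.AFFECTED, Affection.UNAFFECTED
    ped = Pedigree(
        [
            PedigreeMember("p1", affected=A),
            PedigreeMember("p2", affected=U),
        ]
    )
    t, ra, _ = _gene_table({"p1": (HOM, REF), "p2": (HET, REF)})
    res = segregate((ra.variant_id, ra.variant_id), t, ped)
    # affected hom carries the doubled allele; the het unaffected does not
    assert res.verdict == "segregates"
    assert res.per_member == {"p1": "consistent", "p2": "consistent"}


# --------------------------------------------------------------------- report

def test_reference_family_report(reference):
    filtered, _ = run_cascade(
        reference.wgs, reference.pedigree, reference.panel,
        reference.family_samples, reference.control_samples,
    )
    cands = assemble_candidates(filtered, reference.panel)
    pairs = [
        infer_phase(p, reference.genotypes, reference.pedigree)
        for p in enumerate_pairs(cands, reference.genotypes, reference.pedigree)
    ]
    report = family_report(pairs, cands, reference.genotypes, reference.pedigree)
    v = reference.variant_ids
    index = report["members"]["III:3"]
    assert sorted(index["alleles"]) == sorted([v["M2"], v["M4"], v["M5"], v["M6"]])
    assert index["genes"] == ["ADGRV1", "PDZD7", "USH2A"]
    assert index["oligogenic_flag"]
    # allele lists equal brute-force counting of non-ref calls per member
    for member, info in report["members"].items():
        expected = [
            c.variant_id
            for c in cands
            if member in reference.genotypes.samples
            and reference.genotypes.call(c.variant_id, member).carries_alt
        ]
        assert sorted(info["alleles"]) == sorted(expected)
    # branch verdicts surface the published segregation statements
    by_key = {(p["variant_a"], p["variant_b"]): p for p in report["pairs"]}
    m1m3 = by_key[tuple(sorted((v["M1"], v["M3"])))]
    assert m1m3["branch_verdicts"]["II:5+II:6"] == "segregates"
    m2m4 = by_key[tuple(sorted((v["M2"], v["M4"])))]
    assert m2m4["branch_verdicts"]["II:1+II:2"] == "partial"
    assert m2m4["phase"] == "trans"


def test_single_pair_family_has_no_oligogenic_flag():
    cohort = simulate_cohort(SimulationParams(seed=11, n_decoy_variants=0))
    filtered, _ = run_cascade(
        cohort.table, cohort.pedigree, cohort.panel,
        cohort.family_samples, cohort.control_samples,
    )
    cands = assemble_candidates(filtered, cohort.panel)
    pairs = [
        infer_phase(p, cohort.table, cohort.pedigree)
        for p in enumerate_pairs(cands, cohort.table, cohort.pedigree)
    ]
    report = family_report(pairs, cands, cohort.genotypes, cohort.pedigree)
    assert len(report["pairs"]) == 1
    assert not any(m["oligogenic_flag"] for m in report["members"].values())


def test_cis_pairs_excluded_from_relevant_alleles():
    cohort = simulate_cohort(SimulationParams(seed=2, n_decoy_variants=40))
    filtered, _ = run_cascade(
        cohort.table, cohort.pedigree, cohort.panel,
        cohort.family_samples, cohort.control_samples,
    )
    cands = assemble_candidates(filtered, cohort.panel)
    pairs = [
        infer_phase(p, cohort.table, cohort.pedigree)
        for p in enumerate_pairs(cands, cohort.table, cohort.pedigree)
    ]
    report = family_report(pairs, cands, cohort.genotypes, cohort.pedigree)
    cis_vids = {v for v, lab in cohort.truth.variant_labels.items() if lab == "decoy:cis_pair"}
    assert cis_vids  # the mix plants at least one cis pair
    for info in report["members"].values():
        assert not (set(info["alleles"]) & cis_vids)
    assert set(report["clinically_relevant_variants"]) == {
        v for v, lab in cohort.truth.variant_labels.items() if lab == "causal"
    }
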