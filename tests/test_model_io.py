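"""Domain types and file round trips: VCF, PED, BED panels, TSV tables."""

import itertools

import pytest
from hypothesis import given, strategies as st

from irdprio.io import (
    combine_tables,
    read_gene_panel,
    read_genotype_table,
    read_pedigree,
    read_splice_scores,
    read_vcf,
    write_gene_panel,
    write_genotype_table,
    write_pedigree,
    write_splice_scores,
    write_vcf,
)
from irdprio.model import (
    Affection,
    GeneModel,
    GenePanel,
    Pedigree,
    PedigreeMember,
    SpliceScorePair,
    ValidationError,
    VariantRecord,
    VariantTable,
    Zygosity,
    merge_intervals,
)

from helpers import random_table


# ---------------------------------------------------------------------- model

def test_variant_record_invariants():
    with pytest.raises(ValidationError):
        VariantRecord("chr1", 0, "A", "G")
    with pytest.raises(ValidationError):
        VariantRecord("chr1", 5, "A", "A")
    with pytest.raises(ValidationError):
        VariantRecord("chr1", 5, "A", "G,T")
    rec = VariantRecord("chr1", 5, "A", "G")
    assert rec.variant_id == "chr1:5:A:G"


def test_table_rejects_duplicate_ids_and_unknown_keys():
    table = VariantTable(samples=["s1"])
    table.add_record(VariantRecord("chr1", 5, "A", "G"))
    with pytest.raises(ValidationError):
        table.add_record(VariantRecord("chr1", 5, "A", "G"))
    with pytest.raises(ValidationError):
        table.set_call("chr9:1:A:G", "s1", Zygosity.HET)
    with pytest.raises(ValidationError):
        table.set_call("chr1:5:A:G", "nobody", Zygosity.HET)
    # unset pair resolves to missing
    assert table.call("chr1:5:A:G", "s1") is Zygosity.MISSING


# ------------------------------------------------------------------------ VCF

def test_vcf_round_trip_preserves_content(tmp_path, reference_with_decoys):
    table = reference_with_decoys.wgs
    path = tmp_path / "out.vcf"
    write_vcf(table, str(path))
    again = read_vcf(str(path))
    assert again.content_equal(table)
    # serialization reaches a byte-stable fixed point immediately
    path2 = tmp_path / "again.vcf"
    write_vcf(again, str(path2))
    assert path.read_bytes() == path2.read_bytes()


def test_reference_vcf_shape(tmp_path, reference):
    path = tmp_path / "fam.vcf"
    write_vcf(reference.wgs, str(path))
    table = read_vcf(str(path))
    assert table.n_records == 6
    assert len(table.samples) == 9


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def test_multiallelic_site_splits_per_allele(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(_VCF_HEADER + "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2\n")
    table = read_vcf(str(path))
    assert sorted(table.records) == ["chr1:100:A:G", "chr1:100:A:T"]
    assert table.call("chr1:100:A:G", "s1") is Zygosity.HET
    assert table.call("chr1:100:A:T", "s1") is Zygosity.HOM_REF
    assert table.call("chr1:100:A:G", "s2") is Zygosity.HET
    assert table.call("chr1:100:A:T", "s2") is Zygosity.HET
    assert table.call("chr1:100:A:T", "s3") is Zygosity.HOM_ALT


def test_split_count_invariant(tmp_path):
    # biallelic record count >= site lines; equality iff no multiallelic sites
    path = tmp_path / "mix.vcf"
    path.write_text(
        _VCF_HEADER
        + "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        + "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
    )
    assert read_vcf(str(path)).n_records == 3
    path.write_text(_VCF_HEADER + "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t./.\n")
    table = read_vcf(str(path))
    assert table.n_records == 1
    assert table.call("chr1:200:C:T", "s3") is Zygosity.MISSING


def test_empty_body_vcf(tmp_path):
    path = tmp_path / "empty.vcf"
    path.write_text(_VCF_HEADER)
    table = read_vcf(str(path))
    assert table.n_records == 0
    assert table.samples == ["s1", "s2", "s3"]


def test_symbolic_alt_skipped(tmp_path):
    path = tmp_path / "sv.vcf"
    path.write_text(
        _VCF_HEADER
        + "chr1\t100\t.\tA\t<DEL>\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        + "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
    )
    table = read_vcf(str(path))
    assert list(table.records) == ["chr1:200:C:T"]


# -------------------------------------------------------------------- combine

def _mini_table(samples, calls):
    """calls: {variant_id-like (chrom,pos): {sample: zyg}}"""
    table = VariantTable(samples=samples)
    for (chrom, pos), per_sample in calls.items():
        rec = VariantRecord(chrom, pos, "A", "G")
        table.add_record(rec)
        for s, z in per_sample.items():
            table.set_call(rec.variant_id, s, z)
    return table


def test_combine_union_and_missing_default():
    t_a = _mini_table(["a1"], {("chr1", 10): {"a1": Zygosity.HET}})
    t_b = _mini_table(
        ["b1"],
        {("chr1", 10): {"b1": Zygosity.HOM_REF}, ("chr1", 20): {"b1": Zygosity.HET}},
    )
    merged = combine_tables([t_a, t_b])
    assert sorted(merged.records) == ["chr1:10:A:G", "chr1:20:A:G"]
    assert merged.call("chr1:20:A:G", "a1") is Zygosity.MISSING
    all_sites = combine_tables([t_a, t_b], missing_as_ref=True)
    assert all_sites.call("chr1:20:A:G", "a1") is Zygosity.HOM_REF


def test_combine_single_table_is_identity():
    t = random_table(seed=3, n_records=10)
    assert combine_tables([t]).content_equal(t)


def test_combine_rejects_duplicate_samples():
    t = _mini_table(["x"], {("chr1", 10): {"x": Zygosity.HET}})
    with pytest.raises(ValidationError):
        combine_tables([t, _mini_table(["x"], {("chr1", 11): {"x": Zygosity.HET}})])


def test_combine_order_insensitive():
    tables = [
        _mini_table(["a"], {("chr1", 10): {"a": Zygosity.HET}}),
        _mini_table(["b"], {("chr1", 10): {"b": Zygosity.HOM_ALT}, ("chr1", 30): {}}),
        _mini_table(["c"], {("chr2", 5): {"c": Zygosity.HET}}),
    ]
    baseline = combine_tables(tables)
    for perm in itertools.permutations(tables):
        merged = combine_tables(list(perm))
        assert merged.content_equal(baseline)


# ------------------------------------------------------------------------ PED

def test_pedigree_round_trip(tmp_path, reference):
    path = tmp_path / "fam.ped"
    write_pedigree(reference.pedigree, str(path))
    ped = read_pedigree(str(path))
    assert set(ped.members) == set(reference.pedigree.members)
    assert sorted(ped.genotyped_ids) == sorted(reference.pedigree.genotyped_ids)
    assert sorted(ped.sequenced_ids) == sorted(reference.pedigree.sequenced_ids)
    assert ped.member("III:3").affected is Affection.AFFECTED
    assert ped.member("IV:1").mother_id == "III:3"


def test_trio_ped(tmp_path):
    path = tmp_path / "trio.ped"
    path.write_text("F\tdad\t0\t0\t1\t1\nF\tmum\t0\t0\t2\t1\nF\tkid\tdad\tmum\t1\t2\n")
    ped = read_pedigree(str(path))
    assert len(ped.members) == 3
    assert ped.member("kid").father_id == "dad"
    assert ped.member("kid").mother_id == "mum"


def test_ped_errors(tmp_path):
    bad = tmp_path / "bad.ped"
    bad.write_text("F\tkid\tghost\t0\t1\t2\n")
    with pytest.raises(ValidationError):
        read_pedigree(str(bad))
    bad.write_text("F\tkid\tkid\t0\t1\t2\n")
    with pytest.raises(ValidationError):
        read_pedigree(str(bad))
    # two-member parentage cycle
    with pytest.raises(ValidationError):
        Pedigree(
            [
                PedigreeMember("a", father_id="b"),
                PedigreeMember("b", father_id="a"),
            ]
        )


# ------------------------------------------------------------------ BED panel

def test_panel_round_trip(tmp_path, reference):
    path = tmp_path / "panel.bed"
    write_gene_panel(reference.panel, str(path))
    panel = read_gene_panel(str(path))
    assert set(panel.genes) == set(reference.panel.genes)
    for name, gene in panel.genes.items():
        assert gene.span == reference.panel.genes[name].span
        assert gene.exons == reference.panel.genes[name].exons


def test_single_exon_gene_span_is_exon(tmp_path):
    path = tmp_path / "one.bed"
    path.write_text("chr1\t100\t200\tGENE1\n")
    panel = read_gene_panel(str(path))
    assert panel.genes["GENE1"].span == (100, 200)
    assert panel.genes["GENE1"].exons == [(100, 200)]


def test_overlapping_exons_merge(tmp_path):
    path = tmp_path / "two.bed"
    path.write_text("chr1\t100\t200\tG\n" "chr1\t150\t300\tG\n")
    panel = read_gene_panel(str(path))
    assert panel.genes["G"].exons == [(100, 300)]


def test_bad_interval_rejected(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t200\t200\tG\n")
    with pytest.raises(ValidationError):
        read_gene_panel(str(path))
    with pytest.raises(ValidationError):
        GeneModel("G", "chr1", (0, 100), [(50, 150)])  # exon outside span


@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=500))
def test_bed_coordinate_conversion_round_trip(start, length):
    # 0-based half-open [s, e) -> 1-based inclusive [s+1, e] -> back
    end = start + length
    first_1b, last_1b = start + 1, end
    assert (first_1b - 1, last_1b) == (start, end)
    gene = GeneModel("G", "chr1", (start, end), [(start, end)])
    assert gene.in_exon(first_1b) and gene.in_exon(last_1b)
    assert not gene.in_exon(start) and not gene.in_exon(end + 1)


@given(
    st.lists(
        st.tuples(st.integers(0, 100), st.integers(1, 30)).map(lambda t: (t[0], t[0] + t[1])),
        max_size=8,
    )
)
def test_merge_intervals_union(intervals):
    merged = merge_intervals(intervals)
    covered = {p for s, e in intervals for p in range(s, e)}
    covered_merged = {p for s, e in merged for p in range(s, e)}
    assert covered == covered_merged
    assert all(e1 < s2 for (_, e1), (s2, _) in zip(merged, merged[1:]))


# ---------------------------------------------------------------------- TSVs

def test_splice_score_round_trip(tmp_path):
    pairs = [
        SpliceScorePair("chr1:5:A:G", "maxent", 8.0, 4.0),
        SpliceScorePair("chr1:5:A:G", "nnsplice", 0.9, 0.2),
    ]
    path = tmp_path / "scores.tsv"
    write_splice_scores(pairs, str(path))
    assert read_splice_scores(str(path)) == pairs
    bad = tmp_path / "bad.tsv"
    bad.write_text("id\ttool\n")
    with pytest.raises(ValidationError):
        read_splice_scores(str(bad))
    with pytest.raises(ValidationError):
        SpliceScorePair("chr1:5:A:G", "spliceai", 1.0, 0.0)


def test_genotype_table_round_trip(tmp_path, reference):
    path = tmp_path / "gts.tsv"
    write_genotype_table(reference.genotypes, str(path))
    table = read_genotype_table(str(path), records=reference.genotypes.records)
    for (vid, sample), zyg in reference.genotypes.genotypes.items():
        assert table.call(vid, sample) is zyg
    # without a record map, minimal records come from the id string
    bare = read_genotype_table(str(path))
    assert set(bare.records) == set(reference.genotypes.records)
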