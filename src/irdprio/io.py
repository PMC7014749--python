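"""Readers and writers for the pipeline's on-disk formats.

* multi-sample VCF v4.2 (read through cyvcf2; written as text so that a fixed
  table always serializes to identical bytes),
* 6-column PED pedigrees with two optional trailing flag columns
  (``sequenced``, ``genotyped``),
* BED-derived gene panels (0-based half-open exon intervals, optional
  explicit span lines),
* TSV splice-score tables and long-format genotype tables (Sanger results).

Variant annotations travel in configurable INFO keys; the defaults mirror a
gnomAD/ClinVar-annotated VCF (``GENE``, ``GNOMAD_AF``, ``GNOMAD_NHOMALT``,
``CLNSIG``, ``CLNDN``).  Multiallelic sites are split into biallelic records
at read time and per-sample zygosity is derived per alternate allele.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from cyvcf2 import VCF

from .model import (
    Affection,
    ClinVarSignificance,
    GeneModel,
    GenePanel,
    Pedigree,
    PedigreeMember,
    Sex,
    SpliceScorePair,
    ValidationError,
    VariantRecord,
    VariantTable,
    Zygosity,
    natural_chrom_key,
    parse_variant_id,
)

log = logging.getLogger(__name__)

#: default INFO keys carrying annotations (gnomAD/ClinVar-style)
DEFAULT_INFO_KEYS = {
    "gene": "GENE",
    "maf": "GNOMAD_AF",
    "hom_count": "GNOMAD_NHOMALT",
    "clinvar_significance": "CLNSIG",
    "clinvar_phenotypes": "CLNDN",
    "acmg_class": "ACMG_CLASS",
    "label": "LABEL",
}

#: INFO keys holding per-tool pathogenicity predictor calls (carried, not used)
PREDICTOR_INFO_KEYS = ("SIFT", "POLYPHEN2", "MUTATIONTASTER")

_CLNSIG_MAP = {
    "pathogenic": ClinVarSignificance.PATHOGENIC,
    "likely_pathogenic": ClinVarSignificance.LIKELY_PATHOGENIC,
    "pathogenic/likely_pathogenic": ClinVarSignificance.LIKELY_PATHOGENIC,
    "conflicting_interpretations_of_pathogenicity": ClinVarSignificance.CONFLICTING_PATH_VUS,
    "conflicting_path_vus": ClinVarSignificance.CONFLICTING_PATH_VUS,
    "uncertain_significance": ClinVarSignificance.VUS,
    "vus": ClinVarSignificance.VUS,
    "benign": ClinVarSignificance.BENIGN,
    "likely_benign": ClinVarSignificance.LIKELY_BENIGN,
    "benign/likely_benign": ClinVarSignificance.LIKELY_BENIGN,
    "not_reported": ClinVarSignificance.NOT_REPORTED,
}


def parse_clinvar_significance(raw: Optional[str]) -> ClinVarSignificance:
    if raw is None or raw == "":
        return ClinVarSignificance.NOT_REPORTED
    key = str(raw).strip().lower().replace(" ", "_")
    sig = _CLNSIG_MAP.get(key)
    if sig is None:
        log.warning("unrecognized ClinVar significance %r; treating as not_reported", raw)
        return ClinVarSignificance.NOT_REPORTED
    return sig


def _allele_zygosity(gt_alleles: Sequence[int], alt_index: int) -> Zygosity:
    """Zygosity for one alternate allele from GT allele indices (−1 = missing)."""
    called = [a for a in gt_alleles if a >= 0]
    if not called:
        return Zygosity.MISSING
    n_alt = sum(1 for a in called if a == alt_index)
    if n_alt == 0:
        return Zygosity.HOM_REF
    if n_alt >= len(called) and len(called) > 1:
        return Zygosity.HOM_ALT
    if len(called) == 1:  # haploid call: treat as hom (no het on a single allele)
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_vcf(path: str, info_keys: Optional[Mapping[str, str]] = None) -> VariantTable:
    """Parse a VCF v4.x file into a :class:`VariantTable`.

    Multiallelic sites are split into one biallelic record per alternate
    allele; symbolic alternate alleles (``<DEL>`` etc.) are skipped with a
    warning.  Annotation INFO keys absent from a record leave the
    corresponding fields unset.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    table = VariantTable(samples=list(vcf.samples))
    for site_index, variant in enumerate(vcf, start=1):
        gts = variant.genotypes  # per-sample [a0, a1, phased]
        for alt_index, alt in enumerate(variant.ALT, start=1):
            if alt.startswith("<") or "[" in alt or "]" in alt:
                log.warning(
                    "skipping symbolic/breakend ALT %s at %s:%d (site %d)",
                    alt, variant.CHROM, variant.POS, site_index,
                )
                continue
            info = variant.INFO
            raw_maf = info.get(keys["maf"])
            raw_hom = info.get(keys["hom_count"])
            raw_phen = info.get(keys["clinvar_phenotypes"])
            phenotypes = frozenset(
                p.replace("_", " ")
                for p in str(raw_phen).split("|")
                if p
            ) if raw_phen is not None else frozenset()
            predictors = {}
            for pk in PREDICTOR_INFO_KEYS:
                val = info.get(pk)
                if val is not None:
                    predictors[pk.lower()] = str(val)
            raw_acmg = info.get(keys["acmg_class"])
            try:
                rec = VariantRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    gene=str(info.get(keys["gene"]) or ""),
                    # htslib stores INFO floats as float32; re-quantize to the
                    # 6 significant digits the writer emits
                    maf=float(f"{float(raw_maf):.6g}") if raw_maf is not None else None,
                    hom_count=int(raw_hom) if raw_hom is not None else None,
                    clinvar_significance=parse_clinvar_significance(
                        info.get(keys["clinvar_significance"])
                    ),
                    clinvar_phenotypes=phenotypes,
                    predictor_calls=predictors,
                    acmg_class=int(raw_acmg) if raw_acmg is not None else None,
                    label=str(info.get(keys["label"]) or ""),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} site {site_index}: {exc}") from exc
            try:
                table.add_record(rec)
            except ValidationError as exc:
                raise ValidationError(f"{path} site {site_index}: {exc}") from exc
            for sample, gt in zip(table.samples, gts):
                zyg = _allele_zygosity(list(gt[:-1]), alt_index)
                if zyg is not Zygosity.MISSING:
                    table.set_call(rec.variant_id, sample, zyg)
                else:
                    table.genotypes[(rec.variant_id, sample)] = Zygosity.MISSING
    return table


_GT_STRING = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


def _format_float(x: float) -> str:
    # 6 significant digits: stable under htslib's float32 INFO storage,
    # so write → read → write reaches a fixed point immediately
    return f"{float(x):.6g}"


def write_vcf(table: VariantTable, path: str, info_keys: Optional[Mapping[str, str]] = None) -> None:
    """Serialize a table to VCF v4.2 text (records sorted by position).

    The output is deterministic byte-for-byte for a given table, which the
    cohort simulator relies on for its reproducibility contract.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    records = table.sorted_records()
    contigs = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    contigs.sort(key=natural_chrom_key)
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    info_defs = [
        (keys["gene"], "1", "String", "Gene symbol"),
        (keys["maf"], "1", "Float", "Population minor allele frequency"),
        (keys["hom_count"], "1", "Integer", "Population homozygote count"),
        (keys["clinvar_significance"], "1", "String", "ClinVar clinical significance"),
        (keys["clinvar_phenotypes"], "1", "String", "ClinVar phenotype list (| separated)"),
        (keys["acmg_class"], "1", "Integer", "ACMG class (carried annotation)"),
        (keys["label"], "1", "String", "Display label"),
    ] + [(pk, "1", "String", f"{pk} predictor call") for pk in PREDICTOR_INFO_KEYS]
    for name, number, typ, desc in info_defs:
        lines.append(f'##INFO=<ID={name},Number={number},Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header_cols.extend(table.samples)
    lines.append("\t".join(header_cols))
    for rec in records:
        info_parts = []
        if rec.gene:
            info_parts.append(f"{keys['gene']}={rec.gene}")
        if rec.maf is not None:
            info_parts.append(f"{keys['maf']}={_format_float(rec.maf)}")
        if rec.hom_count is not None:
            info_parts.append(f"{keys['hom_count']}={rec.hom_count}")
        if rec.clinvar_significance is not ClinVarSignificance.NOT_REPORTED:
            info_parts.append(f"{keys['clinvar_significance']}={rec.clinvar_significance.value}")
        if rec.clinvar_phenotypes:
            joined = "|".join(sorted(p.replace(" ", "_") for p in rec.clinvar_phenotypes))
            info_parts.append(f"{keys['clinvar_phenotypes']}={joined}")
        if rec.acmg_class is not None:
            info_parts.append(f"{keys['acmg_class']}={rec.acmg_class}")
        if rec.label:
            info_parts.append(f"{keys['label']}={rec.label}")
        for pk in PREDICTOR_INFO_KEYS:
            val = rec.predictor_calls.get(pk.lower())
            if val is not None:
                info_parts.append(f"{pk}={val}")
        row = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            rec.alt,
            ".",
            "PASS",
            ";".join(info_parts) if info_parts else ".",
            "GT",
        ]
        for sample in table.samples:
            row.append(_GT_STRING[table.call(rec.variant_id, sample)])
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def combine_tables(tables: Sequence[VariantTable], missing_as_ref: bool = False) -> VariantTable:
    """Merge per-sample (or per-family) tables into one multi-sample table.

    Records are unioned by variant id; sample columns are concatenated.  A
    sample whose source table lacks a union variant gets ``hom_ref`` when
    ``missing_as_ref`` is set (all-sites VCFs) and ``missing`` otherwise.
    """
    all_samples: list[str] = []
    for t in tables:
        for s in t.samples:
            if s in all_samples:
                raise ValidationError(f"duplicate sample id {s} across combined tables")
            all_samples.append(s)
    out = VariantTable(samples=all_samples)
    for t in tables:
        for vid, rec in t.records.items():
            if vid not in out.records:
                out.records[vid] = rec
    absent_default = Zygosity.HOM_REF if missing_as_ref else Zygosity.MISSING
    for t in tables:
        for vid in out.records:
            present = vid in t.records
            for s in t.samples:
                if present:
                    out.genotypes[(vid, s)] = t.call(vid, s)
                else:
                    out.genotypes[(vid, s)] = absent_default
    return out


_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}
_AFF_TO_PED = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


def read_pedigree(path: str) -> Pedigree:
    """Parse a whitespace-delimited PED file.

    Columns: family, member, father, mother, sex, phenotype
    [, sequenced, genotyped].  ``0`` encodes an unknown parent; sex 1/2 =
    male/female; phenotype 2/1 = affected/unaffected, anything else unknown.
    The optional flag columns take 1/0.
    """
    members = []
    family_id = "FAM"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValidationError(f"{path} line {lineno}: expected >= 6 PED columns")
            family_id = cols[0]
            member = PedigreeMember(
                member_id=cols[1],
                father_id=None if cols[2] == "0" else cols[2],
                mother_id=None if cols[3] == "0" else cols[3],
                sex=_SEX_FROM_PED.get(cols[4], Sex.UNKNOWN),
                affected=_AFF_FROM_PED.get(cols[5], Affection.UNKNOWN),
                sequenced=len(cols) > 6 and cols[6] == "1",
                genotyped=cols[7] == "1" if len(cols) > 7 else True,
            )
            if member.member_id in (member.father_id, member.mother_id):
                raise ValidationError(
                    f"{path} line {lineno}: member {member.member_id} is its own parent"
                )
            members.append(member)
    return Pedigree(members, family_id=family_id)


def write_pedigree(pedigree: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        for m in pedigree.members.values():
            fh.write(
                "\t".join(
                    [
                        pedigree.family_id,
                        m.member_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_TO_PED[m.sex],
                        _AFF_TO_PED[m.affected],
                        "1" if m.sequenced else "0",
                        "1" if m.genotyped else "0",
                    ]
                )
                + "\n"
            )


def read_gene_panel(path: str, name: str = "panel") -> GenePanel:
    """Parse a BED-derived panel: chrom, start, end, gene [, feature].

    Intervals are 0-based half-open.  ``feature`` is ``exon`` (default) or
    ``span``; overlapping exon lines of one gene are merged and the span
    defaults to the hull of the exons when no span line is given.
    """
    exons: dict[str, list] = {}
    spans: dict[str, tuple] = {}
    chroms: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ValidationError(f"{path} line {lineno}: expected >= 4 BED columns")
            chrom, start, end, gene = cols[0], int(cols[1]), int(cols[2]), cols[3]
            feature = cols[4] if len(cols) > 4 else "exon"
            if end <= start:
                raise ValidationError(f"{path} line {lineno}: interval end <= start")
            if gene in chroms and chroms[gene] != chrom:
                raise ValidationError(f"{path} line {lineno}: gene {gene} on two chromosomes")
            chroms[gene] = chrom
            if feature == "span":
                spans[gene] = (start, end)
            else:
                exons.setdefault(gene, []).append((start, end))
    genes = []
    for gene, chrom in chroms.items():
        ex = exons.get(gene, [])
        if gene in spans:
            span = spans[gene]
            if not ex:
                ex = [span]
        else:
            if not ex:
                raise ValidationError(f"gene {gene} has neither exons nor a span line")
            span = (min(s for s, _ in ex), max(e for _, e in ex))
        genes.append(GeneModel(name=gene, chrom=chrom, span=span, exons=ex))
    return GenePanel(genes, name=name)


def write_gene_panel(panel: GenePanel, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(panel.genes.values(), key=lambda g: (natural_chrom_key(g.chrom), g.span)):
            fh.write(f"{g.chrom}\t{g.span[0]}\t{g.span[1]}\t{g.name}\tspan\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\t{s}\t{e}\t{g.name}\texon\n")


def read_splice_scores(path: str) -> list:
    """Parse a TSV of per-variant, per-tool wild-type/mutant splice scores."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["variant_id", "tool", "wt_score", "mut_score"]
        if header != expected:
            raise ValidationError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValidationError(f"{path} line {lineno}: expected 4 columns")
            pairs.append(
                SpliceScorePair(
                    variant_id=cols[0],
                    tool=cols[1],
                    wt_score=float(cols[2]),
                    mut_score=float(cols[3]),
                )
            )
    return pairs


def write_splice_scores(pairs: Iterable[SpliceScorePair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\ttool\twt_score\tmut_score\n")
        for p in pairs:
            fh.write(f"{p.variant_id}\t{p.tool}\t{_format_float(p.wt_score)}\t{_format_float(p.mut_score)}\n")


def read_genotype_table(path: str, records: Optional[Mapping[str, VariantRecord]] = None) -> VariantTable:
    """Parse a long-format genotype TSV: member_id, variant_id, zygosity.

    Used for Sanger-style segregation genotypes.  When ``records`` is given,
    variant ids resolve against it; otherwise minimal records are
    reconstructed from the ``chrom:pos:ref:alt`` ids.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["member_id", "variant_id", "zygosity"]
        if header != expected:
            raise ValidationError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValidationError(f"{path} line {lineno}: expected 3 columns")
            try:
                zyg = Zygosity(cols[2])
            except ValueError:
                raise ValidationError(f"{path} line {lineno}: bad zygosity {cols[2]!r}") from None
            rows.append((cols[0], cols[1], zyg))
    samples: list[str] = []
    for member, _, _ in rows:
        if member not in samples:
            samples.append(member)
    table = VariantTable(samples=samples)
    for _, vid, _ in rows:
        if vid not in table.records:
            rec = records[vid] if records is not None and vid in records else parse_variant_id(vid)
            table.records[vid] = rec
    for member, vid, zyg in rows:
        table.set_call(vid, member, zyg)
    return table


def write_genotype_table(table: VariantTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\tvariant_id\tzygosity\n")
        for rec in table.sorted_records():
            for sample in table.samples:
                zyg = table.call(rec.variant_id, sample)
                if (rec.variant_id, sample) in table.genotypes:
                    fh.write(f"{sample}\t{rec.variant_id}\t{zyg.value}\n")
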