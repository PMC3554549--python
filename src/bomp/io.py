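"""Readers and writers for the study inputs and results.

Input formats: VCF v4.x genotypes (GT field; multiallelic records are
split into biallelic variants on the fly), 6-column TSV gene models
(gene, chrom, start, end, strand, frame; 0-based half-open intervals),
GMT gene sets, 3-column phenotype TSV (sample, status, stratum) and
2-column variant-score TSV. Output: one TSV row per tested functional
group.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    FunctionalGroup,
    GeneMembers,
    GeneModel,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_phenotypes",
    "read_gene_models",
    "read_gene_sets",
    "read_scores",
    "read_vcf_genotypes",
    "build_groups",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_results_tsv",
]

RESULT_COLUMNS = [
    "group", "n_genes", "n_variants", "llr_burden", "llr_position",
    "llr_combined", "p_burden", "p_position", "p_combined", "fdr",
    "burden_threshold",
]


def read_phenotypes(path) -> SampleTable:
    """Read a phenotype TSV with columns sample, status, [stratum]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: phenotype file needs columns {sorted(required)}")
    bad = set(df["status"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: status values must be case/control, found {bad}")
    stratum = df["stratum"].to_numpy() if "stratum" in df.columns else None
    return SampleTable(
        df["sample"].tolist(), (df["status"] == "case").to_numpy(), stratum
    )


def read_gene_models(path) -> dict[str, GeneModel]:
    """Read gene coding models from a 6-column TSV (one row per CDS interval)."""
    df = pd.read_csv(
        path, sep="\t",
        names=["gene", "chrom", "start", "end", "strand", "frame"],
        dtype={"gene": str, "chrom": str, "strand": str},
        comment="#", skiprows=_header_rows(path),
    )
    models = {}
    for gene, sub in df.groupby("gene", sort=False):
        strands = sub["strand"].unique()
        if len(strands) != 1:
            raise ValueError(f"gene {gene}: inconsistent strand annotations")
        models[gene] = GeneModel(
            gene, sub["chrom"].iloc[0], strands[0],
            list(zip(sub["start"].astype(int), sub["end"].astype(int))),
        )
    if not models:
        raise ValueError(f"{path}: no gene models parsed")
    return models


def _header_rows(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.startswith("gene\t") else 0


def read_gene_sets(gmt_path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into (set name, description, gene ids) tuples.

    Genes that later resolve to no loaded variants are retained with empty
    variant lists; duplicate set names or lines without any gene are
    errors.
    """
    sets, seen = [], set()
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description "
                    "and at least one gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{gmt_path}:{lineno}: gene set {name!r} is empty")
            if name in seen:
                raise ValueError(f"{gmt_path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append((name, desc, genes))
    if not sets:
        raise ValueError(f"{gmt_path}: no gene sets parsed")
    return sets


def read_scores(path) -> dict[str, float]:
    """Read 2-column TSV of variant id -> bioinformatics score in [0, 1]."""
    scores = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or row[0].startswith("#") or row[0] == "variant":
                continue
            vid, value = row[0], float(row[1])
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {value} outside [0, 1]")
            scores[vid] = value
    return scores


def read_vcf_genotypes(
    vcf_path,
    sample_table: SampleTable,
    gene_models: dict[str, GeneModel] | None = None,
    scores: dict[str, float] | None = None,
) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix` restricted to the study samples.

    Multiallelic records are split into one biallelic variant per alternate
    allele. Missing genotypes (``./.``) are counted as 0 copies and logged;
    half-calls contribute the called allele count. Variants falling outside
    every gene model are dropped (logged); when no gene models are given,
    each VCF contig is treated as one plus-strand gene spanning the contig
    (contig length required in the header). Variants with no alternate
    allele observed in the study samples are dropped.
    """
    import pysam

    vcf = pysam.VariantFile(str(vcf_path))
    vcf_samples = set(vcf.header.samples)
    for s in sample_table.samples:
        if s not in vcf_samples:
            raise ValueError(f"sample {s!r} in sample table absent from VCF")

    contig_genes: dict[str, GeneModel] = {}
    if gene_models is None:
        for contig in vcf.header.contigs.values():
            if contig.length:
                contig_genes[contig.name] = GeneModel(
                    contig.name, contig.name, "+", [(0, contig.length)]
                )
    else:
        by_chrom: dict[str, list[GeneModel]] = {}
        for model in gene_models.values():
            by_chrom.setdefault(model.chrom, []).append(model)

    status = sample_table.status
    samples = sample_table.samples
    variants, columns = [], []
    n_missing = n_dropped_outside = n_records = 0
    for rec in vcf:
        n_records += 1
        alts = rec.alts or ()
        if gene_models is None:
            model = contig_genes.get(rec.chrom)
            candidates = [model] if model else []
        else:
            candidates = by_chrom.get(rec.chrom, [])
        codon = gene = None
        for model in candidates:
            c = model.codon_of(rec.chrom, rec.pos - 1)
            if c is not None:
                codon, gene = c, model.gene
                break
        if codon is None:
            n_dropped_outside += 1
            continue
        gts = [rec.samples[s].get("GT") or () for s in samples]
        for alt_index, alt in enumerate(alts, start=1):
            col = np.zeros(len(samples), dtype=np.int8)
            missing_here = 0
            for i, gt in enumerate(gts):
                called = [a for a in gt if a is not None]
                if len(called) < max(len(gt), 1):
                    missing_here += 1
                col[i] = sum(1 for a in called if a == alt_index)
            total = int(col.sum())
            if alt_index == 1:
                n_missing += missing_here
            if total < 1:
                continue
            case = int(col[status].sum())
            vid = rec.id if rec.id and len(alts) == 1 else (
                f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            )
            score = scores.get(vid) if scores else None
            variants.append(
                VariantRecord(vid, gene, codon, case, total - case, score)
            )
            columns.append(col)
    vcf.close()

    if not variants:
        raise ValueError(f"{vcf_path}: no biallelic variant with observed "
                         "alternate alleles retained")
    if n_missing:
        logger.info("%s: %d missing genotype calls treated as 0 copies",
                    vcf_path, n_missing)
    if n_dropped_outside:
        logger.info("%s: %d records outside all gene models dropped",
                    vcf_path, n_dropped_outside)
    logger.info("%s: retained %d variants from %d records for %d samples",
                vcf_path, len(variants), n_records, len(samples))
    values = np.stack(columns, axis=1)
    return GenotypeMatrix(samples, variants, values)


def build_groups(gene_sets, gm: GenotypeMatrix, gene_models=None,
                 default_length_codons=500) -> list[FunctionalGroup]:
    """Resolve GMT gene sets against loaded variants into functional groups.

    Gene coding lengths come from ``gene_models`` when available; genes
    unknown to both the models and the VCF get ``default_length_codons``
    and an empty variant list (they contribute nothing to the statistics).
    """
    by_gene: dict[str, list[int]] = {}
    for j, v in enumerate(gm.variants):
        by_gene.setdefault(v.gene, []).append(j)
    groups = []
    for name, _desc, genes in gene_sets:
        members = []
        for gene in genes:
            if gene_models and gene in gene_models:
                length = gene_models[gene].length_codons
            elif gene in by_gene:
                length = max(gm.variants[j].codon_index for j in by_gene[gene]) + 1
            else:
                length = default_length_codons
            members.append(GeneMembers(gene, length,
                                       np.asarray(by_gene.get(gene, []), dtype=int)))
        groups.append(FunctionalGroup(name, members))
    return groups


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Write a genotype matrix (with variant metadata header rows) to TSV."""
    with open(path, "w") as fh:
        fh.write("#variant\tgene\tcodon\tscore\t" + "\t".join(gm.samples) + "\n")
        for j, v in enumerate(gm.variants):
            score = "" if v.score is None else repr(v.score)
            row = "\t".join(str(int(x)) for x in gm.values[:, j])
            fh.write(f"{v.id}\t{v.gene}\t{v.codon_index}\t{score}\t{row}\n")


def read_genotype_tsv(path, sample_table: SampleTable | None = None) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_genotype_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        status = (sample_table.status if sample_table is not None
                  else np.zeros(len(samples), dtype=bool))
        if sample_table is not None and list(sample_table.samples) != samples:
            raise ValueError("sample table does not match genotype TSV columns")
        variants, columns = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            vid, gene, codon, score = fields[:4]
            col = np.array([int(x) for x in fields[4:]], dtype=np.int8)
            case = int(col[status].sum()) if sample_table is not None else 0
            variants.append(VariantRecord(
                vid, gene, int(codon), case, int(col.sum()) - case,
                float(score) if score else None,
            ))
            columns.append(col)
    return GenotypeMatrix(samples, variants, np.stack(columns, axis=1))


def write_results_tsv(results, fdr, path) -> None:
    """One TSV row per functional group, plus the BH FDR column."""
    rows = []
    for res, q in zip(results, fdr):
        rows.append({
            "group": res.group, "n_genes": res.n_genes,
            "n_variants": res.n_variants,
            "llr_burden": f"{res.llr_burden:.6g}",
            "llr_position": f"{res.llr_position:.6g}",
            "llr_combined": f"{res.llr_combined:.6g}",
            "p_burden": f"{res.p_burden:.6g}",
            "p_position": f"{res.p_position:.6g}",
            "p_combined": f"{res.p_combined:.6g}",
            "fdr": f"{q:.6g}",
            "burden_threshold": ("" if res.burden_threshold is None
                                 else f"{res.burden_threshold:.6g}"),
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)
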