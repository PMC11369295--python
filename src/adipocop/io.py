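"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 with GT fields (read back through cyvcf2);
everything else is TSV: expression (genes x samples), phenotypes+covariates,
the GTEx-layout eQTL table, the gene->GO and term->ancestor tables and the
one-column known-gene lists.  Round-tripping a cohort reproduces the
matrices exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING_GENOTYPE, CohortData

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_fixtures",
    "read_cohort",
    "read_eqtl_table",
    "read_known_genes",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GENOTYPE: "./."}


def write_vcf(genotypes: pd.DataFrame, snv_meta: pd.DataFrame, path) -> None:
    """Write a minimal VCF v4.2 with GT genotypes (1-based positions)."""
    path = Path(path)
    samples = list(genotypes.columns)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(snv_meta["chrom"].astype(str)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    G = genotypes.to_numpy()
    for i, vid in enumerate(genotypes.index):
        meta = snv_meta.loc[vid]
        gts = "\t".join(_GT_CODE[int(g)] for g in G[i])
        lines.append(
            f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\t{meta['ref']}\t"
            f"{meta['alt']}\t.\tPASS\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes + SNV metadata from a VCF via cyvcf2.

    Missing calls become -1.  Returns ``(genotypes, snv_meta)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        geno = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING_GENOTYPE
        )
        vid = var.ID or f"{var.CHROM}_{var.POS}"
        rows.append(geno)
        meta.append((vid, str(var.CHROM), var.POS, var.REF, var.ALT[0]))
    vcf.close()
    meta = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    ).set_index("variant_id")
    genotypes = pd.DataFrame(
        np.array(rows, dtype=int), index=meta.index, columns=samples
    )
    return genotypes, meta


def write_fixtures(cohort: CohortData, outdir, eqtl_table=None,
                   gene2go=None, ancestors=None, known_genes=None) -> dict:
    """Write a cohort (and optional annotation fixtures) to ``outdir``.

    Returns the mapping of logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "expression": outdir / "expression.tsv",
        "pheno": outdir / "phenotypes.tsv",
    }
    write_vcf(cohort.genotypes, cohort.snv_meta, paths["vcf"])
    cohort.expression.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    pheno = pd.concat([cohort.phenotypes, cohort.covariates], axis=1)
    pheno.rename_axis("sample_id").to_csv(paths["pheno"], sep="\t")
    (outdir / "snv_meta.tsv").write_text(
        cohort.snv_meta.rename_axis("variant_id").to_csv(sep="\t")
    )
    paths["snv_meta"] = outdir / "snv_meta.tsv"
    if eqtl_table is not None:
        paths["eqtl"] = outdir / "eqtl.tsv"
        eqtl_table.to_csv(paths["eqtl"], sep="\t", index=False)
    if gene2go is not None:
        paths["gene2go"] = outdir / "gene2go.tsv"
        gene2go.to_csv(paths["gene2go"], sep="\t", index=False)
    if ancestors is not None:
        paths["ancestors"] = outdir / "go_ancestors.tsv"
        ancestors.to_csv(paths["ancestors"], sep="\t", index=False)
    if known_genes is not None:
        paths["known_genes"] = outdir / "known_genes.tsv"
        known_genes.to_csv(paths["known_genes"], sep="\t", index=False)
    return paths


def read_cohort(outdir) -> CohortData:
    """Read back a cohort written by :func:`write_fixtures`."""
    outdir = Path(outdir)
    genotypes, meta = read_vcf(outdir / "genotypes.vcf")
    full_meta = pd.read_csv(outdir / "snv_meta.tsv", sep="\t", index_col=0)
    full_meta["chrom"] = full_meta["chrom"].astype(str)
    expression = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(outdir / "phenotypes.tsv", sep="\t", index_col=0)
    pheno_cols = [c for c in ("SAT", "TAT", "aSAT", "VAT") if c in pheno.columns]
    cov_cols = [c for c in pheno.columns if c not in pheno_cols]
    return CohortData(
        expression=expression,
        genotypes=genotypes,
        snv_meta=full_meta.loc[genotypes.index],
        phenotypes=pheno[pheno_cols],
        covariates=pheno[cov_cols],
    )


def read_eqtl_table(path) -> pd.DataFrame:
    """Read a GTEx ``signif_variant_gene_pairs``-layout TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"eQTL table must contain columns {sorted(required)}")
    return df


def read_known_genes(path) -> set[str]:
    """Read a one-column gene-symbol list (case preserved, header optional)."""
    df = pd.read_csv(path, sep="\t")
    return set(df.iloc[:, 0].astype(str))
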