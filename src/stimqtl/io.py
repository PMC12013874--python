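"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF (GT + DS) or plain TSV dosage matrices; expression
and covariates as TSV; gene annotation as BED (0-based half-open, TSS =
start on the + strand and end-1 on the - strand); GWAS summary statistics
as TSV with the header variant_id, chrom, pos, effect_allele, other_allele,
beta, se, p; DAP locus windows as YAML.  All writers use stable float
formatting so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stimqtl.association import CovariateTable, ExpressionMatrix, GenotypeMatrix
from stimqtl.crm import CRM

FLOAT_FMT = "%.10g"

GWAS_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as VCF 4.2 with GT (rounded) and DS fields."""
    path = Path(path)
    contigs = sorted(set(geno.variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stimqtl\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(geno.variants.itertuples()):
            fields = [str(v.chrom), str(v.pos), str(v.variant_id), v.ref_allele,
                      v.alt_allele, ".", "PASS", ".", "GT:DS"]
            col = geno.dosages[:, j]
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with DS (preferred) or GT genotypes into a dosage matrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        rows.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref_allele": var.REF,
                "alt_allele": var.ALT[0] if var.ALT else ".",
            }
        )
        ds = var.format("DS")
        if ds is not None:
            col = ds[:, 0].astype(float)
            col[col < 0] = np.nan
        else:
            gts = np.array(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            col = np.where(gts == 3, 2.0, gts)
            col[gts == 2] = np.nan
        dosages.append(col)
    vcf.close()
    return GenotypeMatrix(
        sample_ids=samples,
        variants=pd.DataFrame(rows),
        dosages=np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
    )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages.T, index=geno.variants["variant_id"], columns=geno.sample_ids)
    meta = geno.variants.set_index("variant_id")[["chrom", "pos", "ref_allele", "alt_allele"]]
    meta.join(df).to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="variant_id")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "ref_allele", "alt_allele"]
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        sample_ids=samples,
        variants=df[meta_cols].copy(),
        dosages=df[samples].to_numpy(dtype=float).T,
    )


# ---------------------------------------------------------------------------
# Expression / covariates / annotation
# ---------------------------------------------------------------------------


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Genes x samples TSV (genes as rows, per the usual matrix convention)."""
    pd.DataFrame(expr.values.T, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="gene_id"
    )


def read_expression_tsv(path, condition: str, gene_annotation: pd.DataFrame) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    anno = gene_annotation[gene_annotation["gene_id"].isin(df.index)].reset_index(drop=True)
    df = df.loc[anno["gene_id"]]
    return ExpressionMatrix(
        sample_ids=list(df.columns),
        gene_ids=list(df.index),
        condition=condition,
        values=df.to_numpy(dtype=float).T,
        gene_annotation=anno,
    )


def write_covariates_tsv(cov: CovariateTable, path) -> None:
    cov.table.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample_id")


def read_covariates_tsv(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t", index_col="sample_id"))


def write_gene_bed(anno: pd.DataFrame, path) -> None:
    """BED6 of gene bodies; TSS recoverable as start (+) or end-1 (-).

    The annotation carries a 1-based TSS; BED is 0-based half-open, so a
    + strand gene spans [tss-1, tss-1+span) and a - strand gene
    [tss-span, tss).
    """
    span = 1000  # nominal gene body length; only the TSS anchor matters
    rows = []
    for r in anno.itertuples():
        if r.strand == "+":
            start, end = r.tss - 1, r.tss - 1 + span
        else:
            start, end = max(r.tss - span, 0), r.tss
        rows.append((r.chrom, start, end, r.gene_id, 0, r.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path) -> pd.DataFrame:
    """Gene annotation from BED: TSS = start (0-based) + 1 on +, end on -."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id", "score", "strand"],
                      dtype={"chrom": str})
    tss = np.where(bed["strand"] == "+", bed["start"] + 1, bed["end"])
    return pd.DataFrame(
        {"gene_id": bed["gene_id"], "chrom": bed["chrom"], "tss": tss.astype(int),
         "strand": bed["strand"]}
    )


# ---------------------------------------------------------------------------
# GWAS summaries, DAP windows, cRM reports
# ---------------------------------------------------------------------------


def write_gwas_tsv(summary: pd.DataFrame, path) -> None:
    summary[GWAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gwas_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_dap_windows(windows: dict, path) -> None:
    """{locus_id: {chrom, start, end, disease}} as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(windows, fh, sort_keys=True)


def read_dap_windows(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def crm_to_dict(crm: CRM, top_nominal_p: dict | None = None) -> dict:
    return {
        "crm_id": crm.crm_id,
        "genes": sorted(crm.genes),
        "conditions": sorted(crm.conditions),
        "labels": dict(sorted(crm.labels.items())),
        "is_multigenic": crm.is_multigenic,
        "is_reqtl": crm.is_reqtl,
        "members": [
            {"gene": g, "condition": c,
             "top_nominal_p": (top_nominal_p or {}).get((g, c))}
            for g, c in sorted(crm.members)
        ],
        "representative": list(crm.representative) if crm.representative else None,
    }


def write_crm_report(crms: list[CRM], path, top_nominal_p: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump([crm_to_dict(c, top_nominal_p) for c in crms], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_crm_report(path) -> list[CRM]:
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for d in raw:
        out.append(
            CRM(
                crm_id=d["crm_id"],
                members=[(m["gene"], m["condition"]) for m in d["members"]],
                labels=d["labels"],
                is_multigenic=d["is_multigenic"],
                is_reqtl=d["is_reqtl"],
                representative=tuple(d["representative"]) if d["representative"] else None,
            )
        )
    return out
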