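"""End-to-end driver: simulate (or load) a cohort and run the full analysis.

Stages: genotype QC -> covariate residualization -> per-condition
gene-level permutation scans -> BH FDR -> EAP construction (with the
extended catalogue) -> monogenic and multigenic cRM clustering -> activity
labels and reQTL flags -> mechanism census -> DAP-EAP colocalization.
Every output carries a provenance manifest (config hash, seeds, package
version) and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import stimqtl
from stimqtl import io as sio
from stimqtl.association import (
    bh_fdr,
    gene_level_permutation_p,
    nominal_scan,
    qc_genotypes,
    residualize_expression,
    select_expression_pcs,
)
from stimqtl.crm import (
    CRM,
    CONDITION_ORDER,
    assign_label,
    default_matcher,
    extend_catalogue,
    merge_monogenic,
    merge_multigenic,
    set_representative,
    summarize_catalogue,
)
from stimqtl.eap import AssociationPattern, build_dap, build_eap
from stimqtl.gwascoloc import annotate_bh, match_dap_to_catalogue, opposite_direction_scan
from stimqtl.mechanisms import (
    DetectabilityRule,
    classify,
    detectability_floor,
    detectable,
    mechanism_census,
)
from stimqtl.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_gwas_summary,
    standard_architectures,
)
from stimqtl.theta import TraitData, theta_permutation_p

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and seeds for one pipeline run.

    Defaults are the analysis constants of the study design this package
    reimplements: +/- 1 Mb cis window, 10,000 permutations for gene-level
    adjusted p, FDR <= 0.05, |theta| >= 0.6 with at least 50 SNPs, SNP
    selection at p < 0.05.  Overrides are recorded in the manifest.
    """

    window_bp: int = 1_000_000
    n_perm_scan: int = 10_000
    fdr: float = 0.05
    theta_min: float = 0.6
    theta_p_max: float = 0.05
    min_snps: int = 50
    p_select: float = 0.05
    weight_exponent: float = 2.0
    n_perm_theta_cluster: int = 200
    n_perm_theta_report: int = 1000
    dap_window_bp: int = 100_000  # half-width around the top GWAS SNP
    pc_candidates: tuple[int, ...] = ()  # expression-PC counts to try (empty: skip)
    pc_scan_subsample: int = 50
    require_edge_p: bool = True
    condition_order: tuple[str, ...] = CONDITION_ORDER
    seed: int = 0
    simulation: SimulationConfig | None = None
    gwas_n_cases: int = 2000
    gwas_n_controls: int = 2000
    gwas_odds_ratio: float = 1.6
    # paths for a non-simulated run (VCF/TSVs); unused with --simulate
    genotype_path: str | None = None
    expression_paths: dict | None = None
    covariate_path: str | None = None
    annotation_path: str | None = None
    gwas_paths: dict | None = None
    dap_windows_path: str | None = None

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "PipelineConfig":
        """A small configuration that exercises every stage in about a minute.

        Windows keep a realistic variant density (the 50-SNP floor for theta
        needs enough background variants), but permutation counts are
        reduced from the full-scale defaults.
        """
        sim = SimulationConfig(
            n_individuals=250, n_variants=1800, n_genes=8, ld_block_size=20,
            ld_within_block=0.9, variant_spacing_bp=1_000, hidden_factor_sd=0.4,
            seed=seed,
        )
        return cls(
            n_perm_scan=300, n_perm_theta_cluster=150, n_perm_theta_report=200,
            dap_window_bp=400_000, seed=seed, simulation=sim,
        )

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the whole analysis and write all artifacts under ``outdir``.

    Returns a results dictionary with the eQTL table, catalogue, cRMs,
    mechanism census and colocalization reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ----- inputs -------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        if not sim.architectures:
            probe = SimulationConfig(**{**dataclasses.asdict(sim), "architectures": []})
            from stimqtl.simulate import default_gene_annotation, simulate_genotypes

            geno_probe = simulate_genotypes(probe)
            anno_probe = default_gene_annotation(probe)
            sim = dataclasses.replace(
                sim, architectures=standard_architectures(geno_probe, anno_probe, sim.conditions)
            )
        geno, cov, anno, expr_by_cond, truth = simulate_cohort(sim)
        shared_gene = sim.architectures[0]
        gwas = simulate_gwas_summary(
            sim, shared_gene.causal_variant_id, config.gwas_odds_ratio,
            config.gwas_n_cases, config.gwas_n_controls, seed=config.seed,
        )
        truth.gwas = {
            "causal_variant": shared_gene.causal_variant_id,
            "odds_ratio": config.gwas_odds_ratio,
            "shared_eqtl_gene": shared_gene.gene_id,
        }
        gwas_by_disease = {"disease_sim": gwas}
        sio.write_vcf(geno, outdir / "genotypes.vcf")
        sio.write_covariates_tsv(cov, outdir / "covariates.tsv")
        sio.write_gene_bed(anno, outdir / "genes.bed")
        for cond, em in expr_by_cond.items():
            sio.write_expression_tsv(em, outdir / f"expression_{cond}.tsv")
        sio.write_gwas_tsv(gwas, outdir / "gwas_disease_sim.tsv")
        truth.effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False,
                             float_format=sio.FLOAT_FMT)
        dap_windows = None
    else:
        geno = sio.read_vcf(config.genotype_path)
        anno = sio.read_gene_bed(config.annotation_path)
        cov = sio.read_covariates_tsv(config.covariate_path)
        expr_by_cond = {
            cond: sio.read_expression_tsv(path, cond, anno)
            for cond, path in (config.expression_paths or {}).items()
        }
        gwas_by_disease = {
            d: sio.read_gwas_tsv(p) for d, p in (config.gwas_paths or {}).items()
        }
        truth = None
        dap_windows = (
            sio.read_dap_windows(config.dap_windows_path) if config.dap_windows_path else None
        )

    # ----- QC + residualization ----------------------------------------
    geno = qc_genotypes(geno)
    conditions = [c for c in config.condition_order if c in expr_by_cond]
    pc_reports = {}
    resid_by_cond = {}
    for cond in conditions:
        em = expr_by_cond[cond]
        cov_c = cov
        if config.pc_candidates:
            cov_c, pc_reports[cond] = select_expression_pcs(
                em, cov, geno, candidate_range=config.pc_candidates,
                scan_subsample=config.pc_scan_subsample,
                n_perm=min(200, config.n_perm_scan), seed=config.seed, fdr=config.fdr,
            )
        resid_by_cond[cond] = residualize_expression(em, cov_c)

    # ----- gene-level scans + FDR ---------------------------------------
    scan_rows = []
    for cond in conditions:
        em = resid_by_cond[cond]
        for gene in em.gene_ids:
            res = gene_level_permutation_p(
                geno, em, gene, window_bp=config.window_bp,
                n_perm=config.n_perm_scan, seed=config.seed,
            )
            scan_rows.append(res)
    scans = pd.DataFrame(scan_rows)
    scans["q"] = np.nan
    for cond in conditions:  # conditions are separate analyses
        m = scans["condition"] == cond
        scans.loc[m, "q"] = bh_fdr(scans.loc[m, "adjusted_p"].to_numpy())
    scans.to_csv(outdir / "eqtl_table.tsv", sep="\t", index=False, float_format=sio.FLOAT_FMT)
    significant = {
        (r.gene_id, r.condition) for r in scans.itertuples() if r.q <= config.fdr
    }

    # ----- EAPs ----------------------------------------------------------
    sig_genes = sorted({g for g, _ in significant})
    eaps: dict[tuple[str, str], AssociationPattern] = {}
    nonsig_eaps: dict[tuple[str, str], AssociationPattern] = {}
    trait_data: dict[tuple[str, str], TraitData] = {}
    top_p: dict[tuple[str, str], float] = {}
    eapdir = outdir / "eaps"
    eapdir.mkdir(exist_ok=True)
    for cond in conditions:
        em = resid_by_cond[cond]
        for gene in sig_genes:
            chrom, tss = em.tss(gene)
            records = nominal_scan(geno, em, gene, window_bp=config.window_bp)
            eap = build_eap(records, gene, cond, chrom, tss, config.window_bp)
            key = (gene, cond)
            top_p[key] = float(records["p"].min())
            win = geno.window(chrom, tss, config.window_bp)
            keep = win.variants["variant_id"].isin(records["variant_id"]).to_numpy()
            trait_data[key] = TraitData(
                dosages=win.dosages[:, keep],
                phenotype=em.gene(gene),
                variant_ids=list(win.variants["variant_id"][keep]),
            )
            (eaps if key in significant else nonsig_eaps)[key] = eap
            eap.to_tsv(eapdir / f"eap_{gene}_{cond}.tsv")
    extended, rescued = extend_catalogue(
        eaps, nonsig_eaps, theta_min=config.theta_min,
        min_snps=config.min_snps, weight_exponent=config.weight_exponent,
        p_threshold=config.p_select,
    )

    # ----- cRM clustering ------------------------------------------------
    def cluster_matcher(a: AssociationPattern, b: AssociationPattern):
        da = trait_data.get((a.trait_id, a.context))
        db = trait_data.get((b.trait_id, b.context))
        if config.require_edge_p and (da is not None or db is not None):
            return theta_permutation_p(
                a, b, da, db, n_perm=config.n_perm_theta_cluster, seed=config.seed,
                min_snps=config.min_snps, weight_exponent=config.weight_exponent,
                p_threshold=config.p_select, assume_harmonized=False,
            )
        return default_matcher(
            min_snps=config.min_snps, weight_exponent=config.weight_exponent,
            p_threshold=config.p_select,
        )(a, b)

    monogenic: list[CRM] = []
    for gene in sorted({g for g, _ in eaps}):
        gene_eaps = {k: v for k, v in eaps.items() if k[0] == gene}
        crms = merge_monogenic(
            gene_eaps, cluster_matcher, config.theta_min, config.theta_p_max,
            require_p=config.require_edge_p, crm_prefix="crm",
        )
        for crm in crms:
            assign_label(crm, significant, tuple(conditions))
            set_representative(crm, top_p)
        monogenic.extend(crms)
    tss_map = {g: (str(r["chrom"]), int(r["tss"]))
               for g, r in anno.set_index("gene_id").iterrows()}
    all_crms = merge_multigenic(
        monogenic, eaps, tss_map, cluster_matcher, config.theta_min,
        config.theta_p_max, require_p=config.require_edge_p, window_bp=config.window_bp,
    )
    for crm in all_crms:
        assign_label(crm, significant, tuple(conditions))
        set_representative(crm, top_p)
    sio.write_crm_report(all_crms, outdir / "crm_report.json", top_p)
    summary = summarize_catalogue(all_crms)

    # ----- mechanisms ----------------------------------------------------
    floor = {}
    for cond in conditions:
        egene_means = [expr_by_cond[cond].gene(g).mean() for g in sig_genes] or [0.0]
        floor[cond] = detectability_floor(np.array(egene_means))
    calls = []
    for gene in sig_genes:
        det = {
            cond: detectable(
                expr_by_cond[cond].gene(gene),
                DetectabilityRule(min_mean_level=floor[cond]),
            )
            for cond in conditions
        }
        calls.extend(classify(gene, all_crms, det, tuple(conditions)))
    census = (
        mechanism_census(calls) if calls else pd.DataFrame(
            columns=["mechanism", "count", "fraction"])
    )
    census.to_csv(outdir / "mechanism_census.tsv", sep="\t", index=False,
                  float_format=sio.FLOAT_FMT)

    # ----- DAP-EAP colocalization ---------------------------------------
    coloc_rows = []
    all_reports = []
    for disease, gw in sorted(gwas_by_disease.items()):
        if dap_windows and disease in dap_windows:
            w = dap_windows[disease]
        else:
            top = gw.loc[gw["p"].idxmin()]
            w = {"chrom": str(top["chrom"]),
                 "start": int(top["pos"]) - config.dap_window_bp,
                 "end": int(top["pos"]) + config.dap_window_bp}
        try:
            dap = build_dap(gw, f"locus_{disease}", disease, w["chrom"], w["start"], w["end"])
        except ValueError:
            continue
        reports = match_dap_to_catalogue(
            dap, extended, trait_data, config.theta_min, config.theta_p_max,
            config.min_snps, n_perm=config.n_perm_theta_report, seed=config.seed,
            resting_condition=conditions[0],
        )
        annotate_bh(reports)
        all_reports.extend(reports)
        coloc_rows.extend(dataclasses.asdict(r) for r in reports)
    coloc = pd.DataFrame(coloc_rows)
    coloc.to_csv(outdir / "coloc_report.tsv", sep="\t", index=False,
                 float_format=sio.FLOAT_FMT)
    opposite = opposite_direction_scan(all_reports)
    with open(outdir / "opposite_direction.json", "w") as fh:
        json.dump(_as_jsonable(opposite), fh, indent=1, sort_keys=True)
        fh.write("\n")

    # ----- manifest ------------------------------------------------------
    manifest = {
        "package_version": stimqtl.__version__,
        "config": _as_jsonable(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_significant_eqtls": len(significant),
        "n_crms": summary.get("n_crms", 0),
        "catalogue_summary": summary,
        "n_rescued_eaps": int(sum(rescued.values())),
        "expression_pc_selection": pc_reports,
        "n_coloc_rows": len(coloc_rows),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_as_jsonable(manifest), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "scans": scans,
        "significant": significant,
        "eaps": eaps,
        "extended": extended,
        "crms": all_crms,
        "summary": summary,
        "mechanism_calls": calls,
        "census": census,
        "coloc": coloc,
        "coloc_reports": all_reports,
        "opposite_direction": opposite,
        "truth": truth,
        "manifest": manifest,
        "trait_data": trait_data,
    }
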