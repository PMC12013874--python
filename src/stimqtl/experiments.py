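"""Repeatable validation experiments for the pipeline's statistical claims.

Each function simulates cohorts with known ground truth, runs the package's
own operations, and measures an operating characteristic: theta's power to
recognize a shared causal variant and its specificity against distinct
variants, permutation-p calibration under the null, end-to-end eQTL
recovery, per-mechanism classification accuracy, and DAP-EAP matching
rates.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from stimqtl.association import (
    CovariateTable,
    bh_fdr,
    gene_level_permutation_p,
    nominal_scan,
    residualize_expression,
)
from stimqtl.crm import assign_label, merge_monogenic
from stimqtl.eap import build_dap, build_eap
from stimqtl.gwascoloc import match_dap_to_catalogue, opposite_direction_scan
from stimqtl.mechanisms import (
    DetectabilityRule,
    classify,
    detectability_floor,
    detectable,
)
from stimqtl.simulate import (
    PlantedEffect,
    SimulationConfig,
    nearest_variant,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_summary,
)
from stimqtl.theta import TraitData, compute_theta, theta_permutation_p


def _eap_and_data(geno, expr, gene_id, window_bp=1_000_000):
    chrom, tss = expr.tss(gene_id)
    records = nominal_scan(geno, expr, gene_id, window_bp=window_bp)
    eap = build_eap(records, gene_id, expr.condition, chrom, tss, window_bp)
    win = geno.window(chrom, tss, window_bp)
    keep = win.variants["variant_id"].isin(records["variant_id"]).to_numpy()
    data = TraitData(
        dosages=win.dosages[:, keep],
        phenotype=expr.gene(gene_id),
        variant_ids=list(win.variants["variant_id"][keep]),
    )
    return eap, data


# ---------------------------------------------------------------------------
# theta power / specificity / calibration
# ---------------------------------------------------------------------------


def theta_power_experiment(
    n_reps: int = 100,
    seed: int = 0,
    shared: bool = True,
    n: int = 300,
    m: int = 800,
    beta: float = 0.8,
    min_snps: int = 50,
) -> dict:
    """Fraction of trait pairs with |theta| >= 0.6.

    ``shared=True`` plants the same common causal variant in both traits
    (a strong cis-eQTL, ~15-25% variance explained); ``shared=False``
    plants the second trait on a variant three LD blocks away (cross-block
    r^2 ~ 0), the configuration theta must reject.
    """
    hits, defined, thetas = 0, 0, []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_individuals=n, n_variants=m, n_genes=2, ld_block_size=25,
            ld_within_block=0.9, variant_spacing_bp=1_000,
            conditions=("CTRL",), covariate_spec={}, n_hidden_factors=0,
            seed=seed + 1000 * rep,
        )
        geno = simulate_genotypes(cfg)
        import pandas as pd

        tss = int(geno.variants.loc[m // 2, "pos"])
        anno = pd.DataFrame(
            {"gene_id": ["geneA", "geneB"], "chrom": cfg.chrom,
             "tss": [tss, tss], "strand": "+"}
        )
        v1 = nearest_variant(geno, cfg.chrom, tss, maf_min=0.2)
        block1 = int(geno.variants.set_index("variant_id").loc[v1, "ld_block"])
        v2 = v1 if shared else nearest_variant(
            geno, cfg.chrom,
            tss + 3 * cfg.ld_block_size * cfg.variant_spacing_bp,
            exclude_block=block1, maf_min=0.2,
        )
        arch = [
            PlantedEffect("geneA", v1, ("CTRL",), {"CTRL": beta}),
            PlantedEffect("geneB", v2, ("CTRL",), {"CTRL": beta}),
        ]
        expr, _ = simulate_expression(
            geno, dataclasses.replace(cfg, architectures=arch), gene_annotation=anno
        )
        em = expr["CTRL"]
        eap_a, _ = _eap_and_data(geno, em, "geneA")
        eap_b, _ = _eap_and_data(geno, em, "geneB")
        res = compute_theta(eap_a, eap_b, min_snps=min_snps)
        if res.defined:
            defined += 1
            thetas.append(res.theta)
            hits += abs(res.theta) >= 0.6
    return {
        "n_reps": n_reps, "n_defined": defined, "n_matching": hits,
        "rate": hits / n_reps, "median_theta": float(np.median(thetas)) if thetas else None,
    }


def theta_null_calibration(
    n_pairs: int = 500,
    n_perm: int = 200,
    seed: int = 0,
    n: int = 300,
    m: int = 800,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the theta permutation p under trait independence.

    One genotype panel is shared across pairs; each pair draws two
    independent Gaussian phenotypes, builds both patterns, and runs the
    two-sided (both-trait) permutation scheme.
    """
    cfg = SimulationConfig(
        n_individuals=n, n_variants=m, n_genes=2, ld_block_size=25,
        ld_within_block=0.9, variant_spacing_bp=1_000, conditions=("CTRL",), seed=seed,
    )
    geno = simulate_genotypes(cfg)
    rng = np.random.default_rng(seed + 1)
    pvals = []
    for pair in range(n_pairs):
        data_a = TraitData(geno.dosages, rng.standard_normal(n))
        data_b = TraitData(geno.dosages, rng.standard_normal(n))
        pat_a = _pattern_from_data(geno, data_a, "traitA")
        pat_b = _pattern_from_data(geno, data_b, "traitB")
        res = theta_permutation_p(
            pat_a, pat_b, data_a, data_b, n_perm=n_perm,
            seed=seed + 7 * pair + 3, assume_harmonized=True,
        )
        if res.defined and res.p_perm is not None:
            pvals.append(res.p_perm)
    pvals = np.array(pvals)
    rate = float(np.mean(pvals <= alpha)) if len(pvals) else float("nan")
    ks = stats.kstest(pvals, "uniform") if len(pvals) else None
    return {
        "n_pairs": n_pairs, "n_defined": int(len(pvals)),
        "rejection_rate": rate, "alpha": alpha,
        "ks_p": float(ks.pvalue) if ks else None,
    }


def scan_null_calibration(
    n_genes: int = 200,
    n_perm: int = 500,
    seed: int = 0,
    n: int = 300,
    m: int = 200,
) -> dict:
    """KS uniformity of gene-level permutation-adjusted p under the null."""
    cfg = SimulationConfig(
        n_individuals=n, n_variants=m, n_genes=n_genes, ld_block_size=20,
        ld_within_block=0.9, variant_spacing_bp=1_000, conditions=("CTRL",),
        covariate_spec={}, n_hidden_factors=0, seed=seed,
    )
    geno = simulate_genotypes(cfg)
    expr, _ = simulate_expression(geno, cfg)
    em = expr["CTRL"]
    adj = [
        gene_level_permutation_p(geno, em, g, n_perm=n_perm, seed=seed + i)["adjusted_p"]
        for i, g in enumerate(em.gene_ids)
    ]
    ks = stats.kstest(adj, "uniform")
    return {"n_genes": n_genes, "ks_p": float(ks.pvalue), "adjusted_p": adj}


def _pattern_from_data(geno, data: TraitData, trait_id: str, context: str = "CTRL"):
    """AssociationPattern over the whole panel for a raw phenotype."""
    import pandas as pd

    from stimqtl.eap import AssociationPattern

    score, p = data.pattern_scores()
    v = geno.variants
    table = pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy(),
            "chrom": v["chrom"].astype(str).to_numpy(),
            "pos": v["pos"].to_numpy(),
            "effect_allele": v["alt_allele"].to_numpy(),
            "other_allele": v["ref_allele"].to_numpy(),
            "beta": np.where(score >= 0, 1.0, -1.0),
            "p": p,
            "score": score,
        }
    )
    return AssociationPattern(
        kind="eap", trait_id=trait_id, context=context, chrom=str(v["chrom"].iloc[0]),
        start=int(v["pos"].min()), end=int(v["pos"].max()), table=table,
    )


# ---------------------------------------------------------------------------
# End-to-end eQTL recovery
# ---------------------------------------------------------------------------


def eqtl_recovery_experiment(
    n_planted: int = 100,
    n_null: int = 100,
    n: int = 300,
    beta: float = 0.5,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> dict:
    """Sensitivity and empirical FDR of the scan + permutation + BH chain.

    One cohort carries ``n_planted`` genes with a cis-eQTL of ``beta`` (in
    noise-sd units) at a common variant near the TSS and ``n_null`` genes
    with no genetic effect; covariate confounding is on and removed by
    residualization.  Discovery at gene-level q <= ``fdr``.
    """
    n_genes = n_planted + n_null
    cfg = SimulationConfig(
        n_individuals=n, n_variants=400, n_genes=n_genes, ld_block_size=20,
        ld_within_block=0.9, variant_spacing_bp=1_000, conditions=("CTRL",),
        n_hidden_factors=0, seed=seed,
    )
    geno = simulate_genotypes(cfg)
    from stimqtl.simulate import default_gene_annotation

    anno = default_gene_annotation(cfg)
    rng = np.random.default_rng(seed + 2)
    planted = set(rng.choice(anno["gene_id"], size=n_planted, replace=False))
    arch, used = [], set()
    for gene in sorted(planted):
        tss = int(anno.set_index("gene_id").loc[gene, "tss"])
        vid = nearest_variant(geno, cfg.chrom, tss, exclude_ids=used, maf_min=0.2)
        used.add(vid)
        arch.append(PlantedEffect(gene, vid, ("CTRL",), {"CTRL": beta}))
    expr, _ = simulate_expression(
        geno, dataclasses.replace(cfg, architectures=arch), gene_annotation=anno
    )
    cov = simulate_covariates(cfg, geno.sample_ids)
    em = residualize_expression(expr["CTRL"], cov)
    adj = np.array([
        gene_level_permutation_p(geno, em, g, n_perm=n_perm, seed=seed + i)["adjusted_p"]
        for i, g in enumerate(em.gene_ids)
    ])
    q = bh_fdr(adj)
    called = {g for g, qv in zip(em.gene_ids, q) if qv <= fdr}
    tp = len(called & planted)
    fp = len(called - planted)
    return {
        "n_planted": n_planted, "n_null": n_null,
        "sensitivity": tp / n_planted,
        "empirical_fdr": fp / max(len(called), 1),
        "n_called": len(called),
    }


# ---------------------------------------------------------------------------
# Mechanism recovery
# ---------------------------------------------------------------------------


def _single_gene_cohort(mechanism: str, seed: int, n: int = 300, m: int = 700):
    """One gene planted with the requested mechanism on its own panel."""
    cfg = SimulationConfig(
        n_individuals=n, n_variants=m, n_genes=1, ld_block_size=20,
        ld_within_block=0.9, variant_spacing_bp=1_000, n_hidden_factors=0,
        seed=seed,
    )
    geno = simulate_genotypes(cfg)
    import pandas as pd

    tss = int(geno.variants.loc[m // 2, "pos"])
    anno = pd.DataFrame({"gene_id": ["g"], "chrom": cfg.chrom, "tss": [tss],
                         "strand": ["+"]})
    v1 = nearest_variant(geno, cfg.chrom, tss, maf_min=0.2)
    block1 = int(geno.variants.set_index("variant_id").loc[v1, "ld_block"])
    beta = 0.8
    if mechanism == "mech1_low_expression":
        arch = PlantedEffect("g", v1, ("TCR", "LPS", "R848"),
                             {c: beta for c in ("TCR", "LPS", "R848")},
                             "mech1_low_expression", suppressed_conditions=("CTRL",))
    elif mechanism == "mech2_effect_loss":
        arch = PlantedEffect("g", v1, ("LPS", "R848"),
                             {c: beta for c in ("LPS", "R848")}, "mech2_effect_loss")
    elif mechanism == "mech3_switch":
        v2 = nearest_variant(geno, cfg.chrom, tss + 4 * 20 * 1_000,
                             exclude_block=block1, maf_min=0.2)
        arch = PlantedEffect("g", v1, ("CTRL",), {"CTRL": beta}, "mech3_switch",
                             second_causal_variant_id=v2,
                             second_affected_conditions=("LPS", "R848"),
                             second_beta=beta)
    else:
        raise ValueError(mechanism)
    expr, _ = simulate_expression(
        geno, dataclasses.replace(cfg, architectures=[arch]), gene_annotation=anno
    )
    return geno, expr


def _classify_single_gene(geno, expr, n_perm_scan, n_perm_theta, seed, fdr=0.05):
    """Full per-gene path: scans, FDR-free adjusted-p threshold, cRMs, calls."""
    conditions = ("CTRL", "TCR", "LPS", "R848")
    cov = CovariateTable(
        simulate_covariates(
            SimulationConfig(seed=seed), geno.sample_ids
        ).table
    )
    adj = {}
    resid = {}
    for cond in conditions:
        em = residualize_expression(expr[cond], cov)
        resid[cond] = em
        adj[cond] = gene_level_permutation_p(
            geno, em, "g", n_perm=n_perm_scan, seed=seed)["adjusted_p"]
    # single-gene cohorts: gene-level adjusted p stands in for the q-value
    significant = {("g", c) for c in conditions if adj[c] <= fdr}
    eaps, data = {}, {}
    for cond in conditions:
        if ("g", cond) in significant:
            eaps[("g", cond)], data[("g", cond)] = _eap_and_data(geno, resid[cond], "g")

    def matcher(a, b):
        return theta_permutation_p(
            a, b, data.get((a.trait_id, a.context)), data.get((b.trait_id, b.context)),
            n_perm=n_perm_theta, seed=seed, assume_harmonized=False,
        )

    crms = merge_monogenic(eaps, matcher, require_p=True) if eaps else []
    for crm in crms:
        assign_label(crm, significant)
    floor = detectability_floor(
        np.array([expr[c].gene("g").mean() for c in conditions]), 10.0
    )
    det = {
        c: detectable(expr[c].gene("g"), DetectabilityRule(min_mean_level=min(floor, 1.0)))
        for c in conditions
    }
    return classify("g", crms, det), crms, significant


def mechanism_recovery_experiment(
    n_per_class: int = 100,
    seed: int = 0,
    n_perm_scan: int = 300,
    n_perm_theta: int = 150,
) -> dict:
    """Per-class recovery of the three planted mechanisms.

    A gene counts as correctly classified when the call for its designed
    inactive condition matches the planted mechanism (mechanism 3: any
    module-switch call across its split cRMs).
    """
    results = {}
    census_counts = {1: 0, 2: 0, 3: 0, "unclassified": 0}
    for mech_idx, mechanism in (
        (1, "mech1_low_expression"), (2, "mech2_effect_loss"), (3, "mech3_switch")
    ):
        correct = 0
        for rep in range(n_per_class):
            rep_seed = seed + 10_000 * mech_idx + 17 * rep
            geno, expr = _single_gene_cohort(mechanism, rep_seed)
            calls, crms, significant = _classify_single_gene(
                geno, expr, n_perm_scan, n_perm_theta, rep_seed
            )
            for call in calls:
                census_counts[call.mechanism if call.mechanism in (1, 2, 3)
                              else "unclassified"] += 1
            if mech_idx == 1:
                correct += any(c.condition == "CTRL" and c.mechanism == 1 for c in calls)
            elif mech_idx == 2:
                ctrl_calls = [c for c in calls if c.condition == "CTRL"]
                correct += bool(ctrl_calls) and all(c.mechanism == 2 for c in ctrl_calls)
            else:
                correct += len(crms) >= 2 and any(c.mechanism == 3 for c in calls)
        results[mechanism] = correct / n_per_class
    total = sum(census_counts.values())
    results["census_fractions"] = {
        str(k): v / max(total, 1) for k, v in census_counts.items()
    }
    results["n_per_class"] = n_per_class
    return results


# ---------------------------------------------------------------------------
# GWAS DAP-EAP colocalization
# ---------------------------------------------------------------------------


def gwas_coloc_experiment(
    n_reps: int = 100,
    seed: int = 0,
    n: int = 300,
    m: int = 4600,
    n_cases: int = 2000,
    n_controls: int = 2000,
    odds_ratio: float = 1.6,
    n_perm: int = 150,
    null_mode: bool = False,
) -> dict:
    """DAP-EAP matching against planted truth.

    Each replicate builds a cohort with a sign-flip gene (effect +beta at
    rest, -beta after LPS, same variant) whose causal variant also drives a
    simulated case/control GWAS, plus a stimulation-only gene at a distant
    locus sharing its variant with a second GWAS.  Measured: the shared
    locus is matched; the matched rows carry opposite theta signs; the
    stimulation-only locus is flagged reqtl-specific.  With
    ``null_mode=True`` the GWAS causal variant is drawn from an LD block
    carrying no eQTL, and the fraction of replicates with zero reported
    rows is measured.
    """
    import pandas as pd

    matched = opposite = reqtl = zero_rows = 0
    half_window = 250_000
    for rep in range(n_reps):
        rep_seed = seed + 977 * rep
        cfg = SimulationConfig(
            n_individuals=n, n_variants=m, n_genes=2, ld_block_size=20,
            ld_within_block=0.9, variant_spacing_bp=250,
            conditions=("CTRL", "LPS"), covariate_spec={}, n_hidden_factors=0,
            seed=rep_seed,
        )
        geno = simulate_genotypes(cfg)
        # loci spaced so no DAP window reaches the other locus's peak
        tss_a, tss_b = (int(geno.variants.loc[1120, "pos"]),
                        int(geno.variants.loc[3520, "pos"]))
        anno = pd.DataFrame(
            {"gene_id": ["geneA", "geneB"], "chrom": cfg.chrom,
             "tss": [tss_a, tss_b], "strand": "+"}
        )
        v_a = nearest_variant(geno, cfg.chrom, tss_a, maf_min=0.2)
        v_b = nearest_variant(geno, cfg.chrom, tss_b, maf_min=0.2, exclude_ids={v_a})
        arch = [
            PlantedEffect("geneA", v_a, ("CTRL", "LPS"),
                          {"CTRL": 1.0, "LPS": -1.0}, "sign_flip"),
            PlantedEffect("geneB", v_b, ("LPS",), {"LPS": 1.0}, "mech2_effect_loss"),
        ]
        expr, _ = simulate_expression(
            geno, dataclasses.replace(cfg, architectures=arch), gene_annotation=anno
        )
        catalogue, data = {}, {}
        for cond in ("CTRL", "LPS"):
            for gene in ("geneA", "geneB"):
                if gene == "geneB" and cond == "CTRL":
                    continue  # stimulation-only gene: no resting eQTL
                eap, td = _eap_and_data(geno, expr[cond], gene)
                catalogue[(gene, cond)] = eap
                data[(gene, cond)] = td
        vmeta = geno.variants.set_index("variant_id")
        if null_mode:
            # causal in a block with no eQTL, between the two genes
            blocks_used = {int(vmeta.loc[v_a, "ld_block"]), int(vmeta.loc[v_b, "ld_block"])}
            v_null = nearest_variant(
                geno, cfg.chrom, (tss_a + tss_b) // 2, maf_min=0.2,
                exclude_ids={v_a, v_b},
            )
            tried = {v_a, v_b, v_null}
            while int(vmeta.loc[v_null, "ld_block"]) in blocks_used:
                v_null = nearest_variant(
                    geno, cfg.chrom, int(vmeta.loc[v_null, "pos"]) + 25_000,
                    maf_min=0.2, exclude_ids=tried,
                )
                tried.add(v_null)
            null_idx = int(geno.variants.index[geno.variants["variant_id"] == v_null][0])
            gwas = simulate_gwas_summary(cfg, v_null, odds_ratio,
                                         min(n_cases, 1000), min(n_controls, 1000),
                                         seed=rep_seed + 1, prevalence=0.25,
                                         variant_range=(null_idx - 1040, null_idx + 1040))
            pos = int(vmeta.loc[v_null, "pos"])
            dap = build_dap(gwas, "locus_null", "disease", cfg.chrom,
                            pos - half_window, pos + half_window)
            rows = match_dap_to_catalogue(dap, catalogue, data, n_perm=n_perm,
                                          seed=rep_seed + 2)
            zero_rows += len(rows) == 0
            continue
        idx_a = int(geno.variants.index[geno.variants["variant_id"] == v_a][0])
        gwas_a = simulate_gwas_summary(cfg, v_a, odds_ratio,
                                       min(n_cases, 1000), min(n_controls, 1000),
                                       seed=rep_seed + 1, prevalence=0.25,
                                       variant_range=(idx_a - 1040, idx_a + 1040))
        pos_a = int(vmeta.loc[v_a, "pos"])
        dap_a = build_dap(gwas_a, "locusA", "disease", cfg.chrom,
                          pos_a - half_window, pos_a + half_window)
        rows_a = match_dap_to_catalogue(dap_a, catalogue, data, n_perm=n_perm,
                                        seed=rep_seed + 2)
        gene_a_rows = [r for r in rows_a if r.gene_id == "geneA"]
        matched += len(gene_a_rows) >= 1
        opposite += any(f["gene_id"] == "geneA"
                        for f in opposite_direction_scan(gene_a_rows))
        idx_b = int(geno.variants.index[geno.variants["variant_id"] == v_b][0])
        gwas_b = simulate_gwas_summary(cfg, v_b, odds_ratio,
                                       min(n_cases, 1000), min(n_controls, 1000),
                                       seed=rep_seed + 3, prevalence=0.25,
                                       variant_range=(idx_b - 1040, idx_b + 1040))
        pos_b = int(vmeta.loc[v_b, "pos"])
        dap_b = build_dap(gwas_b, "locusB", "disease", cfg.chrom,
                          pos_b - half_window, pos_b + half_window)
        rows_b = match_dap_to_catalogue(dap_b, catalogue, data, n_perm=n_perm,
                                        seed=rep_seed + 4)
        gene_b_rows = [r for r in rows_b if r.gene_id == "geneB"]
        reqtl += bool(gene_b_rows) and all(r.reqtl_specific for r in gene_b_rows)
    if null_mode:
        return {"n_reps": n_reps, "zero_row_rate": zero_rows / n_reps}
    return {
        "n_reps": n_reps,
        "match_rate": matched / n_reps,
        "opposite_direction_rate": opposite / n_reps,
        "reqtl_specific_rate": reqtl / n_reps,
    }
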