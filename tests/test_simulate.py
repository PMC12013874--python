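"""Synthetic cohort generator: determinism, MAF/LD structure, planted truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimqtl.association import _simple_regression
from stimqtl.simulate import (
    PlantedEffect,
    SimulationConfig,
    default_gene_annotation,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas_summary,
    standard_architectures,
)


class TestGenotypes:
    def test_same_seed_identical_matrices(self, small_config, small_geno):
        again = simulate_genotypes(small_config)
        np.testing.assert_array_equal(small_geno.dosages, again.dosages)
        pd.testing.assert_frame_equal(small_geno.variants, again.variants)

    def test_different_seed_differs(self, small_config, small_geno):
        other = simulate_genotypes(dataclasses.replace(small_config, seed=12))
        assert not np.array_equal(small_geno.dosages, other.dosages)

    def test_realized_maf_respects_floor(self):
        cfg = SimulationConfig(n_individuals=500, n_variants=1000, n_genes=5, seed=2)
        g = simulate_genotypes(cfg)
        # binomial tolerance around the 0.05 floor
        assert g.maf().min() >= 0.03
        assert np.all(np.isin(g.dosages, [0.0, 1.0, 2.0]))

    def test_ld_confined_to_blocks(self):
        """Adjacent within-block pairs correlate; cross-block pairs do not."""
        within, across = [], []
        for seed in range(50):
            cfg = SimulationConfig(
                n_individuals=150, n_variants=60, n_genes=5, ld_block_size=20,
                ld_within_block=0.8, seed=100 + seed,
            )
            dos = simulate_genotypes(cfg).dosages
            corr = np.corrcoef(dos.T)
            blocks = np.arange(60) // 20
            for j in range(59):
                r = abs(corr[j, j + 1])
                (within if blocks[j] == blocks[j + 1] else across).append(r)
            across.append(abs(corr[5, 45]))  # far cross-block pair
        assert np.mean(within) > np.mean(across)
        assert np.mean(within) > 0.3
        assert np.mean(across) < 0.15

    def test_ld_decays_with_distance(self, small_geno):
        dos = small_geno.dosages
        corr = np.corrcoef(dos.T)
        near = np.mean([abs(corr[j, j + 1]) for j in range(0, 280, 20)])
        far = np.mean([abs(corr[j, j + 15]) for j in range(0, 280, 20)])
        assert near > far

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=0)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.05, 0.6))
        with pytest.raises(ValueError):
            SimulationConfig(conditions=("CTRL", "CTRL"))


class TestExpression:
    def test_truth_has_one_row_per_planted_gene_condition(self, small_config, small_geno):
        anno = default_gene_annotation(small_config)
        arch = standard_architectures(small_geno, anno)
        cfg = dataclasses.replace(small_config, architectures=arch)
        _, truth = simulate_expression(small_geno, cfg, gene_annotation=anno)
        assert not truth.effects.duplicated(["gene_id", "condition"]).any()
        planted_genes = {e.gene_id for e in arch}
        assert set(truth.effects["gene_id"]) == planted_genes
        assert set(truth.effects["causal_variant"]).issubset(
            set(small_geno.variants["variant_id"])
        )

    def test_mech1_gene_silenced_in_suppressed_condition(self, small_config, small_geno):
        anno = default_gene_annotation(small_config)
        arch = standard_architectures(small_geno, anno)
        cfg = dataclasses.replace(small_config, architectures=arch)
        expr, truth = simulate_expression(small_geno, cfg, gene_annotation=anno)
        mech1 = truth.effects[truth.effects["mechanism_tag"] == "mech1_low_expression"]
        gene = mech1["gene_id"].iloc[0]
        suppressed = expr["CTRL"].gene(gene)
        active = expr["LPS"].gene(gene)
        # >90% of resting samples sit below a tenth of the stimulated mean
        assert np.mean(suppressed < 0.1 * active.mean()) > 0.9

    def test_null_gene_scan_pvalues_uniform(self):
        """Per-SNP p-values for unplanted genes pass a KS uniformity check."""
        cfg = SimulationConfig(
            n_individuals=150, n_variants=40, n_genes=200, ld_block_size=20, seed=5,
            covariate_spec={}, n_hidden_factors=0,
        )
        geno = simulate_genotypes(cfg)
        expr, _ = simulate_expression(geno, cfg)
        pvals = []
        for gi, gene in enumerate(expr["CTRL"].gene_ids):
            y = expr["CTRL"].gene(gene)
            _, _, p, valid = _simple_regression(y - y.mean(), geno.dosages[:, [gi % 40]])
            pvals.append(p[valid][0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_beta_recovered_with_nominal_coverage(self):
        """OLS at the causal variant covers the planted beta ~95% of the time."""
        n_reps = 300
        half_width = stats.t.ppf(0.975, 298)
        hits = 0
        zscores = []
        for seed in range(n_reps):
            cfg = SimulationConfig(
                n_individuals=300, n_variants=30, n_genes=5, seed=1000 + seed,
                covariate_spec={}, n_hidden_factors=0, noise_sd=1.0,
            )
            geno = simulate_genotypes(cfg)
            vid = geno.variants["variant_id"].iloc[10]
            arch = [PlantedEffect("gene0000", vid, ("CTRL",), {"CTRL": 0.8})]
            expr, _ = simulate_expression(geno, dataclasses.replace(cfg, architectures=arch))
            y = expr["CTRL"].gene("gene0000")
            beta, se, _, _ = _simple_regression(y - y.mean(), geno.dosages[:, [10]])
            half = half_width * se[0]
            hits += beta[0] - half <= 0.8 <= beta[0] + half
            zscores.append((beta[0] - 0.8) / se[0])
        # nominal coverage with the binomial slack the replicate count implies
        assert hits >= 0.925 * n_reps
        # the pivot is exactly t-distributed conditional on the dosages
        assert stats.kstest(zscores, stats.t(298).cdf).pvalue > 0.01

    def test_unknown_ids_rejected(self, small_config, small_geno):
        bad = [PlantedEffect("nope", "var00001", ("CTRL",), {"CTRL": 1.0})]
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_expression(small_geno, dataclasses.replace(small_config, architectures=bad))
        bad = [PlantedEffect("gene0000", "missing", ("CTRL",), {"CTRL": 1.0})]
        with pytest.raises(ValueError, match="unknown causal variant"):
            simulate_expression(small_geno, dataclasses.replace(small_config, architectures=bad))


class TestGwasSummary:
    CFG = SimulationConfig(n_individuals=50, n_variants=60, n_genes=5, ld_block_size=20, seed=4)

    def test_same_seed_identical_summary(self):
        a = simulate_gwas_summary(self.CFG, "var00030", 1.5, 300, 300, seed=9)
        b = simulate_gwas_summary(self.CFG, "var00030", 1.5, 300, 300, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_gwas_pvalues_uniform(self):
        cfg = dataclasses.replace(self.CFG, n_variants=200)
        summary = simulate_gwas_summary(cfg, None, 1.0, 800, 800, seed=3)
        p = summary["p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_power_at_planted_odds_ratio(self):
        """OR 1.6 with 2000/2000 gives p < 1e-4 at the causal variant."""
        hits = 0
        for seed in range(25):
            summary = simulate_gwas_summary(self.CFG, "var00030", 1.6, 2000, 2000, seed=seed)
            hits += summary.set_index("variant_id").loc["var00030", "p"] < 1e-4
        assert hits >= 23

    def test_effect_sign_is_risk_increasing(self):
        summary = simulate_gwas_summary(self.CFG, "var00030", 1.6, 2000, 2000, seed=1)
        assert summary.set_index("variant_id").loc["var00030", "beta"] > 0

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            simulate_gwas_summary(self.CFG, "var00030", 1.5, 40, 300, seed=0)


def test_covariates_align_to_samples(small_config, small_geno):
    cov = simulate_covariates(small_config, small_geno.sample_ids)
    assert cov.sample_ids == small_geno.sample_ids
    assert set(cov.table.columns) == {"sex", "age", "bmi"}
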