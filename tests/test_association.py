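"""QC, normalization, residualization, scans, permutations and FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimqtl.association import (
    CovariateTable,
    ExpressionMatrix,
    bh_fdr,
    filter_genes,
    gene_level_permutation_p,
    hwe_exact_p,
    nominal_scan,
    permutation_indices,
    phenotype_gwas,
    qc_genotypes,
    quantile_normalize,
    residualize_expression,
)
from tests.conftest import hand_genotypes


def _expr_for(geno, values, tss, condition="CTRL", gene_id="g1"):
    anno = pd.DataFrame(
        {"gene_id": [gene_id], "chrom": ["1"], "tss": [tss], "strand": ["+"]}
    )
    return ExpressionMatrix(
        sample_ids=list(geno.sample_ids), gene_ids=[gene_id], condition=condition,
        values=np.asarray(values, dtype=float).reshape(-1, 1), gene_annotation=anno,
    )


class TestGenotypeQC:
    def test_hand_written_panel_matches_rule_by_rule_oracle(self):
        """Survivors equal brute-force application of the three predicates."""
        rng = np.random.default_rng(0)
        n, m = 200, 20
        dosages = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        dosages[:, 0] = rng.binomial(2, 0.02, size=n)          # rare -> MAF fail
        dosages[:150, 1] = np.nan                               # call rate fail
        dosages[:, 2] = np.tile([0.0, 2.0], n // 2)             # no hets -> HWE fail
        geno = hand_genotypes(dosages)
        out = qc_genotypes(geno, call_rate_min=0.95, maf_min=0.05, hwe_p_min=0.001)

        keep = []
        for j in range(m):
            col = dosages[:, j]
            obs = col[~np.isnan(col)]
            call = len(obs) / n
            af = obs.mean() / 2
            maf = min(af, 1 - af)
            g = np.rint(obs)
            het, alt, ref = np.sum(g == 1), np.sum(g == 2), np.sum(g == 0)
            rare, common = (alt, ref) if alt <= ref else (ref, alt)
            hwe = hwe_exact_p(int(het), int(rare), int(common))
            if call > 0.95 and maf >= 0.05 and hwe >= 0.001:
                keep.append(f"hv{j}")
        assert list(out.variants["variant_id"]) == keep
        assert out.qc_log["fail_maf"] >= 1 and out.qc_log["fail_call_rate"] >= 1
        assert out.qc_log["fail_hwe"] >= 1

    def test_low_maf_variant_removed_and_balanced_variant_kept(self):
        rng = np.random.default_rng(1)
        n = 1000
        dosages = np.column_stack([
            rng.binomial(2, 0.04, size=n),          # MAF ~0.04 -> removed
            np.tile([0, 1, 1, 2], n // 4),          # MAF 0.5, HWE-consistent -> kept
        ]).astype(float)
        out = qc_genotypes(hand_genotypes(dosages))
        assert list(out.variants["variant_id"]) == ["hv1"]

    def test_empty_result_raises_with_counts(self):
        dosages = np.full((100, 2), 0.0)
        dosages[0, :] = 1.0  # MAF 0.005 both
        with pytest.raises(ValueError, match="no variants pass"):
            qc_genotypes(hand_genotypes(dosages))

    def test_hwe_exact_matches_enumeration(self):
        """Exact HWE p equals direct enumeration of heterozygote configurations."""
        from scipy.special import comb

        def oracle(het, rare_hom, common_hom):
            n = het + rare_hom + common_hom
            rare = 2 * rare_hom + het
            probs = {}
            for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
                hr = (rare - h) // 2
                hc = n - h - hr
                probs[h] = (
                    2.0**h * comb(n, h, exact=True)
                    * comb(n - h, hr, exact=True)
                )
            total = sum(probs.values())
            obs = probs[het]
            return sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total

        for het, hr, hc in [(10, 5, 85), (57, 14, 50), (0, 10, 90), (30, 0, 70)]:
            assert hwe_exact_p(het, hr, hc) == pytest.approx(oracle(het, hr, hc), rel=1e-9)


class TestGeneFilter:
    def test_toy_matrix_matches_direct_recount(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(5, size=(20, 10)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"g{j}" for j in range(10)],
        )
        counts.iloc[:19, 0] = 0          # zero in 95% -> removed
        counts.iloc[:10, 1] = 0          # zero in 50% -> kept
        counts.iloc[:, 2] = np.arange(20) + 1  # nonzero everywhere -> kept
        out = filter_genes(counts, zero_fraction=0.90)
        lib = counts.sum(axis=1)
        cpm = counts.div(lib, axis=0) * 1e6
        expect = [g for g in counts.columns if (cpm[g] == 0).mean() < 0.90]
        assert list(out.columns) == expect
        assert "g0" not in out.columns and {"g1", "g2"} <= set(out.columns)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"], columns=["g1", "g2"])
        with pytest.raises(ValueError, match="library size"):
            filter_genes(counts)


class TestQuantileNormalize:
    def test_monotone_and_symmetric(self):
        out = quantile_normalize(np.array([1.0, 100.0, 10000.0]))
        assert np.all(np.diff(out) > 0)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[0] == pytest.approx(-out[2], abs=1e-12)

    def test_rank_preserving_on_normal_sample(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1000)
        out = quantile_normalize(x)
        assert stats.spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_ties_get_average_rank_quantiles(self):
        out = quantile_normalize(np.array([1.0, 2.0, 2.0, 3.0]))
        expect = stats.norm.ppf((np.array([1.0, 2.5, 2.5, 4.0]) - 0.5) / 4)
        np.testing.assert_allclose(out, expect, atol=1e-12)
        assert out[1] == out[2]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            quantile_normalize(np.ones(10))


class TestResidualize:
    def _cov(self, table):
        return CovariateTable(table)

    def test_intercept_only_centers(self, small_geno):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((200, 3)) + 7.0
        expr = ExpressionMatrix(
            sample_ids=small_geno.sample_ids, gene_ids=["a", "b", "c"], condition="CTRL",
            values=y,
            gene_annotation=pd.DataFrame({"gene_id": ["a", "b", "c"], "chrom": "1",
                                          "tss": [1, 2, 3], "strand": "+"}),
        )
        cov = self._cov(pd.DataFrame(index=small_geno.sample_ids))
        out = residualize_expression(expr, cov)
        np.testing.assert_allclose(out.values, y - y.mean(axis=0), atol=1e-10)

    def test_exact_linear_combination_gives_zero_residuals(self, small_geno):
        rng = np.random.default_rng(5)
        C = rng.standard_normal((200, 3))
        y = C @ np.array([1.0, -2.0, 0.5]) + 4.0
        expr = _expr_for(small_geno, y, tss=1000)
        cov = self._cov(pd.DataFrame(C, index=small_geno.sample_ids, columns=list("xyz")))
        out = residualize_expression(expr, cov)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_matches_normal_equations_and_is_idempotent(self):
        rng = np.random.default_rng(6)
        n = 50
        C = rng.standard_normal((n, 5))
        y = rng.standard_normal(n)
        geno = hand_genotypes(rng.binomial(2, 0.3, (n, 3)).astype(float))
        expr = _expr_for(geno, y, tss=1000)
        cov = self._cov(pd.DataFrame(C, index=geno.sample_ids,
                                     columns=[f"c{i}" for i in range(5)]))
        out = residualize_expression(expr, cov)
        X = np.column_stack([np.ones(n), C])
        expect = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(out.values[:, 0], expect, atol=1e-10)
        twice = residualize_expression(out, cov)
        np.testing.assert_allclose(twice.values, out.values, atol=1e-10)
        # residuals orthogonal to every covariate column
        assert np.max(np.abs(C.T @ out.values[:, 0])) < 1e-8 * np.linalg.norm(y)

    def test_collinear_design_reported(self, small_geno):
        C = pd.DataFrame(
            {"a": np.ones(200), "b": 2 * np.ones(200)}, index=small_geno.sample_ids
        )
        expr = _expr_for(small_geno, np.arange(200.0), tss=1000)
        with pytest.raises(ValueError, match="collinear"):
            residualize_expression(expr, self._cov(C))


class TestNominalScan:
    def test_expression_equal_to_dosage_is_perfect_fit(self):
        rng = np.random.default_rng(7)
        dosages = rng.binomial(2, 0.4, (100, 5)).astype(float)
        geno = hand_genotypes(dosages)
        expr = _expr_for(geno, dosages[:, 2], tss=1200)
        rec = nominal_scan(geno, expr, "g1")
        row = rec.set_index("variant_id").loc["hv2"]
        assert row["beta"] == pytest.approx(1.0, abs=1e-10)
        assert row["p"] < 1e-10

    def test_pvalues_match_analytic_correlation_t_test(self):
        rng = np.random.default_rng(8)
        n = 120
        dosages = rng.binomial(2, 0.3, (n, 8)).astype(float)
        geno = hand_genotypes(dosages)
        y = rng.standard_normal(n)
        rec = nominal_scan(geno, _expr_for(geno, y, tss=1300), "g1")
        for row in rec.itertuples():
            x = dosages[:, int(row.variant_id[2:])]
            r = stats.pearsonr(x, y)
            assert row.p == pytest.approx(r.pvalue, abs=1e-10)
            slope = stats.linregress(x, y)
            assert row.beta == pytest.approx(slope.slope, abs=1e-10)
            assert row.se == pytest.approx(slope.stderr, abs=1e-10)

    def test_window_boundary_inclusive_at_one_megabase(self):
        rng = np.random.default_rng(9)
        dosages = rng.binomial(2, 0.4, (60, 3)).astype(float)
        geno = hand_genotypes(dosages, start_pos=1_000_000, spacing=1)
        geno.variants.loc[1, "pos"] = 2_000_000      # exactly +1 Mb from TSS
        geno.variants.loc[2, "pos"] = 2_000_001      # one bp beyond
        expr = _expr_for(geno, rng.standard_normal(60), tss=1_000_000)
        rec = nominal_scan(geno, expr, "g1")
        assert set(rec["variant_id"]) == {"hv0", "hv1"}

    def test_zero_variance_variant_skipped(self):
        rng = np.random.default_rng(10)
        dosages = rng.binomial(2, 0.4, (50, 2)).astype(float)
        dosages[:, 1] = 1.0
        geno = hand_genotypes(dosages)
        rec = nominal_scan(geno, _expr_for(geno, rng.standard_normal(50), tss=1000), "g1")
        assert list(rec["variant_id"]) == ["hv0"]


class TestPermutationP:
    def _setup(self, seed=11, n=80, m=10, effect=0.0):
        rng = np.random.default_rng(seed)
        dosages = rng.binomial(2, 0.3, (n, m)).astype(float)
        geno = hand_genotypes(dosages)
        y = rng.standard_normal(n) + effect * dosages[:, 3]
        return geno, _expr_for(geno, y, tss=1400)

    def test_strong_signal_hits_lower_bound(self):
        geno, expr = self._setup(effect=3.0)
        res = gene_level_permutation_p(geno, expr, "g1", n_perm=200, seed=1)
        assert res["adjusted_p"] == pytest.approx(1 / 201)
        assert res["best_variant"] == "hv3"

    def test_matches_brute_force_reimplementation_of_same_shuffles(self):
        """Adjusted p equals a per-permutation scipy recomputation."""
        geno, expr = self._setup(effect=0.35)
        n_perm, seed = 150, 42
        res = gene_level_permutation_p(geno, expr, "g1", n_perm=n_perm, seed=seed)
        y = expr.gene("g1")
        X = geno.dosages

        def min_p(yy):
            return min(stats.pearsonr(X[:, j], yy).pvalue for j in range(X.shape[1]))

        obs = min_p(y)
        perms = permutation_indices(len(y), n_perm, seed)
        k = sum(min_p(y[idx]) <= obs * (1 + 1e-12) for idx in perms)
        assert res["adjusted_p"] == pytest.approx((1 + k) / (n_perm + 1))

    def test_beta_approximation_mode_close_to_empirical(self):
        geno, expr = self._setup(effect=0.25, n=150)
        emp = gene_level_permutation_p(geno, expr, "g1", n_perm=500, seed=3)
        beta = gene_level_permutation_p(geno, expr, "g1", n_perm=500, seed=3, mode="beta")
        assert beta["adjusted_p"] == pytest.approx(emp["adjusted_p"], rel=0.25)

    def test_too_few_permutations_rejected(self):
        geno, expr = self._setup()
        with pytest.raises(ValueError, match="n_perm"):
            gene_level_permutation_p(geno, expr, "g1", n_perm=50, seed=0)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr(np.array([0.02]))[0] == pytest.approx(0.02)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equals_double_loop_oracle_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            q = bh_fdr(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            oracle = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
                ]
                oracle[idx] = min(1.0, min(candidates))
            np.testing.assert_array_equal(q, oracle)
            # monotone in sorted order
            assert np.all(np.diff(q[order]) >= 0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestPhenotypeGwas:
    def test_phenotype_equal_to_dosage_is_global_minimum(self, small_geno):
        y = small_geno.dosages[:, 17]
        rec = phenotype_gwas(small_geno, y)
        assert rec.loc[rec["p"].idxmin(), "variant_id"] == "var00017"

    def test_null_phenotype_genomic_control_lambda_near_one(self):
        rng = np.random.default_rng(13)
        from stimqtl.simulate import SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(n_individuals=500, n_variants=5000, n_genes=5,
                               ld_block_size=20, seed=21)
        geno = simulate_genotypes(cfg)
        y = rng.standard_normal(500)
        rec = phenotype_gwas(geno, y)
        chi2 = stats.chi2.isf(rec["p"], 1)
        lam = np.median(chi2) / stats.chi2.ppf(0.5, 1)
        assert 0.95 <= lam <= 1.05
        assert (rec["p"] < 5e-8).sum() == 0
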