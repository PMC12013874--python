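"""Genotype/expression QC, normalization, and cis-eQTL association scans.

The scan machinery follows the standard single-variant linear model used by
QTLtools-style pipelines: expression is pre-corrected for covariates, each
variant in the cis window (default +/- 1 Mb around the TSS) is tested by
simple linear regression of residualized expression on allelic dosage, and
gene-level significance is obtained by permuting expression across
individuals and comparing the observed minimum nominal p against the
permutation distribution of minima.  FDR across genes uses
Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000  # +/- 1 Mb around the TSS
FDR_THRESHOLD = 0.05
# Candidate numbers of hidden-confounder expression PCs used at full cohort
# scale when maximizing eGene yield; desk-scale runs use a smaller range.
DEFAULT_PC_CANDIDATES = tuple(range(29, 39))


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage table with variant metadata.

    ``dosages`` is an (n_samples, n_variants) float array with values in
    [0, 2]; NaN marks missing calls.  ``variants`` has one row per variant
    with columns ``variant_id, chrom, pos, ref_allele, alt_allele`` (pos is
    1-based) plus any simulation metadata (true MAF, LD block).
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant_ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, computed on non-missing samples."""
        af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def hwe_p(self) -> np.ndarray:
        """Exact Hardy-Weinberg p per variant from rounded hard genotypes."""
        out = np.empty(self.n_variants)
        hard = np.rint(self.dosages)
        for j in range(self.n_variants):
            g = hard[:, j]
            g = g[~np.isnan(g)]
            n_het = int(np.sum(g == 1))
            n_alt = int(np.sum(g == 2))
            n_ref = int(np.sum(g == 0))
            n_rare, n_common = (n_alt, n_ref) if n_alt <= n_ref else (n_ref, n_alt)
            out[j] = hwe_exact_p(n_het, n_rare, n_common)
        return out

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            dosages=self.dosages[:, np.asarray(mask)],
        )

    def window(self, chrom: str, center: int, window_bp: int = CIS_WINDOW_BP) -> "GenotypeMatrix":
        """Variants with |pos - center| <= window_bp on ``chrom`` (inclusive)."""
        v = self.variants
        mask = (v["chrom"].astype(str) == str(chrom)) & (np.abs(v["pos"] - center) <= window_bp)
        return self.subset_variants(mask.to_numpy())


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact test of Hardy-Weinberg equilibrium (Wigginton-style enumeration).

    Sums, over all heterozygote counts compatible with the observed rare
    allele count, the probabilities no greater than that of the observed
    configuration.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare == 0 or rare == 2 * n:  # monomorphic
        return 1.0
    # heterozygote count must share parity with the rare allele count
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logprob = np.empty(len(het_values), dtype=float)
    from scipy.special import gammaln

    for i, h in enumerate(het_values):
        hr = (rare - h) // 2
        hc = n - h - hr
        logprob[i] = (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hr + 1)
            - gammaln(hc + 1)
        )
    logprob -= logprob.max()
    prob = np.exp(logprob)
    prob /= prob.sum()
    obs = prob[np.searchsorted(het_values, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized expression for one condition.

    ``gene_annotation`` has one row per gene with ``gene_id, chrom, tss,
    strand``; ``tss`` is the 1-based transcription start site used as the
    cis-window anchor.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    condition: str
    values: np.ndarray  # (n_samples, n_genes)
    gene_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("expression shape mismatch")
        self.gene_annotation = self.gene_annotation.set_index(
            self.gene_annotation["gene_id"].values
        )

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]

    def tss(self, gene_id: str) -> tuple[str, int]:
        row = self.gene_annotation.loc[gene_id]
        return str(row["chrom"]), int(row["tss"])


@dataclass
class CovariateTable:
    """Named numeric covariates aligned to samples (no intercept column)."""

    table: pd.DataFrame  # index = sample ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def design(self) -> np.ndarray:
        """Intercept + covariates design matrix; raises on rank deficiency."""
        X = np.column_stack([np.ones(len(self.table)), self.table.to_numpy(dtype=float)])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(X, ["(intercept)"] + list(self.table.columns))
            raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
        return X

    def with_columns(self, extra: pd.DataFrame) -> "CovariateTable":
        return CovariateTable(self.table.join(extra, how="inner"))


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy QR-based diagnosis)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in range(len(names)) if i < len(diag) and diag[i] <= tol]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_genotypes(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.001,
) -> GenotypeMatrix:
    """Drop variants with call rate <= ``call_rate_min``, MAF < ``maf_min``,
    or exact HWE p < ``hwe_p_min``.

    Filter counts per rule are logged and attached to the returned object as
    ``qc_log``.  Raises if no variant survives.
    """
    call = geno.call_rate()
    maf = geno.maf()
    hwe = geno.hwe_p()
    pass_call = call > call_rate_min
    pass_maf = maf >= maf_min
    pass_hwe = hwe >= hwe_p_min
    keep = pass_call & pass_maf & pass_hwe
    log = {
        "n_input": geno.n_variants,
        "fail_call_rate": int(np.sum(~pass_call)),
        "fail_maf": int(np.sum(~pass_maf)),
        "fail_hwe": int(np.sum(~pass_hwe)),
        "n_retained": int(keep.sum()),
    }
    logger.info("genotype QC: %s", log)
    if not keep.any():
        raise ValueError(f"no variants pass genotype QC: {log}")
    out = geno.subset_variants(keep)
    out.qc_log = log  # type: ignore[attr-defined]
    return out


def filter_genes(counts: pd.DataFrame, zero_fraction: float = 0.90) -> pd.DataFrame:
    """Remove genes with zero CPM in at least ``zero_fraction`` of samples.

    ``counts`` is samples x genes of raw nonnegative counts; CPM is
    count * 1e6 / library size.  Returns the CPM matrix of surviving genes.
    """
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        bad = list(counts.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    cpm = counts.div(lib, axis=0) * 1e6
    zero_frac = (cpm == 0).mean(axis=0)
    return cpm.loc[:, zero_frac < zero_fraction]


# ---------------------------------------------------------------------------
# Normalization and residualization
# ---------------------------------------------------------------------------


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map values onto standard-normal quantiles, preserving ranks.

    Uses average ranks for ties and the plotting position (r - 0.5)/n, so
    tied inputs receive identical outputs and the result is symmetric for a
    symmetric rank distribution.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values for quantile normalization")
    if np.all(values == values[0]):
        raise ValueError("all values identical; ranks undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


def residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on design X (projection onto the orthocomplement)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def residualize_expression(expr: ExpressionMatrix, cov: CovariateTable) -> ExpressionMatrix:
    """Per-gene OLS residuals against intercept + covariates.

    The returned residuals are orthogonal to every covariate column; applying
    the operation twice equals applying it once (projection idempotence).
    """
    if list(cov.sample_ids) != list(expr.sample_ids):
        cov = CovariateTable(cov.table.loc[expr.sample_ids])
    X = cov.design()
    resid = residualize(expr.values, X)
    return ExpressionMatrix(
        sample_ids=list(expr.sample_ids),
        gene_ids=list(expr.gene_ids),
        condition=expr.condition,
        values=resid,
        gene_annotation=expr.gene_annotation.reset_index(drop=True),
    )


def select_expression_pcs(
    expr: ExpressionMatrix,
    cov: CovariateTable,
    geno: GenotypeMatrix,
    candidate_range=(0, 1, 2, 3, 4, 5),
    scan_subsample: int = 50,
    n_perm: int = 200,
    seed: int = 0,
    fdr: float = FDR_THRESHOLD,
) -> tuple[CovariateTable, dict]:
    """Choose the number of expression PCs that maximizes eGene yield.

    For each candidate K, the top-K expression PCs are appended to the
    covariates, the first ``scan_subsample`` genes are scanned with
    gene-level permutation p-values, and the K giving the most genes at
    q <= ``fdr`` wins (smallest K on ties).  Returns the augmented table and
    a report with per-K eGene counts.
    """
    candidates = sorted(set(int(k) for k in candidate_range))
    if not candidates:
        raise ValueError("candidate_range is empty")
    n = len(expr.sample_ids)
    if n < 20:
        raise ValueError("too few samples for stable PCA")
    centered = expr.values - expr.values.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    max_k = max(candidates)
    if max_k >= min(centered.shape):
        raise ValueError(f"candidate K={max_k} exceeds available PCs")
    pcs = centered @ vt[:max_k].T if max_k else np.empty((n, 0))
    genes = list(expr.gene_ids)[: min(scan_subsample, len(expr.gene_ids))]
    counts: dict[int, int] = {}
    for k in candidates:
        extra = pd.DataFrame(
            pcs[:, :k], index=expr.sample_ids, columns=[f"expr_PC{i + 1}" for i in range(k)]
        )
        cand = CovariateTable(cov.table.loc[expr.sample_ids].join(extra))
        resid = residualize_expression(expr, cand)
        adj = [
            gene_level_permutation_p(geno, resid, g, n_perm=n_perm, seed=seed)["adjusted_p"]
            for g in genes
        ]
        q = bh_fdr(np.array(adj))
        counts[k] = int(np.sum(q <= fdr))
    best_k = max(candidates, key=lambda k: (counts[k], -k))
    extra = pd.DataFrame(
        pcs[:, :best_k], index=expr.sample_ids, columns=[f"expr_PC{i + 1}" for i in range(best_k)]
    )
    report = {"chosen_k": best_k, "egenes_per_k": counts, "condition": expr.condition}
    logger.info("expression PC selection: %s", report)
    return CovariateTable(cov.table.loc[expr.sample_ids].join(extra)), report


# ---------------------------------------------------------------------------
# Association scans
# ---------------------------------------------------------------------------


def _simple_regression(y: np.ndarray, X: np.ndarray):
    """Vectorized per-column simple linear regression of y on each column of X.

    Returns (beta, se, p, valid) where valid marks columns with non-zero
    dosage variance.  p is the two-sided t-test on n-2 degrees of freedom.
    """
    n = y.shape[0]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = float(yc @ yc)
    valid = sxx > 0
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(valid, sxy / np.where(valid, sxx, 1.0), np.nan)
        rss = syy - beta * sxy
        df = n - 2
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / np.where(valid, sxx, 1.0))
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p, valid


def _impute_missing(X: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant (logged fraction)."""
    if not np.isnan(X).any():
        return X
    X = X.copy()
    frac = float(np.mean(np.isnan(X)))
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(col_mean, idx[1])
    logger.info("mean-imputed %.3f%% of dosages", 100 * frac)
    return X


def nominal_scan(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    gene_id: str,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Per-variant nominal association in the gene's cis window.

    Tests every variant with |pos - TSS| <= ``window_bp`` by simple linear
    regression of (already residualized) expression on dosage.  Variants with
    zero dosage variance are skipped with a log entry.
    """
    chrom, tss = expr.tss(gene_id)
    win = geno.window(chrom, tss, window_bp)
    if win.n_variants == 0:
        raise ValueError(f"no variants within {window_bp} bp of {gene_id} TSS")
    y = expr.gene(gene_id)
    X = _impute_missing(win.dosages)
    beta, se, p, valid = _simple_regression(y, X)
    if not valid.all():
        logger.info("skipped %d zero-variance variants for %s", int(np.sum(~valid)), gene_id)
    v = win.variants
    out = pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "ref_allele": v["ref_allele"].to_numpy(),
            "alt_allele": v["alt_allele"].to_numpy(),
            "gene_id": gene_id,
            "condition": expr.condition,
            "beta": beta,
            "se": se,
            "p": p,
            "n": len(y),
        }
    )
    return out.loc[valid].reset_index(drop=True)


def permutation_indices(n: int, n_perm: int, seed: int) -> np.ndarray:
    """The shuffle sequence used by gene-level permutations (documented
    contract: ``default_rng(seed)`` then ``n_perm`` successive permutations)."""
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(n) for _ in range(n_perm)])


def gene_level_permutation_p(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    gene_id: str,
    window_bp: int = CIS_WINDOW_BP,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "empirical",
) -> dict:
    """Gene-level adjusted p-value by permuting expression across individuals.

    The observed statistic is the minimum nominal p over the cis window; the
    empirical adjusted p is (1 + k) / (n_perm + 1) where k counts
    permutations whose minimum nominal p is <= the observed one (ties count,
    conservatively).  ``mode="beta"`` instead fits a Beta distribution to the
    permuted minima and evaluates its CDF at the observed minimum
    (QTLtools-style approximation).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable tail")
    if mode not in ("empirical", "beta"):
        raise ValueError(f"unknown mode {mode!r}")
    chrom, tss = expr.tss(gene_id)
    win = geno.window(chrom, tss, window_bp)
    if win.n_variants == 0:
        raise ValueError(f"no variants within window of {gene_id}")
    y = expr.gene(gene_id)
    X = _impute_missing(win.dosages)
    n = len(y)
    beta, se, p, valid = _simple_regression(y, X)
    Xv = X[:, valid]
    best = int(np.argmin(p[valid]))
    obs_min_p = float(p[valid][best])
    # |correlation| is a monotone proxy for the minimum p at fixed df, so
    # permutation minima can be compared without per-variant p conversion.
    Xc = Xv - Xv.mean(axis=0)
    xnorm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    perms = permutation_indices(n, n_perm, seed)
    Yp = y[perms]  # (B, n)
    Ypc = Yp - Yp.mean(axis=1, keepdims=True)
    ynorm = np.sqrt(np.einsum("ij,ij->i", Ypc, Ypc))
    R = (Ypc @ Xc) / np.outer(ynorm, xnorm)
    max_abs_r = np.max(np.abs(R), axis=1)
    yc = y - y.mean()
    obs_r = np.abs(yc @ Xc) / (np.sqrt(yc @ yc) * xnorm)
    obs_max_r = float(np.max(obs_r))
    k = int(np.sum(max_abs_r >= obs_max_r * (1 - 1e-12)))
    adjusted = (1 + k) / (n_perm + 1)
    if mode == "beta":
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = max_abs_r * np.sqrt(df / np.maximum(1 - max_abs_r**2, 1e-300))
        min_p_perm = np.clip(2 * stats.t.sf(t_perm, df), np.finfo(float).tiny, 1.0)
        a, b, *_ = stats.beta.fit(min_p_perm, floc=0, fscale=1)
        adjusted = float(np.clip(stats.beta.cdf(obs_min_p, a, b), 1e-300, 1.0))
    win_ids = win.variants["variant_id"].to_numpy()[valid]
    return {
        "gene_id": gene_id,
        "condition": expr.condition,
        "best_variant": str(win_ids[best]),
        "nominal_p": obs_min_p,
        "beta": float(beta[valid][best]),
        "adjusted_p": float(adjusted),
        "n_perm": n_perm,
        "mode": mode,
    }


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j.

    Implemented directly (rather than through a library wrapper) so the
    q-values are bit-identical to the step-up definition.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def phenotype_gwas(
    geno: GenotypeMatrix,
    phenotype: np.ndarray,
    cov: CovariateTable | None = None,
) -> pd.DataFrame:
    """Genome-wide linear-regression association of a quantitative phenotype.

    Same regression contract as :func:`nominal_scan` without the cis-window
    restriction; the phenotype is residualized against covariates first when
    a table is supplied.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != geno.n_samples:
        raise ValueError("phenotype length does not match samples")
    if cov is not None:
        y = residualize(y, cov.design())
    X = _impute_missing(geno.dosages)
    beta, se, p, valid = _simple_regression(y, X)
    v = geno.variants
    out = pd.DataFrame(
        {
            "variant_id": v["variant_id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "ref_allele": v["ref_allele"].to_numpy(),
            "alt_allele": v["alt_allele"].to_numpy(),
            "gene_id": "",
            "condition": "",
            "beta": beta,
            "se": se,
            "p": p,
            "n": len(y),
        }
    )
    return out.loc[valid].reset_index(drop=True)
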