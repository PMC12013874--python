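"""Synthetic multi-condition cohort generator with known regulatory truth.

Emulates the study design of a stimulated whole-blood eQTL cohort: a panel
of N individuals genotyped at M SNPs with block LD and a MAF floor, gene
expression measured in four conditions (resting control plus TCR, TLR4/LPS
and TLR7-8/R848 stimulation) with planted cis-eQTLs that are shared or
condition-specific through each of three mechanisms, covariate confounding,
and case/control GWAS summary statistics whose causal variant can be shared
with a chosen eQTL.  Every planted effect is recorded in a truth table so
downstream stages can be tested by parameter recovery.

Genotypes are built from two latent-Gaussian haplotypes per individual with
an AR(1) correlation within each LD block (adjacent-variant correlation =
``ld_within_block``, decaying with distance, independent across blocks).
Expression is additive: baseline + per-condition shift + sum of planted
dosage effects + covariate effects + Gaussian noise; mechanism-1 genes have
the whole signal multiplied by a small suppression factor in their silenced
conditions so that both expression level and eQTL effect vanish there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from stimqtl.association import CovariateTable, ExpressionMatrix, GenotypeMatrix

DEFAULT_CONDITIONS = ("CTRL", "TCR", "LPS", "R848")
MECHANISM_TAGS = ("shared", "mech1_low_expression", "mech2_effect_loss", "mech3_switch", "sign_flip")

# Non strand-ambiguous allele pairs cycled across simulated variants.
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))


@dataclass
class PlantedEffect:
    """One planted cis-regulatory architecture for a gene.

    ``beta_per_condition`` maps each affected condition to the effect per
    alt-allele copy (signs may differ across conditions, e.g. for the
    sign-flip architecture).  ``mech1_low_expression`` entries additionally
    name ``suppressed_conditions`` where the baseline is silenced;
    ``mech3_switch`` entries carry a ``second_causal_variant_id`` driving
    ``second_affected_conditions``.
    """

    gene_id: str
    causal_variant_id: str
    affected_conditions: tuple[str, ...]
    beta_per_condition: dict[str, float]
    mechanism_tag: str = "shared"
    suppressed_conditions: tuple[str, ...] = ()
    second_causal_variant_id: str | None = None
    second_affected_conditions: tuple[str, ...] = ()
    second_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism_tag not in MECHANISM_TAGS:
            raise ValueError(f"unknown mechanism_tag {self.mechanism_tag!r}")
        if self.mechanism_tag == "mech1_low_expression" and not self.suppressed_conditions:
            raise ValueError("mech1 effects must name suppressed_conditions")
        if self.mechanism_tag == "mech3_switch":
            if not self.second_causal_variant_id:
                raise ValueError("mech3 effects need a second causal variant")
            if self.second_causal_variant_id == self.causal_variant_id:
                raise ValueError("mech3 causal variants must be distinct")
        missing = set(self.affected_conditions) - set(self.beta_per_condition)
        if missing:
            raise ValueError(f"no beta for affected conditions {sorted(missing)}")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror a desk-scale version of the four-condition stimulated
    whole-blood design: a few hundred individuals, block-LD genotypes with
    MAF >= 0.05, additive condition shifts that separate conditions, and
    unit-variance expression noise.
    """

    n_individuals: int = 300
    n_variants: int = 400
    n_genes: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_within_block: float = 0.8
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    architectures: list[PlantedEffect] = field(default_factory=list)
    covariate_spec: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.5, "age": 0.3, "bmi": 0.2}
    )
    n_hidden_factors: int = 1
    hidden_factor_sd: float = 1.0
    baseline_mean: float = 5.0
    condition_shift_sd: float = 1.0
    suppression_factor: float = 0.01
    noise_sd: float = 1.0
    variant_spacing_bp: int = 2_000
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_individuals, self.n_variants, self.n_genes) <= 0:
            raise ValueError("dimensions must be positive")
        if not (0 <= self.ld_within_block < 1):
            raise ValueError("ld_within_block must be in [0, 1)")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ValueError("conditions must be non-empty and unique")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def substream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the root seed."""
        name_entropy = [ord(c) for c in stage]
        return np.random.default_rng(np.random.SeedSequence([self.seed, *name_entropy]))


@dataclass
class CohortTruth:
    """Ground truth of all planted effects plus GWAS truth.

    ``effects`` has one row per planted gene x condition effect (gene_id,
    condition, causal_variant, beta, mechanism_tag, expressed); genes with
    no planted effect in a condition are absent.  ``gwas`` records the
    disease causal variant, odds ratio and the eQTL gene sharing it.
    """

    effects: pd.DataFrame
    gwas: dict = field(default_factory=dict)

    def causal_variants(self, gene_id: str, condition: str) -> list[str]:
        e = self.effects
        sel = e[(e["gene_id"] == gene_id) & (e["condition"] == condition) & (e["beta"] != 0)]
        return list(sel["causal_variant"])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _latent_haplotype(rng: np.random.Generator, n: int, m: int, block: int, rho: float) -> np.ndarray:
    """AR(1) latent Gaussians within blocks, independent across blocks.

    The recursion runs over the within-block offset (block boundaries reset
    it), so the loop length is the block size, not the variant count.
    """
    z = rng.standard_normal((n, m), dtype=np.float32)
    u = np.empty_like(z)
    scale = np.float32(np.sqrt(1.0 - rho**2))
    rho = np.float32(rho)
    n_blocks = -(-m // block)
    pad = n_blocks * block - m
    zp = np.concatenate([z, np.zeros((n, pad))], axis=1) if pad else z
    zb = zp.reshape(n, n_blocks, block)
    ub = np.empty_like(zb)
    ub[:, :, 0] = zb[:, :, 0]
    for j in range(1, block):
        ub[:, :, j] = rho * ub[:, :, j - 1] + scale * zb[:, :, j]
    u[:] = ub.reshape(n, n_blocks * block)[:, :m]
    return u


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate a block-LD dosage panel with MAF drawn from ``maf_range``.

    Each individual carries two latent haplotypes; an allele is present when
    the latent Gaussian falls below the allele-frequency quantile, so
    genotypes are in {0, 1, 2}, Hardy-Weinberg holds, and within-block LD
    decays with variant distance.
    """
    rng = config.substream("genotypes")
    n, m = config.n_individuals, config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    thresh = stats.norm.ppf(maf)
    h1 = _latent_haplotype(rng, n, m, config.ld_block_size, config.ld_within_block)
    h2 = _latent_haplotype(rng, n, m, config.ld_block_size, config.ld_within_block)
    dosage = (h1 < thresh).astype(float) + (h2 < thresh).astype(float)
    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{j:05d}" for j in range(m)],
            "chrom": config.chrom,
            "pos": 1_000_000 + config.variant_spacing_bp * np.arange(m),
            "ref_allele": [a[0] for a in alleles],
            "alt_allele": [a[1] for a in alleles],
            "true_maf": maf,
            "ld_block": np.arange(m) // config.ld_block_size,
        }
    )
    samples = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosage)


# ---------------------------------------------------------------------------
# Covariates and expression
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimulationConfig, sample_ids: list[str]) -> CovariateTable:
    """Sex/age/BMI-like confounders, one row per individual."""
    rng = config.substream("covariates")
    n = len(sample_ids)
    table = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.normal(45.0, 10.0, size=n),
            "bmi": rng.normal(25.0, 4.0, size=n),
        },
        index=sample_ids,
    )
    return CovariateTable(table)


def default_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Genes with TSS spread evenly across the variant panel, alternating strand."""
    span = config.variant_spacing_bp * config.n_variants
    # inset from the panel edges so every cis window keeps enough variants
    frac = 0.15 + 0.7 * (np.arange(config.n_genes) + 0.5) / config.n_genes
    tss = 1_000_000 + (span * frac).astype(int)
    return pd.DataFrame(
        {
            "gene_id": [f"gene{g:04d}" for g in range(config.n_genes)],
            "chrom": config.chrom,
            "tss": tss,
            "strand": ["+", "-"] * (config.n_genes // 2) + ["+"] * (config.n_genes % 2),
        }
    )


def simulate_expression(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    gene_annotation: pd.DataFrame | None = None,
    covariates: CovariateTable | None = None,
) -> tuple[dict[str, ExpressionMatrix], CohortTruth]:
    """Four-condition expression with planted cis-regulatory architectures.

    Expression(gene, sample, condition) = baseline + condition shift
    + sum(beta x dosage over effects active in the condition)
    + covariate effects + hidden-factor effects + N(0, noise_sd);
    mechanism-1 genes are multiplied by ``suppression_factor`` in their
    suppressed conditions after assembly, silencing both level and effect.
    """
    rng = config.substream("expression")
    anno = default_gene_annotation(config) if gene_annotation is None else gene_annotation
    if covariates is None:
        covariates = simulate_covariates(config, geno.sample_ids)
    gene_ids = list(anno["gene_id"])
    n, g = geno.n_samples, len(gene_ids)
    vindex = {v: j for j, v in enumerate(geno.variants["variant_id"])}
    by_gene: dict[str, list[PlantedEffect]] = {}
    for eff in config.architectures:
        if eff.gene_id not in gene_ids:
            raise ValueError(f"unknown gene {eff.gene_id!r} in architectures")
        for vid in filter(None, [eff.causal_variant_id, eff.second_causal_variant_id]):
            if vid not in vindex:
                raise ValueError(f"unknown causal variant {vid!r} in architectures")
        for c in set(eff.affected_conditions) | set(eff.suppressed_conditions) | set(
            eff.second_affected_conditions
        ):
            if c not in config.conditions:
                raise ValueError(f"unknown condition {c!r} in architectures")
        by_gene.setdefault(eff.gene_id, []).append(eff)

    cov_std = covariates.table.apply(lambda col: (col - col.mean()) / (col.std() or 1.0))
    cov_effect = np.zeros(n)
    for name, size in config.covariate_spec.items():
        if name in cov_std.columns:
            cov_effect = cov_effect + size * cov_std[name].to_numpy()
    hidden = rng.standard_normal((n, config.n_hidden_factors))
    loadings = rng.normal(0.0, 0.5, size=(config.n_hidden_factors, g))
    hidden_effect = config.hidden_factor_sd * hidden @ loadings

    shifts = {c: i * config.condition_shift_sd for i, c in enumerate(config.conditions)}
    matrices: dict[str, ExpressionMatrix] = {}
    truth_rows: list[dict] = []
    for cond in config.conditions:
        values = np.full((n, g), config.baseline_mean + shifts[cond])
        values += cov_effect[:, None] + hidden_effect
        values += rng.normal(0.0, config.noise_sd, size=(n, g))
        for gi, gene in enumerate(gene_ids):
            suppressed = False
            for eff in by_gene.get(gene, []):
                if cond in eff.affected_conditions:
                    beta = eff.beta_per_condition[cond]
                    values[:, gi] += beta * geno.dosages[:, vindex[eff.causal_variant_id]]
                if eff.mechanism_tag == "mech3_switch" and cond in eff.second_affected_conditions:
                    values[:, gi] += eff.second_beta * geno.dosages[
                        :, vindex[eff.second_causal_variant_id]
                    ]
                if eff.mechanism_tag == "mech1_low_expression" and cond in eff.suppressed_conditions:
                    suppressed = True
            if suppressed:
                values[:, gi] *= config.suppression_factor
        matrices[cond] = ExpressionMatrix(
            sample_ids=list(geno.sample_ids),
            gene_ids=gene_ids,
            condition=cond,
            values=values,
            gene_annotation=anno.copy(),
        )
    for eff in config.architectures:
        for cond in config.conditions:
            active = cond in eff.affected_conditions
            second = (
                eff.mechanism_tag == "mech3_switch" and cond in eff.second_affected_conditions
            )
            suppressed = (
                eff.mechanism_tag == "mech1_low_expression" and cond in eff.suppressed_conditions
            )
            if not (active or second or suppressed):
                continue
            truth_rows.append(
                {
                    "gene_id": eff.gene_id,
                    "condition": cond,
                    "causal_variant": (
                        eff.second_causal_variant_id if second else eff.causal_variant_id
                    ),
                    "beta": (
                        0.0
                        if suppressed and not active
                        else (eff.second_beta if second else eff.beta_per_condition.get(cond, 0.0))
                    ),
                    "mechanism_tag": eff.mechanism_tag,
                    "expressed": not suppressed,
                }
            )
    truth = CohortTruth(effects=pd.DataFrame(truth_rows, columns=[
        "gene_id", "condition", "causal_variant", "beta", "mechanism_tag", "expressed",
    ]))
    return matrices, truth


def nearest_variant(
    geno: GenotypeMatrix, chrom: str, pos: int, exclude_block=None, exclude_ids=(),
    maf_min: float = 0.0,
) -> str:
    """Variant id closest to a position, optionally outside a given LD block,
    excluding already-used variants and rare variants."""
    v = geno.variants
    mask = v["chrom"].astype(str) == str(chrom)
    if exclude_block is not None and "ld_block" in v:
        mask &= v["ld_block"] != exclude_block
    if len(exclude_ids):
        mask &= ~v["variant_id"].isin(list(exclude_ids))
    if maf_min > 0 and "true_maf" in v:
        mask &= v["true_maf"] >= maf_min
    cand = v[mask]
    if cand.empty:
        raise ValueError(f"no candidate variant near {chrom}:{pos}")
    return str(cand.loc[(cand["pos"] - pos).abs().idxmin(), "variant_id"])


def standard_architectures(
    geno: GenotypeMatrix,
    gene_annotation: pd.DataFrame,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    beta: float = 0.8,
) -> list[PlantedEffect]:
    """One gene per architecture class, anchored near each gene's TSS.

    Plants, in gene order: a shared eQTL (all conditions), a mechanism-1
    gene (silenced at rest), a mechanism-2 gene (effect only after TLR
    stimulation), a mechanism-3 gene (distinct causal variants at rest vs
    after TLR stimulation, in different LD blocks) and a sign-flip gene.
    Remaining genes stay null.  Causal variants are drawn from common
    variants (MAF >= 0.2), matching the allele-frequency spectrum of
    detectable cis-eQTLs.
    """
    if len(gene_annotation) < 5:
        raise ValueError("need at least 5 genes for the standard architecture set")
    rest, stim = conditions[0], conditions[1:]
    tlr = tuple(c for c in conditions if c in ("LPS", "R848")) or stim[-2:]
    g = list(gene_annotation.itertuples())
    v = geno.variants.set_index("variant_id")
    used: set[str] = set()

    def near(row, exclude_block=None):
        vid = nearest_variant(geno, row.chrom, row.tss, exclude_block, exclude_ids=used,
                              maf_min=0.2)
        used.add(vid)
        return vid

    first = near(g[3])
    effects = [
        PlantedEffect(g[0].gene_id, near(g[0]), tuple(conditions),
                      {c: beta for c in conditions}, "shared"),
        PlantedEffect(g[1].gene_id, near(g[1]), tuple(stim),
                      {c: beta for c in stim}, "mech1_low_expression",
                      suppressed_conditions=(rest,)),
        PlantedEffect(g[2].gene_id, near(g[2]), tlr,
                      {c: beta for c in tlr}, "mech2_effect_loss"),
        PlantedEffect(g[3].gene_id, first, (rest,), {rest: beta}, "mech3_switch",
                      second_causal_variant_id=near(
                          g[3], exclude_block=int(v.loc[first, "ld_block"])),
                      second_affected_conditions=tlr, second_beta=beta),
        PlantedEffect(g[4].gene_id, near(g[4]), tuple(conditions),
                      {c: (-beta if c in tlr else beta) for c in conditions}, "sign_flip"),
    ]
    return effects


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: genotypes, covariates, expression and truth."""
    geno = simulate_genotypes(config)
    cov = simulate_covariates(config, geno.sample_ids)
    anno = default_gene_annotation(config)
    expr, truth = simulate_expression(geno, config, gene_annotation=anno, covariates=cov)
    return geno, cov, anno, expr, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def _vectorized_logistic(y: np.ndarray, X: np.ndarray, n_iter: int = 9):
    """Per-variant logistic regression (intercept + dosage) via Newton steps.

    Returns (beta, se, p) on the log-odds scale with Wald p-values.  The
    2 x 2 information matrix is inverted in closed form for all variants at
    once, which keeps thousands of fits fast.
    """
    n, m = X.shape
    a = np.full(m, np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12)))
    b = np.zeros(m)
    for _ in range(n_iter):
        eta = a[None, :] + X * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        s00 = w.sum(axis=0)
        s01 = np.einsum("ij,ij->j", w, X)
        s11 = np.einsum("ij,ij,ij->j", w, X, X)
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", r, X)
        det = s00 * s11 - s01**2
        det = np.where(det > 1e-12, det, np.nan)
        da = (s11 * g0 - s01 * g1) / det
        db = (-s01 * g0 + s00 * g1) / det
        da = np.nan_to_num(np.clip(da, -2, 2))
        db = np.nan_to_num(np.clip(db, -2, 2))
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-6:
            break
    eta = a[None, :] + X * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    s00 = w.sum(axis=0)
    s01 = np.einsum("ij,ij->j", w, X)
    s11 = np.einsum("ij,ij,ij->j", w, X, X)
    det = s00 * s11 - s01**2
    se = np.sqrt(np.where(det > 0, s00 / det, np.inf))
    z = b / se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return b, se, pval


def simulate_gwas_summary(
    config: SimulationConfig,
    causal_variant_id: str | None,
    odds_ratio: float,
    n_cases: int,
    n_controls: int,
    seed: int,
    prevalence: float = 0.1,
    variant_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Case/control GWAS summary statistics over the simulated variant panel.

    Draws a fresh disease cohort from the same genotype-generating process
    (same MAFs and LD structure as the eQTL panel, as for two cohorts of one
    population), assigns disease by a logistic model with additive log-odds
    at the causal variant, and fits per-variant logistic regressions.
    Positive beta means the alt allele increases disease odds.
    ``variant_range`` restricts simulation and output to a (start, stop)
    variant-index slice, widened to whole LD blocks so the local LD process
    is unchanged.
    """
    if min(n_cases, n_controls) < 50:
        raise ValueError("need >= 50 cases and >= 50 controls for stable estimates")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD15EA5E]))
    # Reuse the eQTL panel's MAFs so the two cohorts share allele frequencies.
    template = simulate_genotypes(config)
    bs = config.ld_block_size
    if variant_range is None:
        lo, hi = 0, config.n_variants
    else:
        lo = (max(variant_range[0], 0) // bs) * bs
        hi = min(-(-variant_range[1] // bs) * bs, config.n_variants)
    template = template.subset_variants(
        np.isin(np.arange(config.n_variants), np.arange(lo, hi))
    )
    maf = template.variants["true_maf"].to_numpy()
    thresh = stats.norm.ppf(maf)
    m = hi - lo
    if causal_variant_id is not None:
        cidx = list(template.variants["variant_id"]).index(causal_variant_id)
    logit0 = np.log(prevalence / (1 - prevalence))
    log_or = np.log(odds_ratio)

    cases = np.empty((0, m))
    controls = np.empty((0, m))
    batch = max(
        int(1.15 * max(n_cases / prevalence, n_controls / (1 - prevalence))), 1000
    )
    while len(cases) < n_cases or len(controls) < n_controls:
        h1 = _latent_haplotype(rng, batch, m, bs, config.ld_within_block)
        h2 = _latent_haplotype(rng, batch, m, bs, config.ld_within_block)
        dos = (h1 < thresh).astype(float) + (h2 < thresh).astype(float)
        eta = logit0 + (log_or * dos[:, cidx] if causal_variant_id is not None else 0.0)
        disease = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        cases = np.vstack([cases, dos[disease][: n_cases - len(cases)]])
        controls = np.vstack([controls, dos[~disease][: n_controls - len(controls)]])
    X = np.vstack([cases, controls])
    y = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    mono = X.std(axis=0) == 0
    beta, se, pval = _vectorized_logistic(y, X)
    beta[mono], se[mono], pval[mono] = np.nan, np.nan, 1.0
    v = template.variants
    return pd.DataFrame(
        {
            "variant_id": v["variant_id"],
            "chrom": v["chrom"],
            "pos": v["pos"],
            "effect_allele": v["alt_allele"],
            "other_allele": v["ref_allele"],
            "beta": beta,
            "se": se,
            "p": pval,
        }
    )
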