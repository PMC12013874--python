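"""Signed theta colocalization between two association patterns.

theta is a weighted Pearson correlation of signed log10(1/p) scores over
the variants where at least one of the two traits shows nominal association
(p < 0.05), with weights emphasizing the association peaks
(w = max(-log10 p)^gamma, gamma = 2 by default).  |theta| close to 1 means
the two patterns are driven by the same set of regulatory variants; the
sign tells whether the allelic effects point the same way.  Patterns
sharing fewer than 50 selected SNPs are not compared.  Significance comes
from permutations that randomize the phenotype-genotype pairing of a trait
with individual-level data, rebuild its pattern, and recompute theta; when
both traits have individual-level data the final p is the average of the
two one-sided empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stimqtl.association import _simple_regression
from stimqtl.eap import AssociationPattern, signed_score

P_SELECT_DEFAULT = 0.05
MIN_SNPS_DEFAULT = 50
WEIGHT_EXPONENT_DEFAULT = 2.0
THETA_MATCH_MIN = 0.6
P_MATCH_MAX = 0.05


@dataclass
class ThetaResult:
    """Colocalization verdict between two association patterns."""

    theta: float | None
    n_snps_used: int
    p_perm: float | None = None
    p_side_1: float | None = None
    p_side_2: float | None = None
    weight_exponent: float = WEIGHT_EXPONENT_DEFAULT
    p_threshold: float = P_SELECT_DEFAULT
    min_snps: int = MIN_SNPS_DEFAULT
    reason: str | None = None
    one_sided: bool = False

    @property
    def defined(self) -> bool:
        return self.theta is not None


@dataclass
class TraitData:
    """Individual-level data for one trait, aligned to a harmonized pattern.

    ``dosages`` is (n_samples, n_variants) in the harmonized variant order;
    ``phenotype`` the residualized trait vector.  Permutations shuffle the
    phenotype across individuals and rebuild the pattern from scratch.
    """

    dosages: np.ndarray
    phenotype: np.ndarray
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.dosages.shape[0] != len(self.phenotype):
            raise ValueError("dosage rows must match phenotype length")
        if self.variant_ids is not None and len(self.variant_ids) != self.dosages.shape[1]:
            raise ValueError("variant_ids must match dosage columns")

    def aligned_to(self, pattern: AssociationPattern) -> "TraitData":
        """Subset/reorder dosage columns to a (harmonized) pattern's variants."""
        if self.variant_ids is None:
            if self.dosages.shape[1] != len(pattern.table):
                raise ValueError("trait data not aligned to pattern and has no variant_ids")
            return self
        index = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            cols = [index[v] for v in pattern.table["variant_id"]]
        except KeyError as e:
            raise ValueError(f"pattern variant {e} missing from trait data") from e
        return TraitData(self.dosages[:, cols], self.phenotype, None)

    def pattern_scores(self, phenotype: np.ndarray | None = None):
        """(score, p) per harmonized variant for a (possibly permuted) phenotype."""
        y = self.phenotype if phenotype is None else phenotype
        beta, _, p, valid = _simple_regression(y, self.dosages)
        score = signed_score(np.where(valid, beta, 0.0), np.where(valid, p, 1.0))
        return score, np.where(valid, p, 1.0)


def select_snps(
    p_a: np.ndarray,
    p_b: np.ndarray,
    p_threshold: float = P_SELECT_DEFAULT,
    weight_exponent: float = WEIGHT_EXPONENT_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Variants with min(p_a, p_b) < threshold, and their peak weights.

    The weight of a selected variant is max(log10(1/p_a), log10(1/p_b))
    raised to ``weight_exponent``, emphasizing association peaks.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    mask = np.minimum(p_a, p_b) < p_threshold
    strongest = np.maximum(np.log10(1.0 / np.maximum(p_a, 1e-300)),
                           np.log10(1.0 / np.maximum(p_b, 1e-300)))
    return mask, strongest[mask] ** weight_exponent


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float | None:
    """Weighted Pearson correlation; None when either variance is zero."""
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        return None
    xm = x - (w @ x) / wsum
    ym = y - (w @ y) / wsum
    vx = w @ (xm**2)
    vy = w @ (ym**2)
    if vx <= 0 or vy <= 0:
        return None
    return float((w @ (xm * ym)) / np.sqrt(vx * vy))


def _theta_from_scores(score_a, p_a, score_b, p_b, p_threshold, weight_exponent, min_snps):
    mask, w = select_snps(p_a, p_b, p_threshold, weight_exponent)
    n_used = int(mask.sum())
    if n_used < min_snps:
        return None, n_used, "below min_snps"
    if np.all(w == 0):  # all selected SNPs at p = 1 cannot happen; guard anyway
        w = np.ones(n_used)
    theta = weighted_pearson(score_a[mask], score_b[mask], w)
    if theta is None:
        return None, n_used, "zero weighted variance"
    return theta, n_used, None


def compute_theta(
    a: AssociationPattern,
    b: AssociationPattern,
    min_snps: int = MIN_SNPS_DEFAULT,
    weight_exponent: float = WEIGHT_EXPONENT_DEFAULT,
    p_threshold: float = P_SELECT_DEFAULT,
    assume_harmonized: bool = False,
) -> ThetaResult:
    """Signed theta between two (harmonized) association patterns.

    Patterns are harmonized by variant key first unless ``assume_harmonized``
    is set (in which case rows must already be aligned one-to-one).  No theta
    is reported when fewer than ``min_snps`` variants survive selection.
    """
    if assume_harmonized:
        ta, tb = a.table, b.table
    else:
        from stimqtl.eap import harmonize_alleles

        a2, b2, _ = harmonize_alleles(a, b)
        ta, tb = a2.table, b2.table
    theta, n_used, reason = _theta_from_scores(
        ta["score"].to_numpy(), ta["p"].to_numpy(),
        tb["score"].to_numpy(), tb["p"].to_numpy(),
        p_threshold, weight_exponent, min_snps,
    )
    return ThetaResult(
        theta=theta, n_snps_used=n_used, weight_exponent=weight_exponent,
        p_threshold=p_threshold, min_snps=min_snps, reason=reason,
    )


def theta_permutation_p(
    pattern_a: AssociationPattern,
    pattern_b: AssociationPattern,
    trait_a_data: TraitData | None,
    trait_b_data: TraitData | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    min_snps: int = MIN_SNPS_DEFAULT,
    weight_exponent: float = WEIGHT_EXPONENT_DEFAULT,
    p_threshold: float = P_SELECT_DEFAULT,
    assume_harmonized: bool = True,
) -> ThetaResult:
    """Permutation significance of theta.

    Side 1 shuffles trait a's phenotype across individuals, rebuilds its
    pattern (re-applying SNP selection each time, so the null carries the
    same selection bias as the observed statistic) and recomputes theta
    against the observed pattern b; p1 = (1 + #{|theta*| >= |theta|}) /
    (n_perm + 1).  Side 2 is symmetric when trait b has individual-level
    data.  The final p is the average of the available sides; with a
    summary-only trait b (a DAP) the result is flagged one-sided.
    Permutations whose theta is undefined count as non-exceeding.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if trait_a_data is None and trait_b_data is None:
        raise ValueError("at least one trait needs individual-level data")
    obs = compute_theta(pattern_a, pattern_b, min_snps, weight_exponent, p_threshold,
                        assume_harmonized=assume_harmonized)
    if not obs.defined:
        return obs
    if not assume_harmonized:
        from stimqtl.eap import harmonize_alleles

        pattern_a, pattern_b, _ = harmonize_alleles(pattern_a, pattern_b)
    abs_obs = abs(obs.theta)

    def one_side(data: TraitData, fixed: AssociationPattern, stream: int) -> float:
        """Empirical p for one permuted side.

        Works on precomputed centered dosages; within each permutation,
        SNP selection uses the |r| threshold equivalent to ``p_threshold``
        and p-values are converted only for the selected variants, which
        is algebraically identical to rebuilding the full pattern.
        """
        from scipy import stats as _stats

        rng = np.random.default_rng(np.random.SeedSequence([seed, stream]))
        score_f = fixed.table["score"].to_numpy()
        p_f = fixed.table["p"].to_numpy()
        log_wf = np.log10(1.0 / np.maximum(p_f, 1e-300))
        fixed_sel = p_f < p_threshold
        y = data.phenotype
        n = len(y)
        df = n - 2
        Xc = data.dosages - data.dosages.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        valid = sxx > 0
        sxx_safe = np.where(valid, sxx, 1.0)
        t_thr = _stats.t.isf(p_threshold / 2, df)
        r_thr = t_thr / np.sqrt(df + t_thr**2)
        exceed = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            yc = yp - yp.mean()
            r = (yc @ Xc) / np.sqrt((yc @ yc) * sxx_safe)
            r[~valid] = 0.0
            sel = fixed_sel | (np.abs(r) > r_thr)
            idx = np.nonzero(sel)[0]
            if len(idx) < min_snps:
                continue
            rs = np.clip(r[idx], -1 + 1e-15, 1 - 1e-15)
            tstat = rs * np.sqrt(df / (1 - rs**2))
            p_a = np.clip(2 * _stats.t.sf(np.abs(tstat), df), np.finfo(float).tiny, 1.0)
            log_wa = np.log10(1.0 / p_a)
            score_a = np.sign(rs) * log_wa
            w = np.maximum(log_wa, log_wf[idx]) ** weight_exponent
            if np.all(w == 0):
                w = np.ones(len(idx))
            theta_p = weighted_pearson(score_a, score_f[idx], w)
            if theta_p is not None and abs(theta_p) >= abs_obs - 1e-12:
                exceed += 1
        return (1 + exceed) / (n_perm + 1)

    p1 = (
        one_side(trait_a_data.aligned_to(pattern_a), pattern_b, 1)
        if trait_a_data is not None
        else None
    )
    p2 = (
        one_side(trait_b_data.aligned_to(pattern_b), pattern_a, 2)
        if trait_b_data is not None
        else None
    )
    sides = [p for p in (p1, p2) if p is not None]
    return ThetaResult(
        theta=obs.theta,
        n_snps_used=obs.n_snps_used,
        p_perm=float(np.mean(sides)),
        p_side_1=p1,
        p_side_2=p2,
        weight_exponent=weight_exponent,
        p_threshold=p_threshold,
        min_snps=min_snps,
        one_sided=len(sides) == 1,
    )


def is_matching(
    result: ThetaResult,
    theta_min: float = THETA_MATCH_MIN,
    p_max: float = P_MATCH_MAX,
    require_p: bool = True,
) -> bool:
    """|theta| >= theta_min with permutation support declares a match."""
    if not result.defined:
        return False
    if abs(result.theta) < theta_min:
        return False
    if require_p:
        if result.p_perm is None:
            return False
        return result.p_perm <= p_max
    return True
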