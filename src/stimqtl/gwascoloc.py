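"""Matching disease association patterns (DAPs) against the EAP catalogue.

If a risk locus alters disease susceptibility by changing a gene's
expression in cis, the DAP around the locus and the gene's EAP should
match (|theta| >= 0.6 with permutation support); the sign of theta tells
whether the risk-increasing allele raises or lowers expression.  A match
seen only after stimulation, with no matching resting-condition EAP at the
locus, is reQTL-specific — a candidate that resting-state catalogues miss.
Disease cohorts provide only summary statistics, so permutation p-values
for DAP tests are one-sided (eQTL side only) and flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stimqtl.eap import AssociationPattern, harmonize_alleles
from stimqtl.theta import (
    ThetaResult,
    TraitData,
    compute_theta,
    is_matching,
    theta_permutation_p,
)
from stimqtl.association import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class ColocReport:
    """One DAP-EAP match."""

    locus_id: str
    disease: str
    gene_id: str
    condition: str
    theta: float
    p: float | None
    n_snps: int
    direction: str  # risk allele "increases" or "decreases" expression
    reqtl_specific: bool = False
    one_sided: bool = True
    q: float | None = None


def _direction(theta: float) -> str:
    return "increases" if theta > 0 else "decreases"


def match_dap_to_catalogue(
    dap: AssociationPattern,
    eap_catalogue: dict[tuple[str, str], AssociationPattern],
    trait_data: dict[tuple[str, str], TraitData] | None = None,
    theta_min: float = 0.6,
    p_max: float = 0.05,
    min_snps: int = 50,
    n_perm: int = 1000,
    seed: int = 0,
    resting_condition: str = "CTRL",
) -> list[ColocReport]:
    """Test the DAP against every catalogue EAP overlapping its window.

    One theta test per gene x condition EAP whose window overlaps the DAP
    window; rows passing the match rule (|theta| >= theta_min, permutation
    p <= p_max when individual-level eQTL data is supplied) are reported
    with the signed direction.  ``reqtl_specific`` is set per locus when no
    resting-condition row passes.
    """
    reports: list[ColocReport] = []
    overlapping = {
        key: eap
        for key, eap in eap_catalogue.items()
        if eap.chrom == dap.chrom and eap.start <= dap.end and dap.start <= eap.end
    }
    if not overlapping:
        logger.info("no catalogue EAPs overlap DAP window %s:%d-%d",
                    dap.chrom, dap.start, dap.end)
        return reports
    for (gene, cond), eap in sorted(overlapping.items()):
        try:
            eap_h, dap_h, _ = harmonize_alleles(eap, dap)
        except ValueError:
            continue
        data = (trait_data or {}).get((gene, cond))
        if data is not None:
            res = theta_permutation_p(
                eap_h, dap_h, data, None, n_perm=n_perm, seed=seed,
                min_snps=min_snps, assume_harmonized=True,
            )
        else:
            res = compute_theta(eap_h, dap_h, min_snps=min_snps, assume_harmonized=True)
        if is_matching(res, theta_min, p_max, require_p=data is not None):
            reports.append(
                ColocReport(
                    locus_id=dap.trait_id,
                    disease=dap.context,
                    gene_id=gene,
                    condition=cond,
                    theta=res.theta,
                    p=res.p_perm,
                    n_snps=res.n_snps_used,
                    direction=_direction(res.theta),
                    one_sided=True,
                )
            )
    resting = any(r.condition == resting_condition for r in reports)
    for r in reports:
        r.reqtl_specific = not resting
    return reports


def annotate_bh(reports: list[ColocReport]) -> list[ColocReport]:
    """Attach BH q-values across all reported rows (raw p-values retained)."""
    with_p = [r for r in reports if r.p is not None]
    if with_p:
        q = bh_fdr(np.array([r.p for r in with_p]))
        for r, qv in zip(with_p, q):
            r.q = float(qv)
    return reports


def opposite_direction_scan(reports: list[ColocReport]) -> list[dict]:
    """Pairs of reports for the same gene with opposite theta signs.

    Flags genes whose risk-allele effect on expression reverses between
    conditions or diseases (e.g. risk variants raising expression at rest
    but lowering it after stimulation).
    """
    flagged = []
    by_gene: dict[str, list[ColocReport]] = {}
    for r in reports:
        by_gene.setdefault(r.gene_id, []).append(r)
    for gene, rows in sorted(by_gene.items()):
        for i, a in enumerate(rows):
            for b in rows[i + 1:]:
                if np.sign(a.theta) * np.sign(b.theta) < 0:
                    flagged.append(
                        {
                            "gene_id": gene,
                            "context_1": (a.disease, a.condition, a.theta),
                            "context_2": (b.disease, b.condition, b.theta),
                        }
                    )
    return flagged


def confounder_screen(
    eap: AssociationPattern,
    trait_daps: dict[str, AssociationPattern],
    theta_min: float = 0.6,
    min_snps: int = 50,
) -> list[dict]:
    """Screen an EAP against blood-cell-trait DAPs for composition confounding.

    theta is computed between the eQTL pattern and each positionally
    overlapping trait DAP; matches above threshold are flagged as potential
    cell-composition confounding of the eQTL signal.
    """
    flagged = []
    for trait_id, dap in sorted(trait_daps.items()):
        if dap.chrom != eap.chrom or dap.start > eap.end or eap.start > dap.end:
            continue
        try:
            res = compute_theta(eap, dap, min_snps=min_snps)
        except ValueError:
            continue
        if res.defined and abs(res.theta) >= theta_min:
            flagged.append(
                {
                    "trait": trait_id,
                    "gene_id": eap.trait_id,
                    "condition": eap.context,
                    "theta": res.theta,
                    "n_snps": res.n_snps_used,
                }
            )
    return flagged
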