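"""Clustering of matching association patterns into cis-regulatory modules.

cis-eQTLs whose association patterns match (|theta| >= 0.6 with permutation
support) are merged: first within a gene across conditions (monogenic cRMs,
at most one member per condition), then across genes whose TSSs lie within
1 Mb of each other (multigenic cRMs).  Matching is not transitive, but a
module is the connected component of the matching graph.  Each monogenic
cRM carries a 4-character activity label over the fixed condition order
CTRL-TCR-LPS-R848 ('1' where the gene is a significant eQTL in that
condition); a cRM with no activity in the resting condition is a response
cRM (reQTL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from stimqtl.eap import AssociationPattern
from stimqtl.theta import ThetaResult, compute_theta, is_matching

CONDITION_ORDER = ("CTRL", "TCR", "LPS", "R848")

# A matcher takes two AssociationPatterns and returns a ThetaResult.
Matcher = Callable[[AssociationPattern, AssociationPattern], ThetaResult]


def default_matcher(theta_min: float = 0.6, **theta_kwargs) -> Matcher:
    """Theta-only matcher (no permutation p), for desk-scale clustering."""

    def match(a: AssociationPattern, b: AssociationPattern) -> ThetaResult:
        return compute_theta(a, b, **theta_kwargs)

    return match


@dataclass
class CRM:
    """A connected set of matching association patterns.

    ``members`` are (gene_id, condition) pairs; ``labels`` maps each member
    gene to its activity string over the run's condition order; the
    representative member is the one with the smallest top nominal p.
    """

    crm_id: str
    members: list[tuple[str, str]]
    labels: dict[str, str] = field(default_factory=dict)
    is_multigenic: bool = False
    is_reqtl: bool = False
    representative: tuple[str, str] | None = None
    edges: list[tuple] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.members}

    @property
    def conditions(self) -> set[str]:
        return {c for _, c in self.members}


def _components(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return [sorted(c) for c in nx.connected_components(g)]


def merge_monogenic(
    eaps_for_gene: dict[tuple[str, str], AssociationPattern],
    matcher: Matcher,
    theta_min: float = 0.6,
    p_max: float = 0.05,
    require_p: bool = False,
    crm_prefix: str = "crm",
) -> list[CRM]:
    """Merge one gene's per-condition EAPs into monogenic cRMs.

    Builds the matching graph over the gene's condition-specific EAPs and
    returns one cRM per connected component (singletons allowed).
    """
    nodes = sorted(eaps_for_gene)
    genes = {g for g, _ in nodes}
    if len(genes) > 1:
        raise ValueError(f"monogenic merge received several genes: {sorted(genes)}")
    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            res = matcher(eaps_for_gene[u], eaps_for_gene[v])
            if is_matching(res, theta_min, p_max, require_p=require_p):
                edges.append((u, v, res.theta))
    crms = []
    for k, comp in enumerate(sorted(_components(nodes, [(u, v) for u, v, _ in edges]))):
        crms.append(
            CRM(
                crm_id=f"{crm_prefix}_{next(iter(genes))}_{k}",
                members=list(comp),
                edges=[e for e in edges if e[0] in comp and e[1] in comp],
            )
        )
    return crms


def assign_label(
    crm: CRM,
    significant: set[tuple[str, str]],
    condition_order: tuple[str, ...] = CONDITION_ORDER,
) -> dict[str, str]:
    """Activity label per member gene: bit i = 1 iff the gene is a
    significant eQTL member of this cRM in condition i."""
    for _, c in crm.members:
        if c not in condition_order:
            raise ValueError(f"unknown condition {c!r}")
    labels = {}
    for gene in sorted(crm.genes):
        bits = ""
        for cond in condition_order:
            active = (gene, cond) in crm.members and (gene, cond) in significant
            bits += "1" if active else "0"
        labels[gene] = bits
    crm.labels = labels
    crm.is_reqtl = flag_reqtl_crm(crm, condition_order)
    return labels


def flag_reqtl(label: str) -> bool:
    """True iff the resting-condition bit (first position) is 0."""
    return label[0] == "0"


def flag_reqtl_crm(crm: CRM, condition_order: tuple[str, ...] = CONDITION_ORDER) -> bool:
    """A cRM is a response module when none of its members is active at rest."""
    return all(flag_reqtl(lbl) for lbl in crm.labels.values()) if crm.labels else False


def set_representative(crm: CRM, top_nominal_p: dict[tuple[str, str], float]) -> None:
    """Representative member = smallest top nominal p (display only)."""
    crm.representative = min(crm.members, key=lambda m: top_nominal_p.get(m, np.inf))


def merge_multigenic(
    monogenic_crms: list[CRM],
    eaps: dict[tuple[str, str], AssociationPattern],
    tss_map: dict[str, tuple[str, int]],
    matcher: Matcher,
    theta_min: float = 0.6,
    p_max: float = 0.05,
    require_p: bool = False,
    window_bp: int = 1_000_000,
) -> list[CRM]:
    """Merge monogenic cRMs across genes sharing association patterns.

    Cross-gene matching edges are tested for every EAP pair whose genes'
    TSSs lie within ``window_bp`` of each other (same chromosome); chained
    windows may extend components.  Components spanning more than one gene
    become multigenic cRMs; the rest pass through unchanged.
    """
    nodes = sorted(k for crm in monogenic_crms for k in crm.members)
    intra = [(u, v, t) for crm in monogenic_crms for (u, v, t) in crm.edges]
    cross = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if u[0] == v[0]:
                continue
            cu, tu = tss_map[u[0]]
            cv, tv = tss_map[v[0]]
            if cu != cv or abs(tu - tv) > window_bp:
                continue
            if u not in eaps or v not in eaps:
                continue
            res = matcher(eaps[u], eaps[v])
            if is_matching(res, theta_min, p_max, require_p=require_p):
                cross.append((u, v, res.theta))
    edges = intra + cross
    out = []
    for k, comp in enumerate(sorted(_components(nodes, [(u, v) for u, v, _ in edges]))):
        genes = {g for g, _ in comp}
        crm = CRM(
            crm_id=f"mcrm_{k}",
            members=list(comp),
            is_multigenic=len(genes) > 1,
            edges=[e for e in edges if e[0] in comp and e[1] in comp],
        )
        out.append(crm)
    return out


def extend_catalogue(
    significant_eaps: dict[tuple[str, str], AssociationPattern],
    nonsignificant_eaps: dict[tuple[str, str], AssociationPattern],
    theta_min: float = 0.6,
    **theta_kwargs,
) -> tuple[dict[tuple[str, str], AssociationPattern], dict[tuple[str, str], bool]]:
    """Extended catalogue: rescue sub-threshold EAPs matching a significant one.

    A non-significant EAP is added when its gene is significant in at least
    one condition and it matches (|theta| >= theta_min, theta alone) at
    least one significant EAP of the same gene.  Returns the extended
    catalogue and a provenance map marking rescued members.
    """
    sig_genes = {g for g, _ in significant_eaps}
    extended = dict(significant_eaps)
    rescued = {k: False for k in significant_eaps}
    for key, eap in sorted(nonsignificant_eaps.items()):
        gene, _ = key
        if gene not in sig_genes or key in extended:
            continue
        for (g2, c2), sig in significant_eaps.items():
            if g2 != gene:
                continue
            res = compute_theta(eap, sig, **theta_kwargs)
            if res.defined and abs(res.theta) >= theta_min:
                extended[key] = eap
                rescued[key] = True
                break
    return extended, rescued


def summarize_catalogue(crms: list[CRM]) -> dict:
    """Catalogue summary: pattern counts (upset-plot input), mean active
    conditions per cRM, reQTL fraction, mean genes per multigenic cRM."""
    if not crms:
        return {"n_crms": 0}
    patterns = pd.Series(
        ["|".join(sorted(set(crm.labels.values()))) if crm.labels else "?" for crm in crms]
    )
    n_conditions = [len(crm.conditions) for crm in crms]
    multigenic = [crm for crm in crms if crm.is_multigenic]
    return {
        "n_crms": len(crms),
        "pattern_counts": patterns.value_counts().to_dict(),
        "mean_conditions_per_crm": float(np.mean(n_conditions)),
        "reqtl_fraction": float(np.mean([crm.is_reqtl for crm in crms])),
        "n_multigenic": len(multigenic),
        "mean_genes_per_multigenic": (
            float(np.mean([len(crm.genes) for crm in multigenic])) if multigenic else 0.0
        ),
    }
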