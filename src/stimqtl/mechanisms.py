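"""Three mechanisms of condition-specific cis-regulation.

A monogenic cRM active in condition "a" but not "b" is explained by one of
three mechanisms, assigned in a fixed precedence order:

1. low expression — the target gene is expressed at too low a level in the
   inactive condition for any eQTL to be detectable;
2. effect loss — the gene remains well expressed but the genotype effect
   disappears in the inactive condition;
3. module switch — the gene is an eQTL in both conditions but through
   distinct regulatory variants, i.e. it splits across several cRMs.

Mechanism 1 is decided first (detectability), module switches next, and the
remaining detectable gaps fall to mechanism 2.  Mechanism 2 can be backed
by a condition-permutation test of effect attenuation
(:func:`surrogate_effect_loss_test`, a declared surrogate procedure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stimqtl.crm import CONDITION_ORDER, CRM

MECHANISMS = {1: "low_expression", 2: "effect_loss", 3: "module_switch"}


@dataclass
class DetectabilityRule:
    """When is a gene 'expressed enough' for an eQTL to be detectable.

    ``min_expressed_fraction``: fraction of samples with level > 0.
    ``min_mean_level``: mean normalized expression floor; by convention the
    10th percentile of eGene means in the condition under study (the source
    studies never quantify 'too low', so both knobs are explicit here).
    """

    min_expressed_fraction: float = 0.5
    min_mean_level: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_expressed_fraction <= 1):
            raise ValueError("min_expressed_fraction must be in [0, 1]")


@dataclass
class MechanismCall:
    """One classified condition-specific gap of a cRM."""

    gene_id: str
    crm_id: str
    condition: str
    mechanism: int | None  # 1, 2, 3 or None for unclassified
    evidence: dict = field(default_factory=dict)


def detectability_floor(egene_means: np.ndarray, percentile: float = 10.0) -> float:
    """Default mean-level floor: the given percentile of eGene means."""
    return float(np.percentile(np.asarray(egene_means, dtype=float), percentile))


def detectable(values: np.ndarray, rule: DetectabilityRule) -> bool:
    """True iff enough samples express the gene and the mean clears the floor."""
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("need >= 20 samples per condition for detectability")
    frac = float(np.mean(values > 0))
    return frac >= rule.min_expressed_fraction and float(values.mean()) >= rule.min_mean_level


def classify(
    gene_id: str,
    crms_for_gene: list[CRM],
    detectability_map: dict[str, bool],
    condition_order: tuple[str, ...] = CONDITION_ORDER,
    surrogate_test=None,
) -> list[MechanismCall]:
    """Mechanism calls for every inactive condition of each cRM of a gene.

    Precedence per 0-bit condition: (1) not detectable -> mechanism 1;
    (3) the condition is active in another cRM of the same gene -> mechanism
    3 (module switch); (2) otherwise -> mechanism 2, with an optional
    surrogate-test p-value attached via ``surrogate_test(condition_active,
    condition_inactive)``.
    """
    missing = [c for c in condition_order if c not in detectability_map]
    if missing:
        raise ValueError(f"detectability unknown for conditions {missing}")
    crms = [c for c in crms_for_gene if gene_id in c.genes]
    if not crms:
        return []
    active_anywhere: dict[str, set[str]] = {}
    for crm in crms:
        lbl = crm.labels.get(gene_id)
        if lbl is None:
            raise ValueError(f"cRM {crm.crm_id} lacks a label for {gene_id}")
        for i, cond in enumerate(condition_order):
            if lbl[i] == "1":
                active_anywhere.setdefault(cond, set()).add(crm.crm_id)
    calls: list[MechanismCall] = []
    for crm in sorted(crms, key=lambda c: c.crm_id):
        lbl = crm.labels[gene_id]
        if "0" not in lbl or "1" not in lbl:
            continue  # fully active or fully inactive pattern: nothing to explain
        active_conditions = [c for i, c in enumerate(condition_order) if lbl[i] == "1"]
        for i, cond in enumerate(condition_order):
            if lbl[i] == "1":
                continue
            evidence = {
                "detectable": detectability_map[cond],
                "n_crms_for_gene": len(crms),
                "label": lbl,
            }
            if not detectability_map[cond]:
                mech = 1
            elif cond in active_anywhere and active_anywhere[cond] - {crm.crm_id}:
                mech = 3
                evidence["other_crms"] = sorted(active_anywhere[cond] - {crm.crm_id})
            else:
                mech = 2
                if surrogate_test is not None:
                    evidence["surrogate_p"] = surrogate_test(active_conditions[0], cond)
            calls.append(
                MechanismCall(
                    gene_id=gene_id, crm_id=crm.crm_id, condition=cond,
                    mechanism=mech, evidence=evidence,
                )
            )
    return calls


def surrogate_effect_loss_test(
    dosage_a: np.ndarray,
    expr_a: np.ndarray,
    dosage_b: np.ndarray,
    expr_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Condition-permutation test of genotype-effect attenuation.

    Tests whether the absolute regression effect of the top variant in the
    inactive condition "b" is smaller than expected given the active
    condition "a", by permuting the condition assignment of paired samples
    and recomputing the |beta_a| - |beta_b| contrast.  Returns the empirical
    p-value (1 + k)/(n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if min(len(expr_a), len(expr_b)) < 50:
        raise ValueError("need >= 50 samples per condition")
    if len(expr_a) != len(expr_b):
        raise ValueError("surrogate test expects paired samples across conditions")

    def beta(x, y):
        xc = x - x.mean()
        denom = xc @ xc
        return (xc @ (y - y.mean())) / denom if denom > 0 else 0.0

    obs = abs(beta(dosage_a, expr_a)) - abs(beta(dosage_b, expr_b))
    rng = np.random.default_rng(seed)
    n = len(expr_a)
    exceed = 0
    for _ in range(n_perm):
        flip = rng.random(n) < 0.5
        ya = np.where(flip, expr_b, expr_a)
        yb = np.where(flip, expr_a, expr_b)
        xa = np.where(flip, dosage_b, dosage_a)
        xb = np.where(flip, dosage_a, dosage_b)
        stat = abs(beta(xa, ya)) - abs(beta(xb, yb))
        if stat >= obs - 1e-15:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def mechanism_census(calls: list[MechanismCall]) -> pd.DataFrame:
    """Fractions of classified cases per mechanism, with an explicit
    'unclassified' remainder row (fractions sum to 1 including it)."""
    if not calls:
        raise ValueError("no mechanism calls to summarize")
    counts = {1: 0, 2: 0, 3: 0, "unclassified": 0}
    for call in calls:
        counts[call.mechanism if call.mechanism in MECHANISMS else "unclassified"] += 1
    total = len(calls)
    rows = [
        {"mechanism": MECHANISMS.get(k, "unclassified"), "count": v, "fraction": v / total}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows)
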