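"""Association patterns (EAP/DAP): signed, windowed vectors of -log10 p.

An eQTL association pattern (EAP) is the vector of signed log10(1/p)
association scores for all variants in a gene's cis window; a disease
association pattern (DAP) is the analogous vector built from GWAS summary
statistics around a risk locus.  The sign of the regression beta is folded
into the score so that pattern correlation captures both the shape of the
association peak and the coherence of allelic effect directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # underflow guard before taking logs
AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

PATTERN_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p", "score"]


def signed_score(beta: np.ndarray, p: np.ndarray) -> np.ndarray:
    """sign(beta) * log10(1/p), with p floored at 1e-300."""
    return np.sign(beta) * np.log10(1.0 / np.maximum(np.asarray(p, dtype=float), P_FLOOR))


@dataclass
class VariantKey:
    """Position + unordered allele pair; identical under allele swap."""

    chrom: str
    pos: int
    alleles: frozenset

    @classmethod
    def of(cls, chrom, pos, a1: str, a2: str) -> "VariantKey":
        return cls(str(chrom), int(pos), frozenset({a1.upper(), a2.upper()}))

    @property
    def is_ambiguous(self) -> bool:
        return self.alleles in AMBIGUOUS_PAIRS

    def __hash__(self):
        return hash((self.chrom, self.pos, self.alleles))


@dataclass
class AssociationPattern:
    """EAP or DAP: per-variant signed scores inside a fixed window.

    ``table`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    beta, p, score; rows sorted by position.  ``kind`` is "eap" or "dap";
    ``trait_id`` is the gene (EAP) or risk-locus id (DAP); ``context`` the
    stimulation condition or disease name.
    """

    kind: str
    trait_id: str
    context: str
    chrom: str
    start: int
    end: int
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        if len(t) == 0:
            raise ValueError("empty association pattern")
        if ((t["pos"] < self.start) | (t["pos"] > self.end)).any():
            raise ValueError("pattern entries outside window")
        if not np.isfinite(t["score"]).all():
            raise ValueError("non-finite scores")

    @property
    def top_variant(self) -> str:
        """Variant with the smallest p (max log10(1/p)); first on ties."""
        return str(self.table.loc[self.table["p"].idxmin(), "variant_id"])

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey.of(r.chrom, r.pos, r.effect_allele, r.other_allele)
            for r in self.table.itertuples()
        ]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path, kind, trait_id, context, chrom=None, start=None, end=None):
        t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if chrom is None:
            chrom = str(t["chrom"].iloc[0])
        if start is None:
            start = int(t["pos"].min())
        if end is None:
            end = int(t["pos"].max())
        return cls(kind=kind, trait_id=trait_id, context=context, chrom=chrom,
                   start=start, end=end, table=t)


def _pattern_table(records: pd.DataFrame) -> pd.DataFrame:
    rec = records.copy()
    effect = rec["alt_allele"] if "alt_allele" in rec else rec["effect_allele"]
    other = rec["ref_allele"] if "ref_allele" in rec else rec["other_allele"]
    out = pd.DataFrame(
        {
            "variant_id": rec["variant_id"].astype(str),
            "chrom": rec["chrom"].astype(str),
            "pos": rec["pos"].astype(int),
            "effect_allele": effect.astype(str).str.upper(),
            "other_allele": other.astype(str).str.upper(),
            "beta": rec["beta"].astype(float),
            "p": rec["p"].astype(float),
        }
    )
    out["score"] = signed_score(out["beta"].to_numpy(), out["p"].to_numpy())
    return out.sort_values("pos", kind="stable").reset_index(drop=True)


def build_eap(
    records: pd.DataFrame,
    gene_id: str,
    condition: str,
    chrom: str,
    tss: int,
    window_bp: int = 1_000_000,
) -> AssociationPattern:
    """EAP from nominal association records in the +/- window around the TSS."""
    rec = records[(records["chrom"].astype(str) == str(chrom))
                  & (np.abs(records["pos"] - tss) <= window_bp)]
    if len(rec) == 0:
        raise ValueError(f"no records within {window_bp} bp of TSS for {gene_id}")
    return AssociationPattern(
        kind="eap",
        trait_id=gene_id,
        context=condition,
        chrom=str(chrom),
        start=tss - window_bp,
        end=tss + window_bp,
        table=_pattern_table(rec),
        provenance={"tss": tss, "window_bp": window_bp},
    )


def build_dap(
    summary: pd.DataFrame,
    locus_id: str,
    disease: str,
    chrom: str,
    start: int,
    end: int,
) -> AssociationPattern:
    """DAP from GWAS summary statistics restricted to a per-locus window.

    Windows are supplied externally (configuration stands in for the manual
    inspection of the -log10 p landscape around each risk locus); see
    :func:`suggest_dap_window` for an automated suggestion.
    """
    rec = summary[(summary["chrom"].astype(str) == str(chrom))
                  & (summary["pos"] >= start) & (summary["pos"] <= end)]
    rec = rec.dropna(subset=["beta", "p"])
    if len(rec) == 0:
        raise ValueError(f"no variants in DAP window {chrom}:{start}-{end}")
    return AssociationPattern(
        kind="dap",
        trait_id=locus_id,
        context=disease,
        chrom=str(chrom),
        start=int(start),
        end=int(end),
        table=_pattern_table(rec),
    )


def suggest_dap_window(summary: pd.DataFrame, min_log10p: float = 2.0) -> dict:
    """Suggested locus window: contiguous run with -log10 p >= threshold
    around the top SNP.  A helper for eyeballing only, not a decision rule."""
    s = summary.dropna(subset=["p"]).sort_values("pos").reset_index(drop=True)
    lp = -np.log10(np.maximum(s["p"].to_numpy(), P_FLOOR))
    top = int(np.argmax(lp))
    lo = top
    while lo > 0 and lp[lo - 1] >= min_log10p:
        lo -= 1
    hi = top
    while hi < len(s) - 1 and lp[hi + 1] >= min_log10p:
        hi += 1
    return {
        "chrom": str(s.loc[top, "chrom"]),
        "start": int(s.loc[lo, "pos"]),
        "end": int(s.loc[hi, "pos"]),
        "suggestion_only": True,
    }


def harmonize_alleles(
    a: AssociationPattern, b: AssociationPattern
) -> tuple[AssociationPattern, AssociationPattern, dict]:
    """Match two patterns by position + allele pair and align effect alleles.

    Variants present in both patterns are kept; where the effect allele of
    ``b`` equals the other allele of ``a``, b's beta and score signs are
    flipped so both patterns refer to the same allele.  Strand-ambiguous
    A/T and C/G variants are dropped, as are unmatched variants.  The report
    counts every action taken.
    """
    if a.chrom != b.chrom:
        raise ValueError("patterns on different chromosomes")
    ka = {k: i for i, k in enumerate(a.keys())}
    kb = {k: i for i, k in enumerate(b.keys())}
    shared = [k for k in ka if k in kb]
    report = {
        "ambiguous_dropped": sum(1 for k in shared if k.is_ambiguous),
        "unmatched_a": len(ka) - len(shared),
        "unmatched_b": len(kb) - len(shared),
        "flipped": 0,
    }
    shared = [k for k in shared if not k.is_ambiguous]
    if not shared:
        raise ValueError("zero shared variants after harmonization")
    ta = a.table.iloc[[ka[k] for k in shared]].reset_index(drop=True)
    tb = b.table.iloc[[kb[k] for k in shared]].reset_index(drop=True)
    swap = (tb["effect_allele"].to_numpy() == ta["other_allele"].to_numpy())
    report["flipped"] = int(swap.sum())
    report["matched"] = len(shared)
    tb = tb.copy()
    tb.loc[swap, ["effect_allele", "other_allele"]] = tb.loc[
        swap, ["other_allele", "effect_allele"]
    ].to_numpy()
    tb.loc[swap, "beta"] = -tb.loc[swap, "beta"]
    tb.loc[swap, "score"] = -tb.loc[swap, "score"]
    out_a = AssociationPattern(a.kind, a.trait_id, a.context, a.chrom, a.start, a.end, ta,
                               dict(a.provenance))
    out_b = AssociationPattern(b.kind, b.trait_id, b.context, b.chrom, b.start, b.end, tb,
                               dict(b.provenance))
    logger.debug("harmonization report: %s", report)
    return out_a, out_b, report
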