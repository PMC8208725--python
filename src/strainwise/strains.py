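"""Pairwise strain categorization of genes and enhancers, and cis/trans calls.

Strain-differential induced genes/enhancers fall into three categories by the
basal-level ratio between the noninduced and the induced strain:

* ``high_basal`` — the noninduced strain already has >= ``*_basal_fc`` higher
  basal activity (the element/gene has little room to respond);
* ``low_basal``  — the induced strain has the higher basal level (the
  noninduced strain never builds the element);
* ``equal_basal`` — anything in between (only the response differs).

All ratios use a pseudocount of 1.  Threshold comparisons: the basal-category
ratio is inclusive (>=), the similar/tier comparisons are strict, matching the
documented boundary rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from strainwise.config import PipelineConfig
from strainwise.io import GenomicInterval

__all__ = [
    "call_induced_genes", "categorize_gene", "categorize_enhancer",
    "differential_tiers", "variant_overlap_fraction",
    "cis_trans_classify", "assign_f1_allelic_counts",
]

CATEGORIES = ("low_basal", "equal_basal", "high_basal")


def call_induced_genes(expr: pd.DataFrame, strain: str, cfg: PipelineConfig,
                       q_threshold: float = 0.05) -> pd.DataFrame:
    """Flag genes as induced / repressed for one strain.

    induced  = (mean stim TPM + 1) / (mean basal TPM + 1) > gene_induce_fc AND q < 0.05;
    repressed analogously with the reciprocal fold change.  ``q`` is the
    adjusted p-value of the induction contrast, consumed from the input table.
    """
    sub = expr[expr["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no expression rows for strain {strain!r}")
    mean_tpm = (sub.groupby(["gene_id", "condition"])["tpm"].mean().unstack())
    for cond in ("basal", "stimulated"):
        if cond not in mean_tpm.columns or mean_tpm[cond].isna().any():
            bad = mean_tpm.index[mean_tpm.get(cond, pd.Series(np.nan, mean_tpm.index))
                                 .isna()]
            name = bad[0] if len(bad) else "<all>"
            raise ValueError(f"gene {name!r} missing condition {cond!r} "
                             f"for strain {strain!r}")
    fc = (mean_tpm["stimulated"] + 1.0) / (mean_tpm["basal"] + 1.0)

    if "q" in sub.columns:
        q = sub.groupby("gene_id")["q"].first().reindex(fc.index)
    else:
        q = pd.Series(np.nan, index=fc.index)
    q_ok = q.fillna(1.0) < q_threshold

    return pd.DataFrame({
        "gene_id": fc.index,
        "strain": strain,
        "fc": fc.to_numpy(),
        "q": q.to_numpy(),
        "induced": ((fc > cfg.gene_induce_fc) & q_ok).to_numpy(),
        "repressed": ((fc < 1.0 / cfg.gene_induce_fc) & q_ok).to_numpy(),
        "basal_tpm": mean_tpm["basal"].to_numpy(),
        "stim_tpm": mean_tpm["stimulated"].to_numpy(),
    }).reset_index(drop=True)


def _basal_category(basal_induced: float, basal_noninduced: float,
                    threshold: float) -> tuple[str, float]:
    """Shared low/equal/high rule.  Returns (category, noninduced/induced ratio)."""
    ratio_high = (basal_noninduced + 1.0) / (basal_induced + 1.0)
    if ratio_high >= threshold:
        return "high_basal", ratio_high
    if 1.0 / ratio_high >= threshold:
        return "low_basal", ratio_high
    return "equal_basal", ratio_high


def categorize_gene(basal_induced_strain: float, basal_noninduced_strain: float,
                    cfg: PipelineConfig) -> str:
    """Category of a gene induced in exactly one strain of a pair, from basal TPM."""
    cat, _ = _basal_category(basal_induced_strain, basal_noninduced_strain,
                             cfg.gene_basal_fc)
    return cat


def categorize_enhancer(basal_induced_strain: float, basal_noninduced_strain: float,
                        fc_induced_strain: float, fc_noninduced_strain: float,
                        cfg: PipelineConfig) -> str | None:
    """Category of an enhancer induced in exactly one strain, from basal H3K27ac.

    Eligible only when the two strains' H3K27ac induction fold changes differ
    more than ``gene_induce_fc``-fold; returns None for ineligible pairs.
    """
    if fc_noninduced_strain <= 0 or fc_induced_strain <= 0:
        raise ValueError("fold changes must be positive")
    if fc_induced_strain / fc_noninduced_strain <= cfg.gene_induce_fc:
        return None
    cat, _ = _basal_category(basal_induced_strain, basal_noninduced_strain,
                             cfg.enhancer_basal_fc)
    return cat


def differential_tiers(h3k27ac_a: pd.Series, h3k27ac_b: pd.Series,
                       cfg: PipelineConfig) -> pd.DataFrame:
    """Assign each element a strain-similar flag and cumulative difference tiers.

    ``ratio`` is the larger-over-smaller stimulated H3K27ac ratio between the
    two strains (pseudocount 1).  similar when ratio < similar_fc; a tier
    ``>t`` contains every element with ratio strictly above t, so tiers nest.
    """
    a = h3k27ac_a.astype(float)
    b = h3k27ac_b.reindex(a.index).astype(float)
    r = (a + 1.0) / (b + 1.0)
    ratio = np.maximum(r, 1.0 / r)
    out = pd.DataFrame({"element_id": a.index, "ratio": ratio.to_numpy()})
    out["similar"] = out["ratio"] < cfg.similar_fc
    for t in cfg.differential_tiers:
        out[f"tier_gt_{t:g}"] = out["ratio"] > t
    return out.reset_index(drop=True)


def variant_overlap_fraction(groups: dict[str, list[GenomicInterval]],
                             variants: pd.DataFrame, cfg: PipelineConfig,
                             strain: str | None = None) -> dict[str, float | None]:
    """Fraction of elements per group with >= 1 variant within +-variant_window_bp
    of the element center (window inclusive of both ends)."""
    sub = variants if strain is None else variants[variants["strain"] == strain]
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in sub.groupby("chrom")}
    out: dict[str, float | None] = {}
    for name, ivs in groups.items():
        if not ivs:
            out[name] = None
            continue
        hits = 0
        for iv in ivs:
            positions = pos_by_chrom.get(iv.chrom)
            if positions is None:
                continue
            lo = iv.center - cfg.variant_window_bp
            hi = iv.center + cfg.variant_window_bp
            if np.searchsorted(positions, hi, "right") > np.searchsorted(positions, lo):
                hits += 1
        out[name] = hits / len(ivs)
    return out


def element_has_variant(iv: GenomicInterval, positions: np.ndarray,
                        window_bp: int) -> bool:
    lo, hi = iv.center - window_bp, iv.center + window_bp
    return bool(np.searchsorted(positions, hi, "right")
                > np.searchsorted(positions, lo))


@dataclass(frozen=True)
class CisTransCall:
    label: str          # cis | trans | unclassified
    parental_log2: float
    f1_log2: float


def cis_trans_classify(parental_fc: float, f1_fc: float,
                       cfg: PipelineConfig) -> str:
    """Classify a gene's strain difference as cis, trans, or unclassified.

    cis: |log2 parental - log2 F1| < cis_window_log2 (the allelic ratio is
    preserved in the hybrid).  trans: the parental difference is at least
    parental_fc_min-fold (either direction) and the F1 allelic ratio is
    attenuated toward 1 (|log2 F1| < |log2 parental|).
    """
    if parental_fc <= 0 or f1_fc <= 0:
        raise ValueError("fold changes must be positive")
    lp, lf = np.log2(parental_fc), np.log2(f1_fc)
    if abs(lp - lf) < cfg.cis_window_log2:
        return "cis"
    if abs(lp) >= np.log2(cfg.parental_fc_min) and abs(lf) < abs(lp):
        return "trans"
    return "unclassified"


def assign_f1_allelic_counts(total_count: float, informative_a: float,
                             informative_b: float) -> tuple[float, float, bool]:
    """Split a transcript's total F1 read count between parental alleles in
    proportion to allele-informative (variant-overlapping) reads.

    Returns (count_a, count_b, filtered); transcripts with zero informative
    reads for either allele are flagged filtered and get no counts.
    """
    if total_count < 0 or informative_a < 0 or informative_b < 0:
        raise ValueError("counts must be non-negative")
    if informative_a == 0 or informative_b == 0:
        return np.nan, np.nan, True
    frac_a = informative_a / (informative_a + informative_b)
    return total_count * frac_a, total_count * (1.0 - frac_a), False
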