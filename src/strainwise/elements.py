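"""Responsive-element calling and super-enhancer identification.

Elements are classified from paired basal/stimulated signals of two activity
markers (H3K27ac and RNA Pol II).  An element is *induced* when both markers
rise at least ``induce_fc``-fold, *repressed* when both fall at least that
much, *neutral* when both stay within the ``neutral_fc`` band, *ambiguous*
otherwise, and *below_minimum* when neither condition reaches the minimum tag
thresholds.  Fold changes use a pseudocount of 1 on normalized tags.

Super enhancers are called ROSE-style: enhancers are stitched within
``stitch_dist_bp``, signal within ``tss_exclusion_bp`` of a TSS is excluded,
regions are ranked by total signal, and the cutoff sits where the tangent to
the [0, 1]-scaled rank-signal curve reaches slope 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from strainwise.config import PipelineConfig
from strainwise.io import GenomicInterval

__all__ = [
    "BASAL", "STIM", "H3K27AC", "POLII", "ATAC",
    "ElementCall", "SuperEnhancerCall",
    "classify_elements", "annotate_context", "call_super_enhancers",
    "response_variance_test", "fold_change",
]

# canonical condition / assay labels used throughout the pipeline
BASAL = "basal"
STIM = "stimulated"
H3K27AC = "H3K27ac"
POLII = "PolII"
ATAC = "ATAC"

STATES = ("induced", "repressed", "neutral", "ambiguous", "below_minimum")


@dataclass(frozen=True)
class ElementCall:
    element_id: str
    strain: str
    state: str
    fc_h3k27ac: float
    fc_polii: float


@dataclass
class SuperEnhancerCall:
    chrom: str
    start: int
    end: int
    member_ids: list
    total_signal: float
    is_super: bool
    rank: int  # 1 = strongest


def fold_change(stim: float, basal: float, pseudocount: float = 1.0) -> float:
    """(stim + 1) / (basal + 1); pseudocount stabilizes zero tag counts."""
    return (stim + pseudocount) / (basal + pseudocount)


def _signal_lookup(signals: pd.DataFrame, strain: str) -> pd.DataFrame:
    """Pivot to one row per element with H3K27ac/PolII x basal/stim columns."""
    sub = signals[(signals["strain"] == strain)
                  & (signals["assay"].isin([H3K27AC, POLII]))]
    if sub.empty:
        raise ValueError(f"no H3K27ac/PolII signal rows for strain {strain!r}")
    # replicates are averaged before fold-change computation
    agg = (sub.groupby(["element_id", "assay", "condition"])["value"]
           .mean().unstack(["assay", "condition"]))
    wanted = pd.MultiIndex.from_product([[H3K27AC, POLII], [BASAL, STIM]])
    agg = agg.reindex(columns=wanted)
    incomplete = agg.isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"element {agg.index[incomplete][0]!r} lacks a condition or assay "
            f"for strain {strain!r}")
    return agg


def classify_elements(signals: pd.DataFrame, strain: str,
                      cfg: PipelineConfig) -> list[ElementCall]:
    """Classify every element of a strain as induced/repressed/neutral/....

    Requires H3K27ac and RNA Pol II values in both conditions for each
    element; replicate rows are averaged first.
    """
    agg = _signal_lookup(signals, strain)
    k_b = agg[(H3K27AC, BASAL)].to_numpy()
    k_s = agg[(H3K27AC, STIM)].to_numpy()
    p_b = agg[(POLII, BASAL)].to_numpy()
    p_s = agg[(POLII, STIM)].to_numpy()

    fc_k = (k_s + 1.0) / (k_b + 1.0)
    fc_p = (p_s + 1.0) / (p_b + 1.0)

    below = (np.maximum(k_b, k_s) < cfg.min_h3k27ac) \
        | (np.maximum(p_b, p_s) < cfg.min_polii)
    induced = (fc_k >= cfg.induce_fc) & (fc_p >= cfg.induce_fc)
    repressed = (fc_k <= 1.0 / cfg.induce_fc) & (fc_p <= 1.0 / cfg.induce_fc)
    neutral = ((fc_k > 1.0 / cfg.neutral_fc) & (fc_k < cfg.neutral_fc)
               & (fc_p > 1.0 / cfg.neutral_fc) & (fc_p < cfg.neutral_fc))

    calls = []
    for i, element_id in enumerate(agg.index):
        if below[i]:
            state = "below_minimum"
        elif induced[i]:
            state = "induced"
        elif repressed[i]:
            state = "repressed"
        elif neutral[i]:
            state = "neutral"
        else:
            state = "ambiguous"
        calls.append(ElementCall(element_id, strain, state,
                                 float(fc_k[i]), float(fc_p[i])))
    return calls


def calls_to_frame(calls: list[ElementCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def annotate_context(intervals: list[GenomicInterval], tss_list: list[tuple[str, int]],
                     promoter_window_bp: int = 1000) -> list[GenomicInterval]:
    """Assign kind=promoter to elements whose center lies within
    ``promoter_window_bp`` (inclusive) of a TSS, kind=enhancer otherwise."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss_list:
        tss_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(p)) for c, p in tss_by_chrom.items()}

    out = []
    for iv in intervals:
        positions = tss_by_chrom.get(iv.chrom)
        if positions is None or len(positions) == 0:
            out.append(iv.with_kind("enhancer"))
            continue
        idx = np.searchsorted(positions, iv.center)
        nearest = min(
            (abs(iv.center - positions[j]) for j in (idx - 1, idx)
             if 0 <= j < len(positions)),
            default=np.inf)
        kind = "promoter" if nearest <= promoter_window_bp else "enhancer"
        out.append(iv.with_kind(kind))
    return out


# --------------------------------------------------------------------------
# super enhancers


def _stitch(intervals: list[GenomicInterval], stitch_dist_bp: int
            ) -> list[list[GenomicInterval]]:
    groups: list[list[GenomicInterval]] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if groups and groups[-1][-1].chrom == iv.chrom \
                and iv.start - max(m.end for m in groups[-1]) <= stitch_dist_bp:
            groups[-1].append(iv)
        else:
            groups.append([iv])
    return groups


def _tangent_cutoff(signals: np.ndarray) -> float:
    """ROSE cutoff: signal value where the slope of the [0,1]-scaled, ascending
    rank-signal curve crosses 1.  Returns +inf for a degenerate flat curve
    (all-equal signals -> no super enhancers)."""
    y = np.sort(np.asarray(signals, dtype=float))
    n = len(y)
    if n < 3:
        raise ValueError("super-enhancer cutoff undefined for fewer than 3 regions")
    span = y[-1] - y[0]
    if span == 0:
        return np.inf
    ys = (y - y[0]) / span
    xs = np.arange(n, dtype=float) / (n - 1)
    # hockey-stick curve: the slope-1 tangent point minimizes ys - xs
    i = int(np.argmin(ys - xs))
    return float(y[i])


def call_super_enhancers(enhancers: list[GenomicInterval], signals: pd.DataFrame,
                         tss_list: list[tuple[str, int]], cfg: PipelineConfig,
                         strain: str | None = None, condition: str = STIM,
                         assay: str = H3K27AC) -> list[SuperEnhancerCall]:
    """Stitch enhancers, rank by TSS-excluded total signal, apply the tangent
    cutoff, and flag regions above it as super enhancers."""
    sub = signals[(signals["assay"] == assay) & (signals["condition"] == condition)]
    if strain is not None:
        sub = sub[sub["strain"] == strain]
    per_element = sub.groupby("element_id")["value"].mean()

    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss_list:
        tss_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(p)) for c, p in tss_by_chrom.items()}

    def near_tss(iv: GenomicInterval) -> bool:
        positions = tss_by_chrom.get(iv.chrom)
        if positions is None or len(positions) == 0:
            return False
        idx = np.searchsorted(positions, iv.center)
        return any(abs(iv.center - positions[j]) <= cfg.tss_exclusion_bp
                   for j in (idx - 1, idx) if 0 <= j < len(positions))

    groups = _stitch(enhancers, cfg.stitch_dist_bp)
    regions = []
    for members in groups:
        total = float(sum(per_element.get(m.id, 0.0)
                          for m in members if not near_tss(m)))
        regions.append((members, total))
    if len(regions) < 3:
        raise ValueError("fewer than 3 stitched regions: rank curve undefined")

    totals = np.array([t for _, t in regions])
    cutoff = _tangent_cutoff(totals)
    order = np.argsort(-totals)
    ranks = np.empty(len(regions), dtype=int)
    ranks[order] = np.arange(1, len(regions) + 1)

    out = []
    for i, (members, total) in enumerate(regions):
        out.append(SuperEnhancerCall(
            chrom=members[0].chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            member_ids=[m.id for m in members],
            total_signal=total,
            is_super=bool(total > cutoff),
            rank=int(ranks[i]),
        ))
    return out


def response_variance_test(fc_super: np.ndarray, fc_conventional: np.ndarray
                           ) -> tuple[float, float]:
    """Levene's test (center=median) on log2 fold-change dispersion of super
    vs conventional enhancers.  Returns (statistic, p)."""
    a = np.log2(np.asarray(fc_super, dtype=float))
    b = np.log2(np.asarray(fc_conventional, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 fold changes per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("both groups constant; Levene's test degenerate, p = 1")
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center="median")
    return float(stat), float(p)
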