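"""Interaction classification and enhancer-connectivity attribution.

Proximity-ligation anchor pairs are matched to annotated elements when the
gap between closest edges is at most ``merge_dist_bp`` (or they overlap);
an anchor matching both a promoter and an enhancer takes the promoter
(conservative for enhancer-promoter counts).  The classified pairs feed:

* a (promoter state x enhancer state) contingency table with Fisher tests of
  the three collapsed comparisons of interest;
* the connected-vs-unconnected cross-strain activity-correlation comparison;
* attribution of strain-differential enhancers to local vs connected
  predicted-functional variants (local_only / both_ends / connected_only /
  neither).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from strainwise.config import PipelineConfig
from strainwise.io import GenomicInterval

__all__ = [
    "ClassifiedInteraction", "classify_interactions",
    "promoter_enhancer_contingency", "connected_correlation_comparison",
    "attribute_differential_enhancers", "cohens_d",
]

INTERACTION_CLASSES = ("enhancer-enhancer", "enhancer-promoter",
                       "promoter-promoter", "unassigned")


@dataclass
class ClassifiedInteraction:
    row: int                      # index into the interaction table
    cls: str
    element1: str | None          # matched element id per anchor (or None)
    element2: str | None


def _match_anchor(chrom: str, start: int, end: int,
                  by_chrom: dict, merge_dist: int) -> GenomicInterval | None:
    """Closest element within merge_dist of the anchor; when an anchor
    matches a promoter and an enhancer at the same gap (e.g. overlaps both),
    the promoter wins."""
    candidates = by_chrom.get(chrom, [])
    best: tuple[int, int, GenomicInterval] | None = None
    for iv in candidates:
        gap = max(iv.start - end, start - iv.end, 0)
        if gap > merge_dist:
            continue
        kind_rank = 0 if iv.kind == "promoter" else 1
        key = (gap, kind_rank)
        if best is None or key < best[:2]:
            best = (gap, kind_rank, iv)
    return best[2] if best else None


def classify_interactions(interactions: pd.DataFrame,
                          elements: list[GenomicInterval],
                          cfg: PipelineConfig) -> list[ClassifiedInteraction]:
    """Classify each anchor pair as E-E / E-P / P-P / unassigned."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in elements:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    out = []
    for i, r in interactions.iterrows():
        m1 = _match_anchor(r["chrom1"], int(r["start1"]), int(r["end1"]),
                           by_chrom, cfg.merge_dist_bp)
        m2 = _match_anchor(r["chrom2"], int(r["start2"]), int(r["end2"]),
                           by_chrom, cfg.merge_dist_bp)
        if m1 is None or m2 is None:
            cls = "unassigned"
        else:
            kinds = sorted([m1.kind, m2.kind])
            if kinds == ["enhancer", "enhancer"]:
                cls = "enhancer-enhancer"
            elif kinds == ["enhancer", "promoter"]:
                cls = "enhancer-promoter"
            elif kinds == ["promoter", "promoter"]:
                cls = "promoter-promoter"
            else:
                cls = "unassigned"
        out.append(ClassifiedInteraction(
            int(i), cls,
            m1.id if m1 is not None else None,
            m2.id if m2 is not None else None))
    return out


def promoter_enhancer_contingency(classified: list[ClassifiedInteraction],
                                  elements: list[GenomicInterval],
                                  states: dict[str, str]
                                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """3x3 table of E-P interaction counts by (promoter state, enhancer state)
    over states {induced, neutral, repressed}, with Fisher tests of the three
    collapsed comparisons: induced vs non-induced, repressed vs non-repressed,
    induced vs repressed."""
    kind = {iv.id: iv.kind for iv in elements}
    levels = ["induced", "neutral", "repressed"]
    table = pd.DataFrame(0, index=levels, columns=levels)
    table.index.name = "promoter_state"
    table.columns.name = "enhancer_state"
    for ci in classified:
        if ci.cls != "enhancer-promoter":
            continue
        e1, e2 = ci.element1, ci.element2
        prom, enh = (e1, e2) if kind.get(e1) == "promoter" else (e2, e1)
        ps, es = states.get(prom), states.get(enh)
        if ps in levels and es in levels:
            table.loc[ps, es] += 1
    if table.to_numpy().sum() == 0:
        raise ValueError("no classifiable enhancer-promoter interactions")

    t = table.to_numpy()
    tot = t.sum()

    def collapse(row_mask: np.ndarray, col_mask: np.ndarray) -> float:
        a = t[np.ix_(row_mask, col_mask)].sum()
        b = t[np.ix_(row_mask, ~col_mask)].sum()
        c = t[np.ix_(~row_mask, col_mask)].sum()
        d = tot - a - b - c
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])

    ind = np.array([lev == "induced" for lev in levels])
    rep = np.array([lev == "repressed" for lev in levels])
    pvals = {
        "induced_vs_noninduced": collapse(ind, ind),
        "repressed_vs_nonrepressed": collapse(rep, rep),
    }
    # induced vs repressed: restrict to those rows/cols
    sub = t[np.ix_(ind | rep, ind | rep)]
    if sub.shape == (2, 2):
        pvals["induced_vs_repressed"] = float(
            stats.fisher_exact(sub, alternative="two-sided")[1])
    else:
        pvals["induced_vs_repressed"] = float("nan")
    return table, pvals


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    return float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0


def _pair_correlations(pairs: list[tuple[str, str]],
                       mat: pd.DataFrame) -> np.ndarray:
    out = []
    for e1, e2 in pairs:
        if e1 not in mat.index or e2 not in mat.index:
            continue
        v1, v2 = mat.loc[e1].to_numpy(), mat.loc[e2].to_numpy()
        if v1.std() == 0 or v2.std() == 0:
            continue
        out.append(float(np.corrcoef(v1, v2)[0, 1]))
    return np.asarray(out)


def connected_correlation_comparison(classified: list[ClassifiedInteraction],
                                     signals: pd.DataFrame,
                                     elements: list[GenomicInterval],
                                     cfg: PipelineConfig,
                                     condition: str = "stimulated",
                                     seed: int = 0) -> dict:
    """Cross-strain H3K27ac correlation of connected enhancer pairs vs two
    null constructions (same-chromosome random pairs; distance-matched
    unconnected pairs), compared by Mann-Whitney U with Cohen's d.

    Enhancers are preselected by a between-strain fold-change filter
    (max/min strain signal >= corr_pair_fc, pseudocount 1).
    """
    sub = signals[(signals["assay"] == "H3K27ac")
                  & (signals["condition"] == condition)]
    mat = sub.pivot_table(index="element_id", columns="strain",
                          values="value", aggfunc="mean")
    if mat.shape[1] < 3:
        raise ValueError("cross-strain correlation needs >= 3 strains")
    ratio = (mat.max(axis=1) + 1.0) / (mat.min(axis=1) + 1.0)
    selected = set(mat.index[ratio >= cfg.corr_pair_fc])
    centers = {iv.id: iv.center for iv in elements}

    connected_pairs = []
    connected_set = set()
    for ci in classified:
        if ci.cls != "enhancer-enhancer":
            continue
        if ci.element1 in selected and ci.element2 in selected \
                and ci.element1 != ci.element2:
            connected_pairs.append((ci.element1, ci.element2))
            connected_set.add(frozenset((ci.element1, ci.element2)))
    if not connected_pairs:
        raise ValueError("no connected enhancer pairs after preselection")

    rng = np.random.default_rng(seed)
    ids = sorted(selected & set(centers))

    random_pairs = []
    while len(random_pairs) < max(len(connected_pairs), 50) and len(ids) >= 2:
        i, j = rng.choice(len(ids), size=2, replace=False)
        key = frozenset((ids[i], ids[j]))
        if key not in connected_set:
            random_pairs.append((ids[int(i)], ids[int(j)]))

    # distance-matched: unconnected pairs whose separation falls in the same
    # distance bin as a connected pair
    bin_bp = cfg.null_distance_bin_bp
    conn_bins = {int(abs(centers[a] - centers[b]) // bin_bp)
                 for a, b in connected_pairs if a in centers and b in centers}
    matched_pairs = []
    tries = 0
    while len(matched_pairs) < max(len(connected_pairs), 50) and tries < 20000:
        tries += 1
        i, j = rng.choice(len(ids), size=2, replace=False)
        a, b = ids[int(i)], ids[int(j)]
        if frozenset((a, b)) in connected_set:
            continue
        if int(abs(centers[a] - centers[b]) // bin_bp) in conn_bins:
            matched_pairs.append((a, b))

    r_conn = _pair_correlations(connected_pairs, mat)
    r_rand = _pair_correlations(random_pairs, mat)
    r_match = _pair_correlations(matched_pairs, mat)

    out = {"r_connected": r_conn, "r_random": r_rand,
           "r_distance_matched": r_match}
    for name, null in (("random", r_rand), ("distance_matched", r_match)):
        if len(null) >= 2 and len(r_conn) >= 2:
            u, p = stats.mannwhitneyu(r_conn, null, alternative="two-sided")
            out[f"p_vs_{name}"] = float(p)
            out[f"d_vs_{name}"] = cohens_d(r_conn, null)
        else:
            out[f"p_vs_{name}"] = float("nan")
            out[f"d_vs_{name}"] = float("nan")
    return out


ATTRIBUTIONS = ("local_only", "both_ends", "connected_only", "neither")


def attribute_differential_enhancers(differential_ids: list[str],
                                     flagged_variants: pd.DataFrame,
                                     classified: list[ClassifiedInteraction],
                                     elements: list[GenomicInterval],
                                     cfg: PipelineConfig) -> pd.DataFrame:
    """Attribute each strain-differential enhancer to local and/or connected
    predicted-functional variants.

    A variant counts as *local* to an element when it lies within
    +-variant_window_bp of the element center; *connected* when local to any
    enhancer linked by a classified E-E interaction.  Every differential
    enhancer receives exactly one of local_only / both_ends / connected_only
    / neither.
    """
    flagged = flagged_variants[flagged_variants["predicted_functional"]]
    pos_by_chrom = {c: np.sort(g["pos"].to_numpy())
                    for c, g in flagged.groupby("chrom")}
    by_id = {iv.id: iv for iv in elements}

    def has_local_flag(eid: str) -> bool:
        iv = by_id.get(eid)
        if iv is None:
            return False
        positions = pos_by_chrom.get(iv.chrom)
        if positions is None:
            return False
        lo = iv.center - cfg.variant_window_bp
        hi = iv.center + cfg.variant_window_bp
        return bool(np.searchsorted(positions, hi, "right")
                    > np.searchsorted(positions, lo))

    neighbors: dict[str, set[str]] = {}
    for ci in classified:
        if ci.cls != "enhancer-enhancer" or ci.element1 is None \
                or ci.element2 is None:
            continue
        neighbors.setdefault(ci.element1, set()).add(ci.element2)
        neighbors.setdefault(ci.element2, set()).add(ci.element1)

    rows = []
    for eid in differential_ids:
        local = has_local_flag(eid)
        connected = any(has_local_flag(n) for n in neighbors.get(eid, ())
                        if n != eid)
        if local and connected:
            label = "both_ends"
        elif local:
            label = "local_only"
        elif connected:
            label = "connected_only"
        else:
            label = "neither"
        rows.append({"element_id": eid, "attribution": label,
                     "n_connected": len(neighbors.get(eid, ()))})
    return pd.DataFrame(rows)
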