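from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from strainwise import connectivity as cn
from strainwise import simulate as sim
from strainwise.io import GenomicInterval


def _elements():
    return [
        GenomicInterval("c", 10_000, 10_300, "p1", "promoter"),
        GenomicInterval("c", 40_000, 40_300, "p2", "promoter"),
        GenomicInterval("c", 70_000, 70_300, "e1", "enhancer"),
        GenomicInterval("c", 90_000, 90_300, "e2", "enhancer"),
    ]


def _inter(rows):
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                       "chrom2", "start2", "end2", "strength"])


def test_classify_interactions_geometry(cfg):
    rows = [
        ("c", 9_000, 9_300, "c", 70_100, 70_200, 5),      # 1 kb to p1, inside e1
        ("c", 10_100, 10_200, "c", 40_100, 40_200, 5),    # both promoters
        ("c", 130_000, 130_300, "c", 70_100, 70_200, 5),  # first anchor 3 kb+ away
        ("c", 70_100, 70_200, "c", 90_100, 90_200, 5),    # two enhancers
    ]
    out = cn.classify_interactions(_inter(rows), _elements(), cfg)
    assert [c.cls for c in out] == ["enhancer-promoter", "promoter-promoter",
                                    "unassigned", "enhancer-enhancer"]
    assert out[0].element1 == "p1" and out[0].element2 == "e1"


def test_anchor_prefers_closest_element(cfg):
    # anchor overlaps e1 exactly; a promoter 2 kb away must not steal it
    elements = [GenomicInterval("c", 70_000, 70_300, "e1", "enhancer"),
                GenomicInterval("c", 72_300, 72_600, "p1", "promoter")]
    out = cn.classify_interactions(
        _inter([("c", 70_000, 70_300, "c", 70_000, 70_300, 1)]), elements, cfg)
    assert out[0].element1 == "e1"


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact enumeration with rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    def pmf(x):
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
    p_obs = pmf(a)
    cutoff = p_obs + p_obs * Fraction(1, 10**7)
    total = sum(pmf(x) for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
                if pmf(x) <= cutoff)
    return float(min(total, Fraction(1)))


def test_contingency_fisher_closed_form(cfg):
    elements = _elements()
    # wire p1<->e1 ten times and p2<->e2 ten times
    rows = ([("c", 10_000, 10_300, "c", 70_000, 70_300, 1)] * 10
            + [("c", 40_000, 40_300, "c", 90_000, 90_300, 1)] * 10)
    classified = cn.classify_interactions(_inter(rows), elements, cfg)
    states = {"p1": "induced", "e1": "induced",
              "p2": "repressed", "e2": "repressed"}
    table, pvals = cn.promoter_enhancer_contingency(classified, elements, states)
    assert table.loc["induced", "induced"] == 10
    assert table.loc["repressed", "repressed"] == 10
    expected = 2 / comb(20, 10)
    assert pvals["induced_vs_noninduced"] == pytest.approx(expected, rel=1e-9)
    assert pvals["induced_vs_noninduced"] == pytest.approx(
        _fisher_oracle(10, 0, 0, 10), rel=1e-9)


def test_contingency_independence_p_one(cfg):
    elements = _elements()
    rows = []
    for p, e in (("p1", "e1"), ("p1", "e2"), ("p2", "e1"), ("p2", "e2")):
        pi = next(iv for iv in elements if iv.id == p)
        ei = next(iv for iv in elements if iv.id == e)
        rows += [(pi.chrom, pi.start, pi.end, ei.chrom, ei.start, ei.end, 1)] * 5
    classified = cn.classify_interactions(_inter(rows), elements, cfg)
    states = {"p1": "induced", "e1": "induced",
              "p2": "neutral", "e2": "neutral"}
    _, pvals = cn.promoter_enhancer_contingency(classified, elements, states)
    assert pvals["induced_vs_noninduced"] == pytest.approx(1.0)


def test_contingency_empty_errors(cfg):
    with pytest.raises(ValueError):
        cn.promoter_enhancer_contingency([], _elements(), {})


def test_generator_wiring_enriches_induced_pairs(cfg):
    """Induced promoters preferentially wired to induced enhancers give a
    significant induced-vs-noninduced Fisher test."""
    from strainwise import elements as el
    from strainwise import pipeline as pl
    ds = sim.generate(sim.GeneratorParams(n_elements=300, n_genes=120, seed=9))
    annotated = el.annotate_context(ds.intervals, ds.tss, cfg.promoter_window_bp)
    classified = cn.classify_interactions(ds.interactions, annotated, cfg)
    states = {r["element_id"]: r[f"state_{sim.STRAIN_A}"]
              for _, r in pl.element_state_table(ds.signals, cfg).iterrows()}
    table, pvals = cn.promoter_enhancer_contingency(classified, annotated, states)
    n = table.to_numpy().sum()
    expected = table.sum(axis=1)["induced"] * table.sum(axis=0)["induced"] / n
    assert table.loc["induced", "induced"] > expected
    assert pvals["induced_vs_noninduced"] < 0.01


# --------------------------------------------------------------------------
# connected correlations


def test_connected_correlation_trivial_vectors(cfg):
    sig_rows = []
    ivs = []
    vals = {"a": [10, 20, 30, 40, 50], "b": [20, 40, 60, 80, 100],
            "c": [50, 40, 30, 20, 10]}
    for j, (eid, v) in enumerate(vals.items()):
        ivs.append(GenomicInterval("c", j * 10_000, j * 10_000 + 300, eid,
                                   "enhancer"))
        for s, x in zip("pqrst", v):
            sig_rows.append((eid, s, "stimulated", "H3K27ac", x))
    mat = pd.DataFrame(sig_rows, columns=["element_id", "strain", "condition",
                                          "assay", "value"]) \
        .pivot_table(index="element_id", columns="strain", values="value")
    r = cn._pair_correlations([("a", "b"), ("a", "c")], mat)
    assert r[0] == pytest.approx(1.0)
    assert r[1] == pytest.approx(-1.0)


def test_connected_correlation_needs_three_strains(cfg):
    signals = pd.DataFrame({
        "element_id": ["a", "a", "b", "b"],
        "strain": ["s1", "s2", "s1", "s2"],
        "condition": "stimulated", "assay": "H3K27ac",
        "value": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="3 strains"):
        cn.connected_correlation_comparison([], signals, [], cfg)


def test_connected_pairs_correlate_more_than_nulls(cfg):
    signals, interactions, intervals = sim.simulate_connected_signal_panel(
        n_connected=60, n_unconnected=60, n_strains=5, seed=4)
    classified = cn.classify_interactions(
        interactions, [iv.with_kind("enhancer") for iv in intervals], cfg)
    out = cn.connected_correlation_comparison(
        classified, signals, intervals, cfg.replace(corr_pair_fc=1.5), seed=4)
    assert np.median(out["r_connected"]) > np.median(out["r_random"])
    assert out["p_vs_random"] < 0.01
    assert out["d_vs_random"] > 0


def test_cohens_d_known_value():
    a = np.array([2.0, 4.0, 6.0])
    b = np.array([1.0, 3.0, 5.0])
    assert cn.cohens_d(a, b) == pytest.approx(0.5)


# --------------------------------------------------------------------------
# attribution


def _flag_df(positions, flags):
    return pd.DataFrame({"chrom": "c", "pos": positions,
                         "ref_allele": "A", "alt_allele": "T", "strain": "b",
                         "predicted_functional": flags})


def test_attribution_rules(cfg):
    elements = [GenomicInterval("c", 0, 300, "e1", "enhancer"),
                GenomicInterval("c", 50_000, 50_300, "e2", "enhancer"),
                GenomicInterval("c", 90_000, 90_300, "e3", "enhancer")]
    classified = cn.classify_interactions(
        _inter([("c", 0, 300, "c", 50_000, 50_300, 1)]), elements, cfg)
    # e1 connected to e2; e3 isolated
    flags = _flag_df([50_150, 90_150], [True, False])
    out = cn.attribute_differential_enhancers(["e1", "e2", "e3"], flags,
                                              classified, elements, cfg) \
        .set_index("element_id")["attribution"]
    assert out["e1"] == "connected_only"   # no local flag, partner flagged
    assert out["e2"] == "local_only"
    assert out["e3"] == "neither"          # unflagged local variant only
    assert set(out) <= set(cn.ATTRIBUTIONS)


def test_attribution_both_ends(cfg):
    elements = [GenomicInterval("c", 0, 300, "e1", "enhancer"),
                GenomicInterval("c", 50_000, 50_300, "e2", "enhancer")]
    classified = cn.classify_interactions(
        _inter([("c", 0, 300, "c", 50_000, 50_300, 1)]), elements, cfg)
    flags = _flag_df([150, 50_150], [True, True])
    out = cn.attribute_differential_enhancers(["e1"], flags, classified,
                                              elements, cfg)
    assert out.loc[0, "attribution"] == "both_ends"
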