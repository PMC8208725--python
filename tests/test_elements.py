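import numpy as np
import pandas as pd
import pytest

from strainwise import elements as el
from strainwise.io import GenomicInterval


def _signals(rows):
    return pd.DataFrame(rows, columns=["element_id", "strain", "condition",
                                       "assay", "value"])


def _quad(k_b, k_s, p_b, p_s, eid="e1", strain="s"):
    return [(eid, strain, "basal", "H3K27ac", k_b),
            (eid, strain, "stimulated", "H3K27ac", k_s),
            (eid, strain, "basal", "PolII", p_b),
            (eid, strain, "stimulated", "PolII", p_s)]


@pytest.mark.parametrize("quad,expected", [
    ((20, 60, 10, 30), "induced"),        # both markers rise 3-fold
    ((10, 10, 20, 20), "below_minimum"),  # H3K27ac never reaches 16 tags
    ((20, 26, 10, 13), "neutral"),        # both below the 1.4-fold band
    ((20, 60, 20, 30), "ambiguous"),      # discordant markers
    ((60, 20, 30, 10), "repressed"),      # both fall 3-fold
])
def test_classify_states(cfg, quad, expected):
    calls = el.classify_elements(_signals(_quad(*quad)), "s", cfg)
    assert len(calls) == 1
    assert calls[0].state == expected


def test_classify_missing_condition_names_element(cfg):
    rows = _quad(20, 60, 10, 30)[:3]  # PolII stimulated missing
    with pytest.raises(ValueError, match="e1"):
        el.classify_elements(_signals(rows), "s", cfg)


def _oracle_state(k_b, k_s, p_b, p_s, cfg):
    """Literal restatement of the element-calling rules, written separately
    from the vectorized implementation."""
    if max(k_b, k_s) < cfg.min_h3k27ac or max(p_b, p_s) < cfg.min_polii:
        return "below_minimum"
    fc_k = (k_s + 1) / (k_b + 1)
    fc_p = (p_s + 1) / (p_b + 1)
    if fc_k >= cfg.induce_fc and fc_p >= cfg.induce_fc:
        return "induced"
    if fc_k <= 1 / cfg.induce_fc and fc_p <= 1 / cfg.induce_fc:
        return "repressed"
    if (1 / cfg.neutral_fc < fc_k < cfg.neutral_fc
            and 1 / cfg.neutral_fc < fc_p < cfg.neutral_fc):
        return "neutral"
    return "ambiguous"


def test_classify_matches_oracle_on_random_quadruples(cfg, rng):
    n = 2000
    vals = rng.gamma(1.5, 25, size=(n, 4))
    rows = []
    for i, (kb, ks, pb, ps) in enumerate(vals):
        rows += _quad(kb, ks, pb, ps, eid=f"e{i:05d}")
    calls = {c.element_id: c.state
             for c in el.classify_elements(_signals(rows), "s", cfg)}
    for i, (kb, ks, pb, ps) in enumerate(vals):
        assert calls[f"e{i:05d}"] == _oracle_state(kb, ks, pb, ps, cfg)


def test_state_partition_exhaustive(cfg, rng):
    vals = rng.gamma(1.0, 30, size=(500, 4))
    rows = []
    for i, v in enumerate(vals):
        rows += _quad(*v, eid=f"e{i}")
    calls = el.classify_elements(_signals(rows), "s", cfg)
    assert len(calls) == 500
    assert all(c.state in el.STATES for c in calls)


# --------------------------------------------------------------------------
# promoter/enhancer annotation


def test_annotate_context_boundaries():
    ivs = [GenomicInterval("c", 950, 1250, "near"),     # center 1100
           GenomicInterval("c", 50_000, 50_300, "far"),
           GenomicInterval("c", 1900, 2300, "edge")]    # center 2100, d=1000
    out = el.annotate_context(ivs, [("c", 1100 - 200), ("c", 1100)],
                              promoter_window_bp=1000)
    kinds = {iv.id: iv.kind for iv in out}
    assert kinds["near"] == "promoter"
    assert kinds["far"] == "enhancer"
    assert kinds["edge"] == "promoter"  # inclusive boundary


# --------------------------------------------------------------------------
# super enhancers


def _se_signals(values, condition="stimulated"):
    rows = [(f"e{i}", "s", condition, "H3K27ac", v) for i, v in enumerate(values)]
    return _signals(rows)


def test_super_enhancers_tangent_cutoff(cfg, rng):
    values = np.concatenate([1 + rng.normal(0, 0.05, 95),
                             100 + rng.normal(0, 1, 5)])
    ivs = [GenomicInterval("c", i * 30_000, i * 30_000 + 300, f"e{i}")
           for i in range(100)]
    calls = el.call_super_enhancers(ivs, _se_signals(values), [], cfg)
    supers = {m for c in calls if c.is_super for m in c.member_ids}
    assert supers == {f"e{i}" for i in range(95, 100)}
    # strongest region has rank 1
    top = min(calls, key=lambda c: c.rank)
    assert top.is_super


def test_super_enhancers_all_equal_degenerate(cfg):
    ivs = [GenomicInterval("c", i * 30_000, i * 30_000 + 300, f"e{i}")
           for i in range(10)]
    calls = el.call_super_enhancers(ivs, _se_signals([5.0] * 10), [], cfg)
    assert not any(c.is_super for c in calls)


def test_super_enhancers_stitching_and_minimum(cfg):
    # two enhancers 5 kb apart stitch into one region (5000 < 12500)
    ivs = [GenomicInterval("c", 0, 300, "a"),
           GenomicInterval("c", 5300, 5600, "b"),
           GenomicInterval("c", 100_000, 100_300, "c1"),
           GenomicInterval("c", 200_000, 200_300, "d")]
    calls = el.call_super_enhancers(ivs, _se_signals([1, 1, 1, 1]), [], cfg)
    assert len(calls) == 3
    stitched = max(calls, key=lambda c: len(c.member_ids))
    assert sorted(stitched.member_ids) == ["a", "b"]
    with pytest.raises(ValueError, match="3"):
        el.call_super_enhancers(ivs[:2], _se_signals([1, 1]), [], cfg)


def test_super_enhancers_tss_exclusion(cfg):
    ivs = [GenomicInterval("c", i * 30_000, i * 30_000 + 300, f"e{i}")
           for i in range(4)]
    # e0's signal is excluded by a TSS within 2500 bp of its center
    calls = el.call_super_enhancers(ivs, _se_signals([50, 5, 5, 5]),
                                    [("c", 100)], cfg)
    by_member = {c.member_ids[0]: c for c in calls}
    assert by_member["e0"].total_signal == 0.0


def test_super_enhancer_order_invariance(cfg, rng):
    values = rng.gamma(2, 10, 30)
    ivs = [GenomicInterval("c", i * 30_000, i * 30_000 + 300, f"e{i}")
           for i in range(30)]
    base = el.call_super_enhancers(ivs, _se_signals(values), [], cfg)
    perm = list(range(30))
    rng.shuffle(perm)
    shuffled = el.call_super_enhancers([ivs[i] for i in perm],
                                       _se_signals(values), [], cfg)
    key = lambda calls: sorted((c.start, c.is_super, c.rank) for c in calls)
    assert key(base) == key(shuffled)


# --------------------------------------------------------------------------
# response variance


def test_levene_null_and_alternative(rng):
    base = 2.0 ** rng.normal(0, 1, 400)
    stat, p = el.response_variance_test(base[:200], base[200:])
    assert p > 0.05
    wide = 2.0 ** rng.normal(0, 5, 200)
    narrow = 2.0 ** rng.normal(0, 1, 200)
    _, p2 = el.response_variance_test(wide, narrow)
    assert p2 < 1e-6
    _, p3 = el.response_variance_test(narrow, wide)
    assert p3 == pytest.approx(p2)


def test_levene_constant_groups_warn():
    with pytest.warns(UserWarning):
        stat, p = el.response_variance_test([2.0] * 5, [4.0] * 5)
    assert p == 1.0
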