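import numpy as np
import pandas as pd
import pytest

from strainwise import strains as st
from strainwise.io import GenomicInterval


# --------------------------------------------------------------------------
# induced-gene calling


def _expr(rows):
    return pd.DataFrame(rows, columns=["gene_id", "strain", "condition",
                                       "replicate", "tpm", "count", "q"])


def _gene_rows(gid, basal, stim, q):
    return [(gid, "s", "basal", 0, basal, int(basal * 10), q),
            (gid, "s", "stimulated", 0, stim, int(stim * 10), q)]


@pytest.mark.parametrize("basal,stim,q,induced", [
    (10, 50, 0.001, True),    # fc ~4.6, significant
    (10, 50, 0.2, False),     # q gate fails
    (10, 15, 0.001, False),   # fc 1.45 below the 2-fold gate
])
def test_call_induced_genes(cfg, basal, stim, q, induced):
    out = st.call_induced_genes(_expr(_gene_rows("g", basal, stim, q)), "s", cfg)
    assert bool(out.loc[0, "induced"]) is induced


def test_call_induced_missing_condition_errors(cfg):
    rows = _gene_rows("g", 10, 50, 0.01)[:1]
    with pytest.raises(ValueError, match="g"):
        st.call_induced_genes(_expr(rows), "s", cfg)


# --------------------------------------------------------------------------
# basal categories


@pytest.mark.parametrize("basal_ind,basal_non,expected", [
    (10, 20, "high_basal"),   # noninduced 1.9-fold higher
    (10, 10, "equal_basal"),
    (15, 9, "low_basal"),     # (15+1)/(9+1) = 1.6 >= 1.5
])
def test_categorize_gene(cfg, basal_ind, basal_non, expected):
    assert st.categorize_gene(basal_ind, basal_non, cfg) == expected


@pytest.mark.parametrize("basal_ind,basal_non,expected", [
    (15, 40, "high_basal"),
    (18, 20, "equal_basal"),
    (30, 8, "low_basal"),
])
def test_categorize_enhancer(cfg, basal_ind, basal_non, expected):
    out = st.categorize_enhancer(basal_ind, basal_non,
                                 fc_induced_strain=4.0,
                                 fc_noninduced_strain=1.0, cfg=cfg)
    assert out == expected


def test_categorize_enhancer_requires_differential_induction(cfg):
    # induction fold changes differing less than 2-fold -> ineligible
    assert st.categorize_enhancer(10, 40, 3.0, 2.0, cfg) is None


def test_category_partition_on_ratio_grid(cfg):
    """Every basal-ratio combination yields exactly one category."""
    for b_ind in np.linspace(0, 100, 26):
        for b_non in np.linspace(0, 100, 26):
            cat = st.categorize_gene(b_ind, b_non, cfg)
            assert cat in st.CATEGORIES


# --------------------------------------------------------------------------
# tiers


def test_differential_tiers_examples(cfg):
    a = pd.Series({"e1": 11.0, "e2": 53.0, "e3": 14.0})
    b = pd.Series({"e1": 9.0, "e2": 11.0, "e3": 9.0})
    out = st.differential_tiers(a, b, cfg).set_index("element_id")
    assert bool(out.loc["e1", "similar"])          # ratio 1.2
    assert not bool(out.loc["e2", "similar"])      # ratio 4.5
    assert all(out.loc["e2", [f"tier_gt_{t:g}" for t in (1.5, 2, 3, 4)]])
    # ratio exactly 1.5: neither similar nor in the >1.5 tier
    assert out.loc["e3", "ratio"] == pytest.approx(1.5)
    assert not bool(out.loc["e3", "similar"])
    assert not bool(out.loc["e3", "tier_gt_1.5"])


def test_tiers_are_nested(cfg, rng):
    a = pd.Series(rng.gamma(2, 20, 200), index=[f"e{i}" for i in range(200)])
    b = pd.Series(rng.gamma(2, 20, 200), index=a.index)
    out = st.differential_tiers(a, b, cfg)
    assert (out["tier_gt_4"] <= out["tier_gt_3"]).all()
    assert (out["tier_gt_3"] <= out["tier_gt_2"]).all()
    assert (out["tier_gt_2"] <= out["tier_gt_1.5"]).all()


# --------------------------------------------------------------------------
# variant overlap


def _variants(positions, chrom="chrS"):
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "ref_allele": "A", "alt_allele": "T", "strain": "b"})


def test_variant_overlap_window_geometry(cfg):
    iv = GenomicInterval("chrS", 1000, 1200, "e")  # center 1100
    inside = st.variant_overlap_fraction({"g": [iv]}, _variants([1095]), cfg)
    outside = st.variant_overlap_fraction({"g": [iv]}, _variants([1251]), cfg)
    boundary = st.variant_overlap_fraction({"g": [iv]}, _variants([1250]), cfg)
    assert inside["g"] == 1.0
    assert outside["g"] == 0.0
    assert boundary["g"] == 1.0  # window inclusive of both ends


def test_variant_overlap_fraction_arithmetic(cfg):
    ivs = [GenomicInterval("chrS", i * 10_000, i * 10_000 + 200, f"e{i}")
           for i in range(4)]
    variants = _variants([c.center for c in ivs[:3]])
    out = st.variant_overlap_fraction({"g": ivs, "empty": []}, variants, cfg)
    assert out["g"] == 0.75
    assert out["empty"] is None


def test_variant_overlap_monotone_in_window(cfg):
    rng = np.random.default_rng(1)
    ivs = [GenomicInterval("chrS", i * 10_000, i * 10_000 + 200, f"e{i}")
           for i in range(50)]
    variants = _variants(sorted(rng.integers(0, 500_000, 200)))
    prev = -1.0
    for window in (10, 50, 150, 400, 1000):
        frac = st.variant_overlap_fraction(
            {"g": ivs}, variants, cfg.replace(variant_window_bp=window))["g"]
        assert frac >= prev
        prev = frac


# --------------------------------------------------------------------------
# cis / trans


@pytest.mark.parametrize("parental,f1,expected", [
    (8.0, 6.0, "cis"),            # |3 - 2.58| < 1
    (8.0, 1.0, "trans"),          # attenuated, parental above the 2-fold gate
    (1.5, 0.5, "unclassified"),   # parental below the gate
    (0.125, 1.0, "trans"),        # repressed direction, symmetric rule
])
def test_cis_trans_classify(cfg, parental, f1, expected):
    assert st.cis_trans_classify(parental, f1, cfg) == expected


def test_cis_trans_rejects_nonpositive(cfg):
    with pytest.raises(ValueError):
        st.cis_trans_classify(0.0, 1.0, cfg)


# --------------------------------------------------------------------------
# F1 allelic assignment


def test_assign_f1_counts():
    a, b, filtered = st.assign_f1_allelic_counts(100, 15, 5)
    assert (a, b, filtered) == (75.0, 25.0, False)
    a, b, filtered = st.assign_f1_allelic_counts(100, 10, 0)
    assert filtered and np.isnan(a)
    a, b, _ = st.assign_f1_allelic_counts(100, 7, 7)
    assert a == b == 50.0
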