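import numpy as np
import pandas as pd
import pytest

from strainwise import seqmodel as sm
from strainwise import simulate as sim
from strainwise.config import PipelineConfig
from strainwise.io import GenomicInterval
from strainwise.motifs import revcomp


@pytest.fixture(scope="module")
def small_cfg():
    """Tiny network for mechanics tests (not for accuracy)."""
    return PipelineConfig(seq_len_bp=60, conv_widths=[6, 3, 3],
                          pool_widths=[2, 1, 999], conv_channels=[6, 6, 6],
                          fc_units=8, max_epochs=4)


@pytest.fixture(scope="module")
def small_net(small_cfg):
    return sm.ConvNet(small_cfg, np.random.default_rng(0))


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# --------------------------------------------------------------------------
# encoding and auROC


def test_one_hot_ambiguous_zero_columns():
    x = sm.one_hot("ACGTN")
    assert x.shape == (4, 5)
    assert np.array_equal(x.sum(axis=0), [1, 1, 1, 1, 0])
    assert x[1, 1] == 1  # C at position 1


def test_auroc_known_value():
    scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
    labels = np.array([1, 1, 0, 1, 0])
    # rank-sum identity: pairs won = 5 of 6
    assert sm.auroc(scores, labels) == pytest.approx(5 / 6)


# --------------------------------------------------------------------------
# gradients


def test_parameter_and_input_gradients_numerically(small_cfg):
    net = sm.ConvNet(small_cfg, np.random.default_rng(1))
    rng = np.random.default_rng(2)
    x = rng.random((3, 4, 60)).astype(np.float32)
    y = np.array([1.0, 0.0, 1.0])
    z = net.forward(x)
    _, dz = sm._bce_with_logits(z, y)
    gin = net.backward(dz)
    eps = 1e-3

    def loss():
        return sm._bce_with_logits(net.forward(x), y)[0]

    w = net.convs[0].w
    idx = (1, 2, 3)
    ana = net.convs[0].dw[idx]
    orig = w[idx]
    w[idx] = orig + eps
    lp = loss()
    w[idx] = orig - eps
    lm = loss()
    w[idx] = orig
    assert ana == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)

    xi = (0, 1, 30)
    orig = x[xi]
    x[xi] = orig + eps
    lp = loss()
    x[xi] = orig - eps
    lm = loss()
    x[xi] = orig
    assert gin[xi] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


# --------------------------------------------------------------------------
# GC-matched backgrounds


def test_gc_backgrounds_satisfy_contract(cfg):
    rng = np.random.default_rng(3)
    genome = {"chrS": _random_seq(rng, 400_000)}
    ivs = [GenomicInterval("chrS", 50_000 + i * 20_000,
                           50_300 + i * 20_000, f"e{i}") for i in range(10)]
    bgs = sm.sample_gc_matched_background(genome, ivs, cfg, seed=5)
    fg_spans = [(iv.start, iv.end) for iv in ivs]
    for fg, bg in zip(ivs, bgs):
        assert bg.end - bg.start == fg.end - fg.start
        gc_fg = sm.gc_fraction(genome["chrS"][fg.start:fg.end])
        gc_bg = sm.gc_fraction(genome["chrS"][bg.start:bg.end])
        assert abs(gc_fg - gc_bg) <= cfg.gc_tol
        assert abs(bg.center - fg.center) <= cfg.bg_search_bp
        assert all(bg.end <= s or bg.start >= e for s, e in fg_spans)
    again = sm.sample_gc_matched_background(genome, ivs, cfg, seed=5)
    assert [(b.start, b.end) for b in bgs] == [(b.start, b.end) for b in again]


# --------------------------------------------------------------------------
# functional positions


def test_functional_positions_count_and_ties(cfg):
    track = sm.ImportanceTrack("e", "c", 0, np.zeros(300))
    top = sm.predicted_functional_positions(track, cfg)
    assert len(top) == 60
    assert np.array_equal(top, np.arange(60))  # leftmost tie break


def test_functional_positions_sort_oracle(cfg, rng):
    for _ in range(50):
        scores = rng.random(300)
        top = set(sm.predicted_functional_positions(scores, cfg))
        oracle = set(np.argsort(-scores, kind="stable")[:60])
        assert top == oracle


# --------------------------------------------------------------------------
# importance tracks


def test_reverse_complement_symmetry(small_cfg, small_net, rng):
    for _ in range(5):
        seq = _random_seq(rng, 60)
        fwd = sm.importance_scores(small_net, seq)
        rc = sm.importance_scores(small_net, revcomp(seq))
        assert np.array_equal(fwd.scores, rc.scores[::-1])


def test_wrong_length_rejected(small_net):
    with pytest.raises(ValueError, match="length"):
        sm.importance_scores(small_net, "ACGT")


def test_homopolymer_on_zeroed_model_gives_zero(small_cfg):
    net = sm.ConvNet(small_cfg, np.random.default_rng(0))
    for layer in net.convs + [net.fc1, net.fc2]:
        layer.w = np.zeros_like(layer.w)
        layer.b = np.zeros_like(layer.b)
    track = sm.importance_scores(net, "A" * 60)
    assert np.allclose(track.scores, 0.0)


# --------------------------------------------------------------------------
# variant prioritization


def _track_with_top(eid, start, top_positions, cfg):
    scores = np.zeros(300)
    scores[list(top_positions)] = np.linspace(2, 1, len(top_positions))
    tr = sm.ImportanceTrack(eid, "chrS", start, scores)
    tr.top_positions = sm.predicted_functional_positions(tr, cfg)
    return tr


def test_prioritize_variants_rules(cfg):
    # top positions: 0..59 by construction (scores zero elsewhere -> leftmost
    # ties fill the remainder, so craft explicit distinct scores)
    scores = np.concatenate([np.linspace(3, 2, 60), np.linspace(1, 0.5, 240)])
    tr = sm.ImportanceTrack("e", "chrS", 1000, scores)
    tr.top_positions = sm.predicted_functional_positions(tr, cfg)
    elements = [GenomicInterval("chrS", 1000, 1300, "e")]
    variants = pd.DataFrame({
        "chrom": ["chrS"] * 4,
        "pos": [1000, 1060, 1058, 5000],      # rank-1, rank-61, deletion, outside
        "ref_allele": ["A", "A", "AAAA", "A"],
        "alt_allele": ["T", "T", "A", "T"],
        "strain": ["b"] * 4,
    })
    out, n_outside = sm.prioritize_variants(variants, {"e": tr}, elements, cfg)
    flags = out["predicted_functional"].tolist()
    assert flags[0] is True or flags[0] == True      # top-ranked position
    assert not flags[1]                              # rank 61
    assert flags[2]                                  # deletion spans ranks 59-61
    assert not flags[3] and n_outside == 1


# --------------------------------------------------------------------------
# enrichment and k-mers


def test_category_enrichment_arithmetic():
    groups = {"half": ["a", "b"], "same": ["a", "b", "c", "d"]}
    flagged = {"a"}
    out = sm.category_enrichment(groups, flagged, ["a", "b", "c", "d"])
    assert out["half"] == pytest.approx(1.0)   # 50% vs global 25%
    assert out["same"] == pytest.approx(0.0)
    assert sm.category_enrichment({"g": []}, flagged, ["a"])["g"] is None


def test_kmer_null_odds_ratios(cfg, rng):
    tracks, seqs = [], {}
    for i in range(120):
        eid = f"e{i}"
        seqs[eid] = _random_seq(rng, 300)
        tr = sm.ImportanceTrack(eid, "c", 0, rng.random(300))
        tracks.append(tr)
    out = sm.kmer_interpretation(tracks, seqs, cfg)
    assert len(out) == 1024
    # random scores: no k-mer survives a Bonferroni-corrected Fisher test
    assert (out["p"] < 0.05 / len(out)).sum() == 0
    assert out["odds_ratio"].median() == pytest.approx(1.0, abs=0.35)


def test_kmer_planted_motif_enriched(cfg, rng):
    tracks, seqs = [], {}
    core = "TTCGA"
    for i in range(120):
        eid = f"e{i}"
        s = list(_random_seq(rng, 300))
        off = int(rng.integers(0, 290))
        s[off:off + 5] = core
        seqs[eid] = "".join(s)
        scores = rng.random(300) * 0.2
        scores[off:off + 5] = 3.0          # model importance at the motif
        tracks.append(sm.ImportanceTrack(eid, "c", 0, scores))
    out = sm.kmer_interpretation(tracks, seqs, cfg).set_index("kmer")
    assert out.loc[core, "odds_ratio"] > 1
    assert out.loc[core, "p"] < 1e-4


def test_kmer_size_guard(cfg):
    with pytest.raises(ValueError):
        sm.kmer_interpretation([], {}, cfg.replace(kmer_k=400))


# --------------------------------------------------------------------------
# training mechanics (small scale)


def test_training_guards(cfg):
    with pytest.raises(ValueError, match="200"):
        sm.train_classifier(["A" * 300] * 10, ["C" * 300] * 10,
                            np.arange(10), np.arange(10), cfg, 0)
    with pytest.raises(ValueError, match="imbalance"):
        sm.train_classifier(["A" * 300] * 3000, ["C" * 300] * 250,
                            np.arange(3000), np.arange(250), cfg, 0)


def test_combine_tracks_weighting(cfg):
    t1 = {"e": sm.ImportanceTrack("e", "c", 0, np.ones(300))}
    t2 = {"e": sm.ImportanceTrack("e", "c", 0, np.zeros(300))}
    ens = sm.combine_tracks([t1, t2], cfg, weights=[1.0, 0.0])
    assert np.allclose(ens["e"].scores, 1.0)
    with pytest.raises(ValueError):
        sm.combine_tracks([t1, t2], cfg, weights=[0.0, 0.0])


def test_coordinate_thirds_split():
    coords = np.array([0, 100, 200, 300, 400, 500, 599])
    split = sm.coordinate_thirds_split(coords, span=600)
    assert np.array_equal(split, [0, 0, 1, 1, 2, 2, 2])
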