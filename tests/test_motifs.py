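import itertools

import numpy as np
import pandas as pd
import pytest

from strainwise import motifs as mo
from strainwise import simulate as sim
from strainwise.config import load_config
from strainwise.io import PWM


@pytest.fixture(scope="module")
def stat6():
    return sim.consensus_pwm("STAT6_like", "TTTCCCAGGAAG")


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# --------------------------------------------------------------------------
# scanning


def test_consensus_scores_maximum(stat6):
    seq = "AC" + stat6.consensus + "GT"
    max_score = float(np.log2(stat6.matrix.max(axis=1) / 0.25).sum())
    assert mo.best_motif_score(seq, stat6) == pytest.approx(max_score)


def test_uniform_pwm_scores_zero(rng):
    uniform = PWM("u", np.full((6, 4), 0.25))
    assert mo.best_motif_score(_random_seq(rng, 50), uniform) == pytest.approx(0.0)


def test_scan_matches_brute_force(stat6, rng):
    """Vectorized scan equals an exhaustive two-strand window enumeration."""
    lo = np.log2(stat6.matrix / 0.25)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def brute(seq):
        best = -np.inf
        for s in (seq, mo.revcomp(seq)):
            for off in range(len(s) - len(stat6) + 1):
                best = max(best, sum(lo[i, idx[s[off + i]]]
                                     for i in range(len(stat6))))
        return best

    for _ in range(20):
        seq = _random_seq(rng, 50)
        assert mo.best_motif_score(seq, stat6) == pytest.approx(brute(seq))


def test_short_sequence_returns_floor(stat6):
    assert mo.best_motif_score("ACGT", stat6) == pytest.approx(
        mo.score_floor(stat6))


def test_reverse_complement_invariance(stat6, rng):
    seq = _random_seq(rng, 80)
    assert mo.best_motif_score(seq, stat6) == pytest.approx(
        mo.best_motif_score(mo.revcomp(seq), stat6))


# --------------------------------------------------------------------------
# association test


def _pairs_from(seqs_pos, seqs_neg):
    return [mo.SequencePair(f"p{i}", a, b)
            for i, (a, b) in enumerate(zip(seqs_pos, seqs_neg))]


def test_identical_pairs_give_zero(stat6, rng):
    seqs = [_random_seq(rng, 100) for _ in range(12)]
    res = mo.motif_mutation_test(_pairs_from(seqs, seqs), stat6)
    assert res.signed_logp == 0.0
    assert res.n_nonzero == 0


def test_planted_mutations_strongly_positive(stat6, rng):
    pos, neg = [], []
    cons = stat6.consensus
    mut = cons[:5] + "A" + cons[6:] if cons[5] != "A" else cons[:5] + "T" + cons[6:]
    for _ in range(50):
        background = _random_seq(rng, 100)
        off = int(rng.integers(0, 88))
        pos.append(background[:off] + cons + background[off + 12:])
        neg.append(background[:off] + mut + background[off + 12:])
    res = mo.motif_mutation_test(_pairs_from(pos, neg), stat6)
    assert res.signed_logp > 5
    flipped = mo.motif_mutation_test(_pairs_from(neg, pos), stat6)
    assert flipped.signed_logp == pytest.approx(-res.signed_logp)


def test_too_few_pairs_rejected(stat6, rng):
    seqs = [_random_seq(rng, 50) for _ in range(5)]
    with pytest.raises(ValueError, match="10"):
        mo.motif_mutation_test(_pairs_from(seqs, seqs), stat6)


def test_exact_signed_rank_null_matches_enumeration(stat6, rng):
    """For n <= 10 nonzero diffs the p-value equals the exact enumeration of
    all 2^n sign assignments of the rank statistic."""
    diffs = rng.normal(0, 1, 8)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_obs = ranks[diffs > 0].sum()
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(diffs))]
    dist = np.array(dist)
    p_exact = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
    from scipy import stats
    p_scipy = float(stats.wilcoxon(diffs, method="exact").pvalue)
    assert p_scipy == pytest.approx(p_exact, abs=1e-12)


# --------------------------------------------------------------------------
# clustering and expression filter


def _result(name, diffs, logp):
    return mo.MotifResult(name, np.asarray(diffs, float), logp,
                          10.0 ** -abs(logp), int(np.sum(np.asarray(diffs) != 0)))


def test_identical_motifs_cluster_and_mean(cfg):
    d = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
    clusters = mo.cluster_motifs([_result("m1", d, 6.0), _result("m2", d, 4.0)],
                                 cfg)
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == ["m1", "m2"]
    assert clusters[0].mean_signed_logp == pytest.approx(5.0)
    assert clusters[0].representative == "m1"


def test_uncorrelated_motifs_stay_separate(cfg, rng):
    d1 = rng.normal(0, 1, 60)
    d2 = rng.normal(0, 1, 60)
    assert abs(np.corrcoef(d1, d2)[0, 1]) < 0.6
    clusters = mo.cluster_motifs([_result("m1", d1, 2.0), _result("m2", d2, 1.0)],
                                 cfg)
    assert len(clusters) == 2


def test_constant_diff_vector_forms_singleton(cfg):
    clusters = mo.cluster_motifs(
        [_result("flat", np.zeros(20), 0.0),
         _result("m", np.arange(20.0), 3.0)], cfg)
    assert len(clusters) == 2


def test_expression_filter_boundary(cfg):
    expr = pd.DataFrame({
        "gene_id": ["Stat6", "Egr2", "Zzz"],
        "strain": ["s"] * 3, "condition": ["basal"] * 3, "replicate": [0] * 3,
        "tpm": [5.0, 0.1, 2.0], "count": [50, 1, 20],
    })
    mapping = {"hi": "Stat6", "lo": "Egr2", "edge": "Zzz"}
    clusters = [mo.MotifCluster(["hi"], 4.0), mo.MotifCluster(["lo"], 3.0),
                mo.MotifCluster(["edge"], 2.0)]
    kept = mo.expression_filter(clusters, expr, mapping, cfg)
    names = {c.members[0] for c in kept}
    assert names == {"hi"}  # 0.1 fails, exactly 2.0 TPM fails ("larger than 2")


def test_expression_filter_warns_on_unmapped(cfg):
    expr = pd.DataFrame({"gene_id": ["g"], "strain": ["s"],
                         "condition": ["basal"], "replicate": [0],
                         "tpm": [9.0], "count": [90]})
    with pytest.warns(UserWarning, match="mystery"):
        kept = mo.expression_filter([mo.MotifCluster(["mystery"], 1.0)],
                                    expr, {}, cfg)
    assert kept == []
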