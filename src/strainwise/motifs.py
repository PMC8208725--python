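"""PWM scanning and the motif-mutation association statistic.

For each homologous sequence pair (responsive strain = positive, unresponsive
strain = negative) and each motif, the best log-odds score difference
(positive - negative) is computed; pairs with a zero difference carry no
information about that motif and are dropped; the remaining differences are
tested against a zero median with the Wilcoxon signed-rank test.  The summary
statistic is sign(median difference) x -log10(p): a positive value means the
motif tends to be *better* in the responsive strain, i.e. motif mutations in
the unresponsive strain track loss of activity.

Motifs whose score-difference vectors are strongly correlated (Pearson r above
``motif_cluster_corr``, single linkage) are grouped into clusters, and clusters
without any member whose TF gene is expressed above ``expr_filter_tpm`` TPM
are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from strainwise.config import PipelineConfig
from strainwise.io import PWM

__all__ = [
    "SequencePair", "MotifResult", "MotifCluster",
    "best_motif_score", "motif_mutation_test", "cluster_motifs",
    "expression_filter", "encode_bases", "revcomp",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# pseudo-probability assigned to ambiguous (non-ACGT) bases during scoring
AMBIGUOUS_PROB = 1e-3


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, ambiguous=4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _logodds(pwm: PWM) -> np.ndarray:
    """(L, 5) log2(p/bg) matrix; column 4 holds the ambiguous-base penalty."""
    lo = np.log2(pwm.matrix / pwm.background)
    amb = np.log2(AMBIGUOUS_PROB / pwm.background.mean())
    return np.hstack([lo, np.full((lo.shape[0], 1), amb)])


def score_floor(pwm: PWM) -> float:
    """Minimum attainable two-strand score; returned for too-short sequences."""
    return float(_logodds(pwm).min(axis=1).sum())


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> float:
    m = lo.shape[0]
    n_off = len(codes) - m + 1
    scores = np.zeros(n_off)
    for i in range(m):
        scores += lo[i, codes[i:i + n_off]]
    return float(scores.max())


def best_motif_score(seq: str, pwm: PWM) -> float:
    """Maximum log2-odds score over all offsets and both strands.

    Sequences shorter than the motif score at the motif's floor (the minimum
    attainable score) rather than raising.
    """
    lo = _logodds(pwm)
    if len(seq) < len(pwm):
        return score_floor(pwm)
    fwd = encode_bases(seq)
    rc = encode_bases(revcomp(seq))
    return max(_scan_one_strand(fwd, lo), _scan_one_strand(rc, lo))


@dataclass(frozen=True)
class SequencePair:
    """Homologous element sequences: responsive (positive) vs unresponsive."""

    id: str
    positive_seq: str
    negative_seq: str

    def __post_init__(self):
        if not self.positive_seq or not self.negative_seq:
            raise ValueError(f"pair {self.id}: sequences must be non-empty")


@dataclass
class MotifResult:
    motif: str
    score_diffs: np.ndarray      # per pair, positive - negative best score
    signed_logp: float           # sign(median nonzero diff) x -log10 p
    p: float
    n_nonzero: int


@dataclass
class MotifCluster:
    members: list
    mean_signed_logp: float
    representative: str = ""

    def __post_init__(self):
        if not self.representative:
            self.representative = self.members[0]


_EXACT_N_MAX = 25  # exact signed-rank null below this many nonzero diffs


def motif_mutation_test(pairs: list[SequencePair], pwm: PWM,
                        zero_tol: float = 1e-9) -> MotifResult:
    """Test whether motif-score changes track the activity difference.

    Requires >= 10 pairs.  Exact Wilcoxon null for < 26 nonzero differences
    (no ties), normal approximation with continuity correction otherwise.
    """
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 sequence pairs, got {len(pairs)}")
    diffs = np.array([best_motif_score(p.positive_seq, pwm)
                      - best_motif_score(p.negative_seq, pwm) for p in pairs])
    nonzero = diffs[np.abs(diffs) > zero_tol]
    n = len(nonzero)
    if n == 0:
        return MotifResult(pwm.name, diffs, 0.0, 1.0, 0)
    has_ties = len(np.unique(np.abs(nonzero))) < n
    if n <= _EXACT_N_MAX and not has_ties:
        res = stats.wilcoxon(nonzero, method="exact")
    else:
        res = stats.wilcoxon(nonzero, method="approx", correction=True)
    p = float(res.pvalue)
    sign = float(np.sign(np.median(nonzero)))
    # p of exactly 0 cannot occur for the signed-rank test; guard regardless
    logp = -np.log10(max(p, np.finfo(float).tiny))
    return MotifResult(pwm.name, diffs, sign * logp, p, n)


def cluster_motifs(results: list[MotifResult],
                   cfg: PipelineConfig | None = None,
                   corr_threshold: float | None = None) -> list[MotifCluster]:
    """Group motifs by single-linkage on Pearson correlation of score-diff
    vectors at correlation > threshold; constant vectors form singletons."""
    if corr_threshold is None:
        corr_threshold = cfg.motif_cluster_corr if cfg else 0.6
    n = len(results)
    mat = np.vstack([r.score_diffs for r in results])
    stds = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)

    # union-find over edges with defined correlation above the threshold
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if stds[i] == 0 or stds[j] == 0:
                continue
            if np.isfinite(corr[i, j]) and corr[i, j] > corr_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        members = [results[i].motif for i in idxs]
        logps = [results[i].signed_logp for i in idxs]
        rep = members[int(np.argmax([abs(v) for v in logps]))]
        clusters.append(MotifCluster(members, float(np.mean(logps)), rep))
    clusters.sort(key=lambda c: -abs(c.mean_signed_logp))
    return clusters


def expression_filter(clusters: list[MotifCluster], expression: pd.DataFrame,
                      motif_to_gene: dict[str, str], cfg: PipelineConfig,
                      ) -> list[MotifCluster]:
    """Keep clusters with >= 1 member whose TF gene exceeds expr_filter_tpm TPM
    in any condition; unmapped motifs count as non-expressed."""
    import warnings

    max_tpm = expression.groupby("gene_id")["tpm"].max()
    kept = []
    for cluster in clusters:
        expressed = False
        for motif in cluster.members:
            gene = motif_to_gene.get(motif)
            if gene is None:
                warnings.warn(f"motif {motif!r} has no gene mapping; "
                              "treated as non-expressed")
                continue
            if max_tpm.get(gene, 0.0) > cfg.expr_filter_tpm:
                expressed = True
                break
        if expressed:
            kept.append(cluster)
    return kept
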