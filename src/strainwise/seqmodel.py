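"""Convolutional sequence classifier with per-nucleotide importance scores.

A compact 1-D convolutional network (three conv layers with ReLU + max
pooling, then two fully connected layers) classifies fixed-length (default
300 bp) sequences as active enhancer vs background.  The implementation is
pure numpy with analytic backpropagation, which makes training bit-for-bit
reproducible under a fixed seed and gives exact input gradients.

Importance scores attribute the positive-class logit to each input position
against a uniform-base reference: score contribution = gradient x (input -
0.25), computed for the sequence and its reverse complement; the reverse-
complement track is re-aligned and the final per-position score is the
absolute maximum of the two.  The top ``top_frac`` positions of each window
(60 of 300 at the default 20%) are the predicted functional positions, and
variants falling on them are flagged predicted-functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from strainwise.config import PipelineConfig
from strainwise.io import GenomicInterval
from strainwise.motifs import revcomp

__all__ = [
    "one_hot", "ImportanceTrack", "TrainedModel", "ConvNet",
    "sample_gc_matched_background", "train_classifier", "auroc",
    "importance_scores", "predicted_functional_positions",
    "prioritize_variants", "category_enrichment", "kmer_interpretation",
]

_DTYPE = np.float32


def one_hot(seq: str) -> np.ndarray:
    """(4, L) indicator matrix; ambiguous bases become all-zero columns."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros((4, len(seq)), dtype=_DTYPE)
    for i, base in enumerate("ACGT"):
        out[i, arr == ord(base)] = 1.0
    return out


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum identity (tie-aware)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auROC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# network layers


class _Conv1D:
    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * width))
        self.w = (rng.standard_normal((c_out, c_in, width)) * scale).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        k = self.w.shape[2]
        xs = sliding_window_view(x, k, axis=2)      # (B, C_in, T, K)
        return np.einsum("bctk,ock->bot", xs, self.w, optimize=True) \
            + self.b[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, (c_out, c_in, k) = self._x, self.w.shape
        xs = sliding_window_view(x, k, axis=2)
        self.dw = np.einsum("bot,bctk->ock", dout, xs, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        ps = sliding_window_view(pad, k, axis=2)    # (B, C_out, L, K)
        return np.einsum("bolk,ock->bcl", ps, self.w[:, :, ::-1], optimize=True)

    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool1D:
    def __init__(self, width: int):
        self.width = width

    def forward(self, x):
        b, c, t = x.shape
        t_trim = (t // self.width) * self.width
        xr = x[:, :, :t_trim].reshape(b, c, t // self.width, self.width)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        b, c, tp = dout.shape
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dxr = dx[:, :, :tp * self.width].reshape(b, c, tp, self.width)
        bi, ci, ti = np.ogrid[:b, :c, :tp]
        dxr[bi, ci, ti, self._argmax] = dout
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


class ConvNet:
    """Three conv + two fully connected layers, binary output logit."""

    def __init__(self, cfg: PipelineConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = [4] + list(cfg.conv_channels)
        self.convs, self.pools = [], []
        t = cfg.seq_len_bp
        for i in range(3):
            self.convs.append(_Conv1D(chans[i], chans[i + 1],
                                      cfg.conv_widths[i], rng))
            t_conv = t - cfg.conv_widths[i] + 1
            pool = min(cfg.pool_widths[i], t_conv)  # clamp: full-width = global
            self.pools.append(_MaxPool1D(pool))
            t = t_conv // pool
        self.relus = [_ReLU() for _ in range(4)]
        self.flat_dim = chans[-1] * t
        self.fc1 = _Dense(self.flat_dim, cfg.fc_units, rng)
        self.fc2 = _Dense(cfg.fc_units, 1, rng)

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(_DTYPE)
        for i in range(3):
            h = self.pools[i].forward(self.relus[i].forward(
                self.convs[i].forward(h)))
        self._pool_out_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relus[3].forward(self.fc1.forward(h))
        return self.fc2.forward(h)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        """Backprop d(loss)/d(logit); returns d(loss)/d(input)."""
        d = self.fc2.backward(dlogit[:, None])
        d = self.fc1.backward(self.relus[3].backward(d))
        d = d.reshape(self._pool_out_shape)
        for i in reversed(range(3)):
            d = self.convs[i].backward(
                self.relus[i].backward(self.pools[i].backward(d)))
        return d

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(logit)/d(input) for a batch, shape like x."""
        self.forward(x)
        return self.backward(np.ones(x.shape[0], dtype=_DTYPE))

    # -- parameters ----------------------------------------------------------

    def parameters(self) -> list:
        layers = self.convs + [self.fc1, self.fc2]
        return [(layer, name) for layer in layers for name in ("w", "b")]

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights):
            setattr(layer, name, w.copy())

    def save(self, path) -> None:
        arrays = {f"p{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        self.set_weights([data[f"p{i}"] for i in range(len(data.files))])


class _Adam:
    def __init__(self, model: ConvNet, lr: float):
        self.model, self.lr = model, lr
        self.t = 0
        self.m = [np.zeros_like(getattr(l, n)) for l, n in model.parameters()]
        self.v = [np.zeros_like(getattr(l, n)) for l, n in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = getattr(layer, "d" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p = getattr(layer, name)
            setattr(layer, name,
                    (p - self.lr * mh / (np.sqrt(vh) + eps)).astype(_DTYPE))


# --------------------------------------------------------------------------
# GC-matched backgrounds


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


def sample_gc_matched_background(genome: dict[str, str],
                                 intervals: list[GenomicInterval],
                                 cfg: PipelineConfig,
                                 seed: int) -> list[GenomicInterval]:
    """One background window per foreground: equal length, GC content within
    ``gc_tol``, center within ``bg_search_bp`` of the foreground, no overlap
    with any foreground.

    All candidate starts in the search range are enumerated (prefix-sum GC
    and coverage make this cheap), and one eligible window is drawn with the
    seeded generator — deterministic, and it fails only when no eligible
    window exists.  For GC-extreme foregrounds the range is widened once
    (x10) before raising."""
    rng = np.random.default_rng(seed)

    gc_prefix: dict[str, np.ndarray] = {}
    cov_prefix: dict[str, np.ndarray] = {}
    for chrom in {iv.chrom for iv in intervals}:
        arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        gc_prefix[chrom] = np.concatenate([[0], np.cumsum(is_gc)])
        cov = np.zeros(len(arr), dtype=np.int64)
        for iv in intervals:
            if iv.chrom == chrom:
                cov[iv.start:iv.end] = 1
        cov_prefix[chrom] = np.concatenate([[0], np.cumsum(cov)])

    out = []
    for iv in intervals:
        length = iv.end - iv.start
        gp, cp = gc_prefix[iv.chrom], cov_prefix[iv.chrom]
        chrom_len = len(gp) - 1
        target_gc = (gp[iv.end] - gp[iv.start]) / length
        chosen = None
        for search_bp in (cfg.bg_search_bp, cfg.bg_search_bp * 10):
            lo = max(0, iv.center - search_bp)
            hi = min(chrom_len - length, iv.center + search_bp)
            if hi <= lo:
                continue
            starts = np.arange(lo, hi)
            gc = (gp[starts + length] - gp[starts]) / length
            overlap = (cp[starts + length] - cp[starts]) > 0
            eligible = starts[(np.abs(gc - target_gc) <= cfg.gc_tol) & ~overlap]
            if len(eligible):
                chosen = int(eligible[rng.integers(len(eligible))])
                break
        if chosen is None:
            raise RuntimeError(f"no GC-matched background found for {iv.id} "
                               f"within widened search range")
        out.append(GenomicInterval(iv.chrom, chosen, chosen + length,
                                   f"bg_{iv.id}"))
    return out


# --------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    model: ConvNet
    log: pd.DataFrame                 # per-epoch train/val loss and lr
    val_auroc: float
    test_auroc: float
    architecture: str = ""
    n_train: int = 0

    def __post_init__(self):
        if not 0 <= self.test_auroc <= 1:
            raise ValueError("auROC must lie in [0, 1]")


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    # stable softplus: log(1 + e^z) = max(z, 0) + log1p(e^{-|z|})
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss.mean()), ((p - y) / len(z)).astype(_DTYPE)


def coordinate_thirds_split(coords: np.ndarray, span: float | None = None
                            ) -> np.ndarray:
    """Partition by genomic coordinate into thirds: 0=train, 1=val, 2=test.

    Mirrors leaving whole chromosomes out for validation and testing when
    only a single chromosome exists."""
    coords = np.asarray(coords, dtype=float)
    if span is None:
        span = coords.max() + 1
    out = np.zeros(len(coords), dtype=int)
    out[coords >= span / 3] = 1
    out[coords >= 2 * span / 3] = 2
    return out


def train_classifier(pos_seqs: list[str], neg_seqs: list[str],
                     pos_coords: np.ndarray, neg_coords: np.ndarray,
                     cfg: PipelineConfig, seed: int,
                     span: float | None = None,
                     labels: np.ndarray | None = None) -> TrainedModel:
    """Train the classifier with the stated protocol and report held-out auROC.

    Splits are by genomic coordinate (thirds of the chromosome: train /
    validation / test).  The learning rate starts at ``lr_init`` and is
    multiplied by ``lr_factor`` whenever validation loss has not improved for
    ``stagnation_epochs`` epochs; training stops after ``patience_epochs``
    epochs without improvement (or at ``max_epochs``).  ``labels`` overrides
    the class labels (for label-shuffle controls) but not the sequences.
    """
    if len(pos_seqs) < 200 or len(neg_seqs) < 200:
        raise ValueError("need >= 200 sequences per class")
    ratio = max(len(pos_seqs), len(neg_seqs)) / max(min(len(pos_seqs),
                                                        len(neg_seqs)), 1)
    if ratio > 10:
        raise ValueError(f"class imbalance {ratio:.1f}:1 exceeds 10:1; "
                         "resample the larger class")

    seqs = list(pos_seqs) + list(neg_seqs)
    y = np.concatenate([np.ones(len(pos_seqs)), np.zeros(len(neg_seqs))]) \
        if labels is None else np.asarray(labels, dtype=float)
    if len(y) != len(seqs):
        raise ValueError("labels length mismatch")
    coords = np.concatenate([np.asarray(pos_coords), np.asarray(neg_coords)])
    if len(coords) != len(seqs):
        raise ValueError("coordinates length mismatch")
    for s in seqs:
        if len(s) != cfg.seq_len_bp:
            raise ValueError(f"all sequences must have length {cfg.seq_len_bp}")

    x = np.stack([one_hot(s) for s in seqs])
    split = coordinate_thirds_split(coords, span)
    x_tr, y_tr = x[split == 0], y[split == 0]
    x_va, y_va = x[split == 1], y[split == 1]
    x_te, y_te = x[split == 2], y[split == 2]
    if min(len(x_tr), len(x_va), len(x_te)) == 0:
        raise ValueError("coordinate split produced an empty partition")

    rng = np.random.default_rng(seed)
    model = ConvNet(cfg, rng)
    opt = _Adam(model, cfg.lr_init)

    # stagnation and stopping monitor the training loss; the validation loss
    # selects the weights that are kept (and is reported in the log)
    best_val = np.inf
    best_train = np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0
    stagnant = 0
    rows = []
    n = len(x_tr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            z = model.forward(x_tr[idx])
            loss, dz = _bce_with_logits(z, y_tr[idx])
            model.backward(dz)
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= n
        val_loss, _ = _bce_with_logits(model.forward(x_va), y_va)
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_weights = model.get_weights()
        if train_loss < best_train - 1e-6:
            best_train = train_loss
            epochs_since_best = 0
            stagnant = 0
        else:
            epochs_since_best += 1
            stagnant += 1
            if stagnant >= cfg.stagnation_epochs:
                opt.lr *= cfg.lr_factor
                stagnant = 0
            if epochs_since_best > cfg.patience_epochs:
                break

    model.set_weights(best_weights)
    val_auc = auroc(model.forward(x_va), y_va > 0.5)
    test_auc = auroc(model.forward(x_te), y_te > 0.5)
    arch = (f"conv{cfg.conv_channels}x{cfg.conv_widths}"
            f"-pool{cfg.pool_widths}-fc[{cfg.fc_units},1]")
    return TrainedModel(model, pd.DataFrame(rows), float(val_auc),
                        float(test_auc), arch, n)


# --------------------------------------------------------------------------
# importance scores


@dataclass
class ImportanceTrack:
    element_id: str
    chrom: str
    start: int                     # genomic start of the scored window
    scores: np.ndarray             # per-position, >= 0
    top_positions: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if (self.scores < 0).any():
            raise ValueError("importance scores must be non-negative")


_IG_STEPS = 16


def _attribution(model: ConvNet, x: np.ndarray) -> np.ndarray:
    """Integrated-gradients attribution of the logit against a uniform-base
    reference (0.25 per channel), summed over bases per position.

    The path integral satisfies completeness (attributions sum to the logit
    difference from the reference) and, unlike a single gradient step,
    distributes credit across features even when max-pooling routes the
    instantaneous gradient through one argmax position per channel."""
    ref = np.full_like(x, 0.25)
    delta = x - ref
    alphas = (np.arange(_IG_STEPS, dtype=_DTYPE) + 0.5) / _IG_STEPS
    batch = ref[None] + alphas[:, None, None] * delta[None]
    grads = model.input_gradient(batch.astype(_DTYPE))
    avg_grad = grads.mean(axis=0)
    return (delta * avg_grad).sum(axis=0)


def importance_scores(model: ConvNet, seq: str, element_id: str = "",
                      chrom: str = "", start: int = 0,
                      cfg: PipelineConfig | None = None) -> ImportanceTrack:
    """Attribution track for one sequence, combined across strands.

    The reverse-complement track is reversed to align positions; the final
    score at each position is max(|forward|, |reverse-complement|)."""
    expected = model.cfg.seq_len_bp
    if len(seq) != expected:
        raise ValueError(f"sequence length {len(seq)} != model input {expected}")
    fwd = _attribution(model, one_hot(seq))
    rc = _attribution(model, one_hot(revcomp(seq)))[::-1]
    scores = np.maximum(np.abs(fwd), np.abs(rc))
    track = ImportanceTrack(element_id, chrom, start, scores)
    if cfg is not None:
        track.top_positions = predicted_functional_positions(track, cfg)
    return track


def combine_tracks(track_sets: list[dict[str, "ImportanceTrack"]],
                   cfg: PipelineConfig,
                   weights: list[float] | None = None
                   ) -> dict[str, "ImportanceTrack"]:
    """Average importance tracks over an ensemble of trained models.

    Independently initialized trainings of a redundant-feature task can each
    favor a different discriminative motif; averaging their tracks (each
    normalized by its model-wide mean score) yields importance that reflects
    every feature any member learned.  ``weights`` (e.g. each member's
    held-out accuracy above chance) down-weight members that learned little.
    Top positions are recomputed on the combined track."""
    if not track_sets:
        raise ValueError("need at least one track set")
    if weights is None:
        weights = [1.0] * len(track_sets)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    consts = [np.mean([t.scores.mean() for t in ts.values()]) or 1.0
              for ts in track_sets]
    out = {}
    for eid, first in track_sets[0].items():
        scores = sum(wk * ts[eid].scores / c
                     for wk, ts, c in zip(w, track_sets, consts))
        tr = ImportanceTrack(eid, first.chrom, first.start, scores)
        tr.top_positions = predicted_functional_positions(tr, cfg)
        out[eid] = tr
    return out


def predicted_functional_positions(track: ImportanceTrack | np.ndarray,
                                   cfg: PipelineConfig) -> np.ndarray:
    """Indices of the top round(top_frac x length) scores; ties at the cutoff
    break toward the leftmost position."""
    scores = track.scores if isinstance(track, ImportanceTrack) else np.asarray(track)
    k = int(round(cfg.top_frac * len(scores)))
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:k])


def prioritize_variants(variants: pd.DataFrame,
                        tracks: dict[str, ImportanceTrack],
                        elements: list[GenomicInterval],
                        cfg: PipelineConfig) -> tuple[pd.DataFrame, int]:
    """Flag variants that fall on a predicted functional position of any
    covering element window.  A multi-base (indel) variant is flagged when any
    overlapped position is a top position.  Returns (flagged table, number of
    variants outside every scored window)."""
    windows = []
    for iv in elements:
        track = tracks.get(iv.id)
        if track is None:
            continue
        top = track.top_positions
        if len(top) == 0:
            top = predicted_functional_positions(track, cfg)
        windows.append((track.chrom, track.start,
                        track.start + len(track.scores), set(int(t) for t in top)))

    flags = np.zeros(len(variants), dtype=bool)
    covered = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    ref_len = variants["ref_allele"].astype(str).str.len().to_numpy()
    chroms = variants["chrom"].to_numpy()
    for chrom, wstart, wend, top in windows:
        in_win = (chroms == chrom) & (pos < wend) & (pos + ref_len > wstart)
        for i in np.flatnonzero(in_win):
            covered[i] = True
            span = range(max(int(pos[i]), wstart) - wstart,
                         min(int(pos[i] + ref_len[i]), wend) - wstart)
            if any(p in top for p in span):
                flags[i] = True
    out = variants.copy()
    out["predicted_functional"] = flags
    return out, int((~covered).sum())


def category_enrichment(groups: dict[str, list[str]],
                        flagged_elements: set[str],
                        all_elements: list[str]) -> dict[str, float | None]:
    """log2( (% of group with a top-scoring variant) / (% of all elements) ).

    Returns None for a group when the global percentage is zero or the group
    percentage is zero (enrichment undefined on the log scale)."""
    global_pct = sum(1 for e in all_elements if e in flagged_elements) \
        / max(len(all_elements), 1)
    out: dict[str, float | None] = {}
    for name, members in groups.items():
        if not members or global_pct == 0:
            out[name] = None
            continue
        pct = sum(1 for e in members if e in flagged_elements) / len(members)
        out[name] = float(np.log2(pct / global_pct)) if pct > 0 else None
    return out


def kmer_interpretation(tracks: list[ImportanceTrack],
                        sequences: dict[str, str],
                        cfg: PipelineConfig) -> pd.DataFrame:
    """Odds ratio + Fisher p for each k-mer's enrichment among top-scoring
    k-mer occurrences.

    Every k-mer occurrence is scored by the mean importance over its span;
    occurrences in the global top ``kmer_top_frac`` are cross-tabulated per
    k-mer identity against the rest; the odds ratio uses a Haldane 0.5
    correction and the p-value is the two-sided Fisher exact test."""
    k = cfg.kmer_k
    if k > cfg.seq_len_bp:
        raise ValueError("k-mer size exceeds sequence length")
    if len(tracks) < 100:
        raise ValueError("need >= 100 scored sequences")
    kmers, occ_scores = [], []
    for track in tracks:
        seq = sequences[track.element_id]
        scores = track.scores
        window_means = np.convolve(scores, np.ones(k) / k, mode="valid")
        for off in range(len(seq) - k + 1):
            kmer = seq[off:off + k]
            if any(b not in "ACGT" for b in kmer):
                continue
            kmers.append(kmer)
            occ_scores.append(window_means[off])
    occ_scores = np.asarray(occ_scores)
    kmers = np.asarray(kmers)
    cutoff = np.quantile(occ_scores, 1.0 - cfg.kmer_top_frac)
    in_top = occ_scores > cutoff
    n_top, n_rest = int(in_top.sum()), int((~in_top).sum())

    rows = []
    for kmer in np.unique(kmers):
        mask = kmers == kmer
        a = int((mask & in_top).sum())
        b = int((mask & ~in_top).sum())
        c, d = n_top - a, n_rest - b
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"kmer": kmer, "n_top": a, "n_rest": b,
                     "odds_ratio": oddsr, "p": float(p)})
    return (pd.DataFrame(rows)
            .sort_values("odds_ratio", ascending=False)
            .reset_index(drop=True))
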