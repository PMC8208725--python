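"""Synthetic strain-pair datasets with known ground truth.

The generator emulates a pair of inbred-strain genomes ("strainA" responsive,
"strainB" carrying variants) and the epigenomic readouts of a cytokine
stimulation experiment.  Each regulatory element carries one planted
lineage-determining TF (LDTF) motif instance and one signal-dependent TF
(SDTF) motif instance; activity follows an occupancy model

    mean = base + b_a * occ_L + a_i * occ_L * occ_S * s(condition)

where occ_L / occ_S are logistic functions of the planted instances' log-odds
scores, s(stimulated) = 1 and s(basal) = relief(occ_L): basal SDTF engagement
is granted only to elements whose LDTF occupancy exceeds the standard planted
level (i.e. improved motifs), rendering them constitutively active.

The per-element mechanism determines how strainB's sequence differs:

* ``low_basal``   — LDTF core mutated in B: B loses basal occupancy, chromatin
                    accessibility, and all induction.
* ``equal_basal`` — SDTF core mutated in B: equal basal activity, induction
                    only in A.
* ``high_basal``  — LDTF motif improved to consensus in B: constitutively
                    high basal activity, no further induction.
* ``conserved``   — no motif-disrupting edit; induced in both strains.
* ``background``  — no planted motifs; quiescent (near-floor, neutral) in
                    both strains.

A small extra set of *linked* elements is sequence-identical between strains
yet differentially active (activity suppressed in B by an external factor);
each is wired by an interaction to a causal-variant-bearing equal-basal
element, providing ground truth for connectivity attribution.

Tag counts are drawn with negative-binomial overdispersion; dispersion 0
yields the exact means (the deterministic, noise-free limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from strainwise.config import PipelineConfig
from strainwise.io import (GenomicInterval, PWM, read_bed, read_bedpe,
                           read_fasta, read_signal_table, read_vcf_like,
                           write_bed, write_bedpe, write_fasta,
                           write_signal_table, write_vcf_like,
                           read_expression_table, write_expression_table,
                           _read_table, _write_table)

__all__ = [
    "GeneratorParams", "SyntheticDataset", "generate", "write_dataset",
    "read_dataset", "default_ldtf_pwms", "default_sdtf_pwms",
    "make_decoy_pwms", "consensus_pwm", "apply_variants", "liftover",
    "element_sequences", "simulate_connected_signal_panel",
]

CHROM = "chrS"
STRAIN_A = "strainA"
STRAIN_B = "strainB"
MECHANISMS = ("low_basal", "equal_basal", "high_basal", "conserved", "background")

# per-assay (baseline, basal-coefficient multiplier, induced-coefficient multiplier)
ASSAY_MODEL = {
    "H3K27ac": (4.0, 1.00, 1.000),
    "PolII":   (6.0, 0.833, 0.875),
    "ATAC":    (5.0, 1.10, 0.060),
    "TF_LDTF": (3.0, 1.40, 0.050),
    "TF_SDTF": (3.0, 0.00, 0.750),
}
_QUIET_LEVEL = 18.0   # background-element signal, just above the minimum-tag filter
_CORE_INFO = 0.95     # consensus probability at core motif positions
_FLANK_INFO = 0.9     # consensus probability at flanking positions
_CORE_OFFSETS = (4, 5, 6, 7)  # core positions of the packaged 12-bp matrices


def consensus_pwm(name: str, consensus: str,
                  core: tuple = _CORE_OFFSETS) -> PWM:
    """Consensus-like PWM: high-information core, moderate-information flanks."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus.upper()):
        info = _CORE_INFO if i in core else _FLANK_INFO
        mat[i, :] = (1.0 - info) / 3.0
        mat[i, idx[base]] = info
    return PWM(name, mat)


def default_ldtf_pwms() -> list[PWM]:
    """Packaged consensus-like matrices standing in for the PU.1 / C/EBP class."""
    return [consensus_pwm("PU1_like", "AAAGAGGAAGTG"),
            consensus_pwm("CEBP_like", "GATTGCGCAATC")]


def default_sdtf_pwms() -> list[PWM]:
    """Packaged consensus-like matrices standing in for the STAT6 / EGR class."""
    return [consensus_pwm("STAT6_like", "TTTCCCAGGAAG"),
            consensus_pwm("EGR_like", "AGCGTGGGCGGT")]


def make_decoy_pwms(n: int, length: int = 12, seed: int = 0,
                    avoid: list[str] | None = None,
                    max_matches: int = 5) -> list[PWM]:
    """Random consensus-like PWMs with the same information profile, used as
    null motifs in association tests.

    ``avoid`` lists sequences (e.g. planted motif instances) the decoys must
    not resemble: candidates sharing more than ``max_matches`` aligned bases
    with any avoided sequence (any shift, either strand) are rejected, so the
    decoys cannot cross-react with planted instances and their association
    statistics stay null.
    """
    comp = str.maketrans("ACGT", "TGCA")

    def max_identity(a: str, b: str) -> int:
        best = 0
        for bb in (b, b.translate(comp)[::-1]):
            for shift in range(-len(a) + 4, len(bb) - 3):
                m = sum(1 for i, ch in enumerate(a)
                        if 0 <= i + shift < len(bb) and bb[i + shift] == ch)
                best = max(best, m)
        return best

    rng = np.random.default_rng(seed)
    out: list[PWM] = []
    while len(out) < n:
        consensus = "".join("ACGT"[j] for j in rng.integers(0, 4, size=length))
        if avoid and any(max_identity(consensus, s) > max_matches
                         for s in avoid):
            continue
        out.append(consensus_pwm(f"decoy_{len(out):02d}", consensus))
    return out


def planted_instance_strings(params: GeneratorParams) -> list[str]:
    """Consensus plus every single-core-mutation variant of the planted
    motifs (the sequences decoy PWMs must not resemble)."""
    out = []
    for pwm in list(params.ldtf_pwms) + list(params.sdtf_pwms):
        cons = pwm.consensus
        out.append(cons)
        for c in _CORE_OFFSETS:
            for b in "ACGT":
                if b != cons[c]:
                    out.append(cons[:c] + b + cons[c + 1:])
    return out


# --------------------------------------------------------------------------
# planted instances and occupancies


def _instance_score(pwm: PWM, seq: str) -> float:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    return float(sum(np.log2(pwm.matrix[i, idx[b]] / 0.25)
                     for i, b in enumerate(seq)))


def _lowest_prob_base(pwm: PWM, position: int) -> str:
    return "ACGT"[int(np.argmin(pwm.matrix[position]))]


def _planted_instances(pwm: PWM, rng: np.random.Generator | None = None
                       ) -> dict[str, str]:
    """Allele triplet of a planted instance.

    standard — consensus core with one designated core mismatch (a solid but
    improvable site); mutated — a second core position knocked out; improved
    — all core positions restored to consensus.  When ``rng`` is given the
    flanking bases are sampled from the PWM probabilities (shared by all
    three alleles), so instances vary in affinity across elements the way
    natural suboptimal sites do; occupancies are computed relative to each
    element's own standard-instance score, so the activity model is
    unaffected."""
    if rng is None:
        c1, c2 = _CORE_OFFSETS[0], _CORE_OFFSETS[1]
    else:  # core positions tie in information content; pick the pair randomly
        c1, c2 = (int(c) for c in rng.choice(_CORE_OFFSETS, size=2,
                                             replace=False))
    bases = []
    for i in range(len(pwm)):
        if rng is None or i in _CORE_OFFSETS:
            bases.append("ACGT"[int(np.argmax(pwm.matrix[i]))])
        else:
            bases.append("ACGT"[int(rng.choice(4, p=pwm.matrix[i]
                                               / pwm.matrix[i].sum()))])

    def low_base(position: int) -> str:
        # all non-consensus bases tie for lowest probability; sample the tie
        col = pwm.matrix[position]
        ties = np.flatnonzero(np.isclose(col, col.min()))
        j = ties[0] if rng is None else rng.choice(ties)
        return "ACGT"[int(j)]

    improved = "".join(bases)
    std = improved[:c1] + low_base(c1) + improved[c1 + 1:]
    mut = std[:c2] + low_base(c2) + std[c2 + 1:]
    return {"standard": std, "mutated": mut, "improved": improved}


@dataclass
class GeneratorParams:
    """Study conditions of the synthetic experiment.

    ``mechanism_mix`` gives the proportions of the five element classes;
    ``frac_linked`` adds, on top, variant-free differential elements wired to
    causal partners.  ``noise_dispersion`` is the negative-binomial
    overdispersion (variance = mu + dispersion * mu^2); 0 = deterministic
    means.  ``frac_silent_variants`` is the fraction of all planted variants
    that fall outside motif instances.
    """

    n_elements: int = 300
    n_genes: int = 100
    chrom_len: int | None = None          # default: 2200 bp per placed feature
    ldtf_pwms: list = field(default_factory=default_ldtf_pwms)
    sdtf_pwms: list = field(default_factory=default_sdtf_pwms)
    mechanism_mix: dict = field(default_factory=lambda: {
        "low_basal": 0.10, "equal_basal": 0.20, "high_basal": 0.15,
        "conserved": 0.40, "background": 0.15})
    frac_linked: float = 0.05
    gene_mix: dict = field(default_factory=lambda: {
        "cis": 0.30, "trans": 0.20, "conserved": 0.50})
    occupancy_slope: float = 1.5          # logistic steepness per log-odds unit
    occupancy_offset: float = 3.5         # log-odds above midpoint of standard instance
    act_basal_coef: float = 36.0
    act_induced_coef: float = 160.0
    act_gain_range: tuple = (1.0, 2.0)    # per-element log-uniform induced-term gain
    linked_suppression_range: tuple = (1.8, 6.0)
    noise_dispersion: float = 0.05
    frac_silent_variants: float = 0.5
    n_replicates: int = 3
    frac_responsive_genes: float = 0.4
    gene_ratio_log2_range: tuple = (1.75, 3.0)
    f1_total_count: float = 500.0         # mean F1 read count per transcript
    f1_informative_mean: float = 150.0    # mean variant-overlapping reads
    n_indels: int | None = None           # default: max(2, n_elements // 100)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise ValueError("mechanism_mix must sum to 1")
        if set(self.mechanism_mix) - set(MECHANISMS):
            raise ValueError(f"unknown mechanisms: "
                             f"{set(self.mechanism_mix) - set(MECHANISMS)}")
        if abs(sum(self.gene_mix.values()) - 1.0) > 1e-9:
            raise ValueError("gene_mix must sum to 1")
        if self.n_elements < 10:
            raise ValueError("need n_elements >= 10")
        if not 0 <= self.frac_silent_variants < 1:
            raise ValueError("frac_silent_variants must lie in [0, 1)")
        if self.act_basal_coef < 0 or self.act_induced_coef < 0:
            raise ValueError("activity coefficients must be >= 0")


@dataclass
class SyntheticDataset:
    genomes: dict                    # strain -> sequence
    intervals: list                  # element GenomicIntervals (strainA coords)
    tss: list                        # (chrom, pos) gene TSS list
    variants: pd.DataFrame           # strainB differences vs strainA (0-based)
    signals: pd.DataFrame            # replicate-averaged normalized tags
    expression: pd.DataFrame
    interactions: pd.DataFrame       # BEDPE-style with strength
    f1_counts: pd.DataFrame          # gene_id, total_count, informative_a/b
    truth_elements: pd.DataFrame     # element_id, mechanism, linked_partner, ...
    truth_variants: pd.DataFrame     # chrom, pos, causal, element_id
    truth_genes: pd.DataFrame        # gene_id, regulation, log2_ratio, responsive
    params: GeneratorParams | None = None


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _nb_sample(rng: np.random.Generator, mean: float, dispersion: float,
               n: int) -> np.ndarray:
    if dispersion <= 0:
        return np.full(n, mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n).astype(float)


def generate(params: GeneratorParams) -> SyntheticDataset:  # noqa: C901
    """Generate a full strain-pair dataset; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n_el, n_genes = params.n_elements, params.n_genes
    n_linked = int(round(params.frac_linked * n_el))
    chrom_len = params.chrom_len or 2200 * (n_el + n_genes) + 4000

    # --- genome A ----------------------------------------------------------
    genome_a = rng.integers(0, 4, size=chrom_len)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    # --- feature layout: interleave enhancer slots and gene TSSs -----------
    total = n_el + n_genes
    spacing = chrom_len // (total + 1)
    jitter = rng.integers(-spacing // 5, spacing // 5 + 1, size=total)
    positions = spacing * (np.arange(1, total + 1)) + jitter
    gene_slots = set(int(i) for i in rng.choice(total, size=n_genes, replace=False))
    el_centers = [int(p) for i, p in enumerate(positions) if i not in gene_slots]
    tss_positions = [int(p) for i, p in enumerate(positions) if i in gene_slots]

    # --- element mechanisms -------------------------------------------------
    mechs = list(params.mechanism_mix)
    probs = np.array([params.mechanism_mix[m] for m in mechs])
    counts = np.floor(probs * (n_el - n_linked)).astype(int)
    while counts.sum() < n_el - n_linked:       # distribute rounding remainder
        counts[int(np.argmax(probs * (n_el - n_linked) - counts))] += 1
    mech_labels = [m for m, c in zip(mechs, counts) for _ in range(c)] \
        + ["linked"] * n_linked
    rng.shuffle(mech_labels)

    # --- plant motifs in A, record per-element model state ------------------
    elements, rows = [], []
    motif_spans: list[tuple[int, int]] = []
    variant_rows, truth_variant_rows = [], []
    half = 150
    for i, center in enumerate(el_centers):
        eid = f"el{i:05d}"
        mech = mech_labels[i]
        iv = GenomicInterval(CHROM, center - half, center + half, eid)
        elements.append(iv)
        ldtf = params.ldtf_pwms[int(rng.integers(len(params.ldtf_pwms)))]
        sdtf = params.sdtf_pwms[int(rng.integers(len(params.sdtf_pwms)))]
        gain = float(np.exp(rng.uniform(np.log(params.act_gain_range[0]),
                                        np.log(params.act_gain_range[1]))))
        row = {"element_id": eid, "mechanism": mech, "center": center,
               "ldtf": ldtf.name, "sdtf": sdtf.name, "gain": gain,
               "linked_partner": "", "suppression": 1.0}

        if mech == "background":
            row.update(sL_A=None, sL_B=None, sS_A=None, sS_B=None)
            rows.append(row)
            continue

        inst_l = _planted_instances(ldtf, rng)
        inst_s = _planted_instances(sdtf, rng)
        l_start = center - 60 + int(rng.integers(0, 31))
        s_start = center + 15 + int(rng.integers(0, 31))

        # allele per strain and motif: "improved" carries consensus cores;
        # "standard" knocks one core position down to a low-probability base.
        # Only the mechanism's target motif differs between strains; the
        # improvable (weak) allele sits in the responsive strain only for
        # high_basal elements, whose strainB copy restores the consensus.
        a_allele_l = a_allele_s = "improved"
        b_allele_l = b_allele_s = "improved"
        if mech == "low_basal":
            b_allele_l = "standard"
        elif mech == "equal_basal":
            b_allele_s = "standard"
        elif mech == "high_basal":
            a_allele_l = "standard"

        for pwm, inst, start, allele in ((ldtf, inst_l, l_start, a_allele_l),
                                         (sdtf, inst_s, s_start, a_allele_s)):
            seq = np.frombuffer(inst[allele].encode(), dtype=np.uint8)
            genome_a[start:start + len(pwm)] = np.searchsorted(bases, seq)
            motif_spans.append((start, start + len(pwm)))

        for inst, start, aa, ba in ((inst_l, l_start, a_allele_l, b_allele_l),
                                    (inst_s, s_start, a_allele_s, b_allele_s)):
            if aa == ba:
                continue
            for off, (a, b) in enumerate(zip(inst[aa], inst[ba])):
                if a != b:
                    pos = start + off
                    variant_rows.append((CHROM, pos, a, b, STRAIN_B))
                    truth_variant_rows.append((CHROM, pos, True, eid))

        if mech == "linked":
            row["suppression"] = float(np.exp(rng.uniform(
                np.log(params.linked_suppression_range[0]),
                np.log(params.linked_suppression_range[1]))))

        # occupancies are anchored at the responsive (strainA) allele score
        row.update(
            sL_A=_instance_score(ldtf, inst_l[a_allele_l]),
            sL_B=_instance_score(ldtf, inst_l[b_allele_l]),
            sS_A=_instance_score(sdtf, inst_s[a_allele_s]),
            sS_B=_instance_score(sdtf, inst_s[b_allele_s]),
            sL_std=_instance_score(ldtf, inst_l[a_allele_l]),
            sS_std=_instance_score(sdtf, inst_s[a_allele_s]),
        )
        rows.append(row)

    # wire linked elements to causal equal-basal partners
    causal_pool = [r["element_id"] for r in rows if r["mechanism"] == "equal_basal"]
    li = 0
    for r in rows:
        if r["mechanism"] == "linked" and causal_pool:
            r["linked_partner"] = causal_pool[li % len(causal_pool)]
            li += 1

    # --- silent variants and intergenic indels ------------------------------
    n_causal = len(variant_rows)
    f = params.frac_silent_variants
    n_silent = int(round(n_causal * f / (1.0 - f))) if f > 0 else 0
    spans = sorted(motif_spans)
    silent_eligible = []
    for iv, r in zip(elements, rows):
        if r["mechanism"] in ("linked",):
            continue  # linked elements stay variant-free
        for p in range(iv.start, iv.end):
            silent_eligible.append((p, iv.id))
    span_starts = np.array([s for s, _ in spans]) if spans else np.array([])
    span_ends = np.array([e for _, e in spans]) if spans else np.array([])

    def in_motif(p: int) -> bool:
        if len(span_starts) == 0:
            return False
        j = np.searchsorted(span_starts, p, "right") - 1
        return bool(j >= 0 and p < span_ends[j])

    eligible = [(p, eid) for p, eid in silent_eligible if not in_motif(p)]
    taken = set(p for _, p, *_ in [(0, v[1]) for v in variant_rows])
    pick = rng.choice(len(eligible), size=min(n_silent, len(eligible)),
                      replace=False) if eligible and n_silent else []
    for j in np.atleast_1d(pick):
        p, eid = eligible[int(j)]
        if p in taken:
            continue
        taken.add(p)
        ref = "ACGT"[genome_a[p]]
        alt = "ACGT"[(genome_a[p] + 1 + int(rng.integers(3))) % 4]
        variant_rows.append((CHROM, p, ref, alt, STRAIN_B))
        truth_variant_rows.append((CHROM, p, False, eid))

    n_indels = params.n_indels if params.n_indels is not None \
        else max(2, n_el // 100)
    el_bounds = sorted((iv.start - 20, iv.end + 20) for iv in elements)
    el_bounds += [(t - 170, t + 170) for t in tss_positions]
    indel_sites: list[int] = []
    for _ in range(n_indels):
        for _try in range(50):
            p = int(rng.integers(100, chrom_len - 100))
            if any(s <= p < e for s, e in el_bounds):
                continue
            if p in taken or any(abs(p - q) < 10 for q in indel_sites):
                continue
            taken.add(p)
            indel_sites.append(p)
            ref_base = "ACGT"[genome_a[p]]
            ins = bool(rng.integers(2))
            extra = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=1 + int(
                rng.integers(3))))
            if ins:
                variant_rows.append((CHROM, p, ref_base, ref_base + extra, STRAIN_B))
            else:
                dlen = len(extra)
                ref = "".join("ACGT"[int(b)] for b in genome_a[p:p + 1 + dlen])
                variant_rows.append((CHROM, p, ref, ref[0], STRAIN_B))
            truth_variant_rows.append((CHROM, p, False, ""))
            break

    genome_a_str = "".join("ACGT"[int(b)] for b in genome_a)
    variants = (pd.DataFrame(variant_rows,
                             columns=["chrom", "pos", "ref_allele", "alt_allele",
                                      "strain"])
                .sort_values("pos").reset_index(drop=True))
    truth_variants = (pd.DataFrame(truth_variant_rows,
                                   columns=["chrom", "pos", "causal", "element_id"])
                      .sort_values("pos").reset_index(drop=True))
    genome_b_str = apply_variants(genome_a_str, variants)

    # --- occupancies and signal table ---------------------------------------
    slope, off = params.occupancy_slope, params.occupancy_offset
    ab, ai = params.act_basal_coef, params.act_induced_coef

    def occ(score, std_score):
        return _sigmoid(slope * (score - (std_score - off)))

    sig_rows = []
    for r in rows:
        eid, mech, gain = r["element_id"], r["mechanism"], r["gain"]
        for strain in (STRAIN_A, STRAIN_B):
            if mech == "background":
                occ_l = occ_s = relief = 0.0
            else:
                suffix = "A" if strain == STRAIN_A else "B"
                occ_l = occ(r[f"sL_{suffix}"], r["sL_std"])
                occ_s = occ(r[f"sS_{suffix}"], r["sS_std"])
                occ_std = occ(r["sL_std"], r["sL_std"])
                relief = max(0.0, min(1.0, (occ_l - occ_std) / (1.0 - occ_std)))
            suppress = r["suppression"] if (strain == STRAIN_B
                                            and mech == "linked") else 1.0
            for assay, (base, bc, ic) in ASSAY_MODEL.items():
                if mech == "background":
                    quiet = _QUIET_LEVEL if assay in ("H3K27ac",) else \
                        _QUIET_LEVEL * 0.6
                    mu_b = mu_s = base + quiet
                else:
                    drive = ai * gain * occ_l * occ_s / suppress
                    mu_b = base + bc * ab * occ_l + ic * drive * relief
                    mu_s = base + bc * ab * occ_l + ic * drive
                for cond, mu in (("basal", mu_b), ("stimulated", mu_s)):
                    reps = _nb_sample(rng, mu, params.noise_dispersion,
                                      params.n_replicates)
                    sig_rows.append((eid, strain, cond, assay,
                                     float(reps.mean())))

    # --- genes: expression, q-values, F1 counts -----------------------------
    gene_classes = list(params.gene_mix)
    gprobs = np.array([params.gene_mix[g] for g in gene_classes])
    gcounts = np.floor(gprobs * n_genes).astype(int)
    while gcounts.sum() < n_genes:
        gcounts[int(np.argmax(gprobs * n_genes - gcounts))] += 1
    gene_labels = [g for g, c in zip(gene_classes, gcounts) for _ in range(c)]
    rng.shuffle(gene_labels)

    expr_rows, truth_gene_rows, f1_rows = [], [], []
    lo, hi = params.gene_ratio_log2_range
    for gi, tss in enumerate(tss_positions):
        gid = f"gene{gi:04d}"
        reg = gene_labels[gi]
        responsive = bool(rng.random() < params.frac_responsive_genes)
        base_tpm = float(np.exp(rng.normal(np.log(20.0), 0.8)))
        log2_ratio = 0.0
        if reg in ("cis", "trans"):
            log2_ratio = float(rng.uniform(lo, hi) * (1 if rng.random() < 0.5
                                                      else -1))
        ratio = 2.0 ** log2_ratio  # strainA / strainB expression ratio
        for strain in (STRAIN_A, STRAIN_B):
            strain_factor = 1.0 if strain == STRAIN_A else 1.0 / ratio
            for cond in ("basal", "stimulated"):
                induce = 4.0 if (responsive and cond == "stimulated") else 1.0
                mu_tpm = base_tpm * strain_factor * induce
                cnts = _nb_sample(rng, mu_tpm * 10.0, params.noise_dispersion,
                                  params.n_replicates)
                for ri, c in enumerate(cnts):
                    expr_rows.append((gid, strain, cond, ri,
                                      float(c) / 10.0, float(round(c))))
        # F1 allelic counts at the stimulated condition
        total = float(_nb_sample(rng, params.f1_total_count,
                                 params.noise_dispersion, 1)[0])
        n_info = int(rng.poisson(params.f1_informative_mean))
        p_a = ratio / (1.0 + ratio) if reg == "cis" else 0.5
        info_a = int(rng.binomial(n_info, p_a)) if n_info else 0
        f1_rows.append((gid, total, info_a, n_info - info_a))
        truth_gene_rows.append((gid, reg, log2_ratio, responsive, tss))

    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", "strain", "condition", "replicate",
                            "tpm", "count"])
    expression["count"] = expression["count"].astype(int)
    expression = _attach_q_values(expression)
    truth_genes = pd.DataFrame(
        truth_gene_rows,
        columns=["gene_id", "regulation", "log2_ratio", "responsive", "tss"])
    f1_counts = pd.DataFrame(
        f1_rows, columns=["gene_id", "total_count", "informative_a",
                          "informative_b"])

    # --- promoter elements for genes ----------------------------------------
    prom_rows = []
    for gi, tss in enumerate(tss_positions):
        pid = f"prom{gi:04d}"
        responsive = bool(truth_genes.loc[gi, "responsive"])
        elements.append(GenomicInterval(CHROM, max(0, tss - 150), tss + 150, pid))
        basal_mu = {"H3K27ac": 40.0, "PolII": 30.0, "ATAC": 45.0,
                    "TF_LDTF": 40.0, "TF_SDTF": 3.0}
        for strain in (STRAIN_A, STRAIN_B):
            for assay, mu0 in basal_mu.items():
                for cond in ("basal", "stimulated"):
                    mu = mu0 * (4.0 if (responsive and cond == "stimulated"
                                        and assay in ("H3K27ac", "PolII"))
                                else 1.0)
                    reps = _nb_sample(rng, mu, params.noise_dispersion,
                                      params.n_replicates)
                    prom_rows.append((pid, strain, cond, assay,
                                      float(reps.mean())))
    signals = pd.DataFrame(sig_rows + prom_rows,
                           columns=["element_id", "strain", "condition",
                                    "assay", "value"])

    # --- interactions --------------------------------------------------------
    inter_rows = []
    enh_ivs = {r["element_id"]: iv for iv, r in zip(elements, rows)}
    induced_enh = [r["element_id"] for r in rows
                   if r["mechanism"] in ("conserved", "low_basal",
                                         "equal_basal", "high_basal")]
    quiet_enh = [r["element_id"] for r in rows if r["mechanism"] == "background"]
    prom_ids = [f"prom{gi:04d}" for gi in range(n_genes)]
    prom_iv = {pid: iv for pid, iv in
               zip(prom_ids, elements[len(rows):len(rows) + n_genes])}

    def add_pair(iv1: GenomicInterval, iv2: GenomicInterval):
        inter_rows.append((iv1.chrom, iv1.start, iv1.end,
                           iv2.chrom, iv2.start, iv2.end,
                           float(rng.poisson(20) + 1)))

    for gi, pid in enumerate(prom_ids):
        responsive = bool(truth_genes.loc[gi, "responsive"])
        pool = induced_enh if (responsive and rng.random() < 0.85) else \
            (quiet_enh if quiet_enh and not responsive and rng.random() < 0.85
             else induced_enh + quiet_enh)
        if not pool:
            continue
        for _ in range(int(rng.integers(1, 3))):
            partner = pool[int(rng.integers(len(pool)))]
            add_pair(prom_iv[pid], enh_ivs[partner])
    # random enhancer-enhancer pairs
    all_enh = list(enh_ivs)
    for _ in range(n_el // 3):
        i, j = rng.integers(len(all_enh)), rng.integers(len(all_enh))
        if i == j:
            continue
        add_pair(enh_ivs[all_enh[int(i)]], enh_ivs[all_enh[int(j)]])
    # wired linked pairs
    for r in rows:
        if r["mechanism"] == "linked" and r["linked_partner"]:
            add_pair(enh_ivs[r["element_id"]], enh_ivs[r["linked_partner"]])

    interactions = pd.DataFrame(
        inter_rows, columns=["chrom1", "start1", "end1",
                             "chrom2", "start2", "end2", "strength"])

    truth_elements = pd.DataFrame(
        [{"element_id": r["element_id"],
          "mechanism": r["mechanism"],
          "linked_partner": r["linked_partner"],
          "gain": r["gain"], "ldtf": r["ldtf"], "sdtf": r["sdtf"]}
         for r in rows])

    return SyntheticDataset(
        genomes={STRAIN_A: genome_a_str, STRAIN_B: genome_b_str},
        intervals=elements,
        tss=[(CHROM, p) for p in tss_positions],
        variants=variants,
        signals=signals,
        expression=expression,
        interactions=interactions,
        f1_counts=f1_counts,
        truth_elements=truth_elements,
        truth_variants=truth_variants,
        truth_genes=truth_genes,
        params=params,
    )


def _attach_q_values(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, strain) induction q-values: Welch t-test on log2(count + 1)
    replicates, Benjamini-Hochberg adjusted within strain."""
    from scipy import stats as sstats
    from statsmodels.stats.multitest import multipletests

    qmap = {}
    for strain, sub in expression.groupby("strain"):
        genes, pvals = [], []
        piv = sub.pivot_table(index="gene_id", columns="condition",
                              values="count", aggfunc=list)
        for gid, row in piv.iterrows():
            a = np.log2(np.asarray(row["stimulated"], float) + 1)
            b = np.log2(np.asarray(row["basal"], float) + 1)
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p = 1.0
            else:
                p = float(sstats.ttest_ind(a, b, equal_var=False).pvalue)
            genes.append(gid)
            pvals.append(p if np.isfinite(p) else 1.0)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for g, q in zip(genes, qvals):
            qmap[(g, strain)] = float(q)
    out = expression.copy()
    out["q"] = [qmap[(g, s)] for g, s in zip(out["gene_id"], out["strain"])]
    return out


# --------------------------------------------------------------------------
# variant application / liftover


def apply_variants(seq: str, variants: pd.DataFrame) -> str:
    """Apply left-aligned ref/alt edits (sorted by position) to a sequence."""
    out = []
    cursor = 0
    for _, v in variants.sort_values("pos").iterrows():
        pos, ref, alt = int(v["pos"]), str(v["ref_allele"]), str(v["alt_allele"])
        if seq[pos:pos + len(ref)] != ref:
            raise ValueError(f"ref allele mismatch at {pos}: "
                             f"expected {ref!r}, found {seq[pos:pos + len(ref)]!r}")
        out.append(seq[cursor:pos])
        out.append(alt)
        cursor = pos + len(ref)
    out.append(seq[cursor:])
    return "".join(out)


def liftover(variants: pd.DataFrame, pos: int) -> int:
    """Shift a strainA coordinate to its strainB equivalent given the edits."""
    vpos = variants["pos"].to_numpy(int)
    ref_len = variants["ref_allele"].astype(str).str.len().to_numpy(int)
    alt_len = variants["alt_allele"].astype(str).str.len().to_numpy(int)
    before = vpos + ref_len <= pos
    return pos + int((alt_len[before] - ref_len[before]).sum())


def make_liftover(variants: pd.DataFrame):
    """Vectorized strainA -> strainB coordinate shift function."""
    v = variants.sort_values("pos")
    vpos = v["pos"].to_numpy(int)
    ref_len = v["ref_allele"].astype(str).str.len().to_numpy(int)
    alt_len = v["alt_allele"].astype(str).str.len().to_numpy(int)
    ends = vpos + ref_len
    cum = np.concatenate([[0], np.cumsum(alt_len - ref_len)])

    def shift(pos: int) -> int:
        i = int(np.searchsorted(ends, pos, "right"))
        return pos + int(cum[i])

    return shift


def element_sequences(ds: SyntheticDataset, element_id: str) -> tuple[str, str]:
    """Homologous (strainA, strainB) sequences of an element window."""
    iv = next(v for v in ds.intervals if v.id == element_id)
    seq_a = ds.genomes[STRAIN_A][iv.start:iv.end]
    b_start = liftover(ds.variants, iv.start)
    b_end = liftover(ds.variants, iv.end)
    seq_b = ds.genomes[STRAIN_B][b_start:b_end]
    return seq_a, seq_b


# --------------------------------------------------------------------------
# on-disk round trip


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta({f"{CHROM}_{s}": seq for s, seq in ds.genomes.items()},
                d / "genomes.fa")
    write_bed(ds.intervals, d / "elements.bed")
    write_vcf_like(ds.variants, d / "variants.tsv")
    write_signal_table(ds.signals, d / "signals.tsv")
    write_expression_table(ds.expression, d / "expression.tsv")
    write_bedpe(ds.interactions, d / "interactions.bedpe")
    _write_table(pd.DataFrame(ds.tss, columns=["chrom", "pos"]), d / "tss.tsv")
    _write_table(ds.f1_counts, d / "f1_counts.tsv")
    _write_table(ds.truth_elements, d / "truth_elements.tsv")
    _write_table(ds.truth_variants, d / "truth_variants.tsv")
    _write_table(ds.truth_genes, d / "truth_genes.tsv")


def read_dataset(directory: str | Path) -> SyntheticDataset:
    d = Path(directory)
    genomes = {name.split("_", 1)[1]: seq
               for name, seq in read_fasta(d / "genomes.fa").items()}
    truth_elements = _read_table(d / "truth_elements.tsv")
    truth_elements["linked_partner"] = \
        truth_elements["linked_partner"].fillna("").astype(str)
    truth_variants = _read_table(d / "truth_variants.tsv")
    truth_variants["element_id"] = \
        truth_variants["element_id"].fillna("").astype(str)
    return SyntheticDataset(
        genomes=genomes,
        intervals=read_bed(d / "elements.bed"),
        tss=[(r["chrom"], int(r["pos"]))
             for _, r in _read_table(d / "tss.tsv").iterrows()],
        variants=read_vcf_like(d / "variants.tsv"),
        signals=read_signal_table(d / "signals.tsv"),
        expression=read_expression_table(d / "expression.tsv"),
        interactions=read_bedpe(d / "interactions.bedpe"),
        f1_counts=_read_table(d / "f1_counts.tsv"),
        truth_elements=truth_elements,
        truth_variants=truth_variants,
        truth_genes=_read_table(d / "truth_genes.tsv"),
    )


# --------------------------------------------------------------------------
# multi-strain panel for connectivity correlation tests


def simulate_connected_signal_panel(n_connected: int = 60, n_unconnected: int = 60,
                                    n_strains: int = 5, seed: int = 0,
                                    latent_sd: float = 1.0,
                                    noise_sd: float = 0.4
                                    ) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Signals across several strains where connected enhancer pairs share a
    per-strain latent activity factor; unconnected enhancers vary
    independently.  Returns (signals, interactions, intervals)."""
    rng = np.random.default_rng(seed)
    strains = [f"strain{i}" for i in range(n_strains)]
    intervals, sig_rows, inter_rows = [], [], []
    pos = 10_000
    eid = 0

    def add_element(values: np.ndarray) -> GenomicInterval:
        nonlocal pos, eid
        iv = GenomicInterval(CHROM, pos, pos + 300, f"pe{eid:04d}")
        intervals.append(iv)
        for s, v in zip(strains, values):
            sig_rows.append((iv.id, s, "stimulated", "H3K27ac", float(v)))
        pos += 5000
        eid += 1
        return iv

    for _ in range(n_connected):
        latent = rng.normal(0, latent_sd, size=n_strains)
        v1 = np.exp(np.log(50) + latent + rng.normal(0, noise_sd, n_strains))
        v2 = np.exp(np.log(50) + latent + rng.normal(0, noise_sd, n_strains))
        iv1, iv2 = add_element(v1), add_element(v2)
        inter_rows.append((iv1.chrom, iv1.start, iv1.end,
                           iv2.chrom, iv2.start, iv2.end, 10.0))
    for _ in range(n_unconnected):
        v = np.exp(np.log(50) + rng.normal(0, latent_sd, n_strains)
                   + rng.normal(0, noise_sd, n_strains))
        add_element(v)
    signals = pd.DataFrame(sig_rows, columns=["element_id", "strain",
                                              "condition", "assay", "value"])
    interactions = pd.DataFrame(inter_rows,
                                columns=["chrom1", "start1", "end1",
                                         "chrom2", "start2", "end2", "strength"])
    return signals, interactions, intervals
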