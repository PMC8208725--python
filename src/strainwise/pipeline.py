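"""End-to-end orchestration: simulate -> call -> compare -> model -> report.

The pipeline stages are thin compositions of the analysis modules; every
intermediate table is written to the output directory so each stage's output
is the next stage's input, and a manifest records digests for provenance.
This module also hosts the strain-pair analysis routines that combine
per-strain primitives (element categorization, cis/trans tables) used by the
analysis scripts and the acceptance checks.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from strainwise import __version__
from strainwise.config import PipelineConfig
from strainwise import elements as el
from strainwise import strains as st
from strainwise import motifs as mo
from strainwise import seqmodel as sm
from strainwise import connectivity as cn
from strainwise import simulate as sim
from strainwise.io import GenomicInterval, write_bed, write_signal_table

__all__ = [
    "element_state_table", "categorize_pair_elements", "cis_trans_table",
    "run_pipeline", "report", "score_all_elements", "differential_element_ids",
]


# --------------------------------------------------------------------------
# strain-pair analysis layer


def element_state_table(signals: pd.DataFrame, cfg: PipelineConfig,
                        strains: tuple[str, str] = (sim.STRAIN_A, sim.STRAIN_B)
                        ) -> pd.DataFrame:
    """Wide per-element table of state and H3K27ac fold change per strain."""
    frames = []
    for strain in strains:
        calls = el.classify_elements(signals, strain, cfg)
        frames.append(pd.DataFrame([c.__dict__ for c in calls])
                      .set_index("element_id")
                      .rename(columns={"state": f"state_{strain}",
                                       "fc_h3k27ac": f"fc_{strain}",
                                       "fc_polii": f"fc_polii_{strain}"})
                      .drop(columns="strain"))
    return pd.concat(frames, axis=1).reset_index()


def _basal_h3k27ac(signals: pd.DataFrame) -> pd.DataFrame:
    sub = signals[(signals["assay"] == el.H3K27AC)
                  & (signals["condition"] == el.BASAL)]
    return sub.pivot_table(index="element_id", columns="strain",
                           values="value", aggfunc="mean")


def categorize_pair_elements(signals: pd.DataFrame, cfg: PipelineConfig,
                             strains: tuple[str, str] = (sim.STRAIN_A,
                                                         sim.STRAIN_B)
                             ) -> pd.DataFrame:
    """Low/equal/high-basal categories for elements induced in exactly one
    strain of the pair (None for ineligible elements)."""
    s_a, s_b = strains
    states = element_state_table(signals, cfg, strains).set_index("element_id")
    basal = _basal_h3k27ac(signals)
    rows = []
    for eid, r in states.iterrows():
        ind_a = r[f"state_{s_a}"] == "induced"
        ind_b = r[f"state_{s_b}"] == "induced"
        if ind_a == ind_b:
            continue
        ind, non = (s_a, s_b) if ind_a else (s_b, s_a)
        category = st.categorize_enhancer(
            basal_induced_strain=float(basal.loc[eid, ind]),
            basal_noninduced_strain=float(basal.loc[eid, non]),
            fc_induced_strain=float(r[f"fc_{ind}"]),
            fc_noninduced_strain=float(r[f"fc_{non}"]),
            cfg=cfg)
        rows.append({"element_id": eid, "induced_strain": ind,
                     "category": category})
    return pd.DataFrame(rows, columns=["element_id", "induced_strain",
                                       "category"])


def differential_element_ids(signals: pd.DataFrame, cfg: PipelineConfig,
                             strains=(sim.STRAIN_A, sim.STRAIN_B)) -> list[str]:
    """Elements induced in exactly one strain of the pair."""
    s_a, s_b = strains
    states = element_state_table(signals, cfg, strains)
    ind_a = states[f"state_{s_a}"] == "induced"
    ind_b = states[f"state_{s_b}"] == "induced"
    return states.loc[ind_a ^ ind_b, "element_id"].tolist()


def cis_trans_table(expression: pd.DataFrame, f1_counts: pd.DataFrame,
                    cfg: PipelineConfig, condition: str = "stimulated",
                    strains=(sim.STRAIN_A, sim.STRAIN_B)) -> pd.DataFrame:
    """Classify each gene's strain difference as cis / trans / unclassified.

    Parental fold change = strainA/strainB mean TPM ratio (pseudocount 1) at
    the given condition; the F1 fold change comes from allele-assigned counts.
    Genes lacking informative reads for an allele are flagged filtered.
    """
    s_a, s_b = strains
    sub = expression[expression["condition"] == condition]
    mean_tpm = sub.pivot_table(index="gene_id", columns="strain",
                               values="tpm", aggfunc="mean")
    rows = []
    for _, r in f1_counts.iterrows():
        gid = r["gene_id"]
        if gid not in mean_tpm.index:
            continue
        a, b, filtered = st.assign_f1_allelic_counts(
            float(r["total_count"]), float(r["informative_a"]),
            float(r["informative_b"]))
        parental_fc = (float(mean_tpm.loc[gid, s_a]) + 1.0) \
            / (float(mean_tpm.loc[gid, s_b]) + 1.0)
        if filtered:
            rows.append({"gene_id": gid, "label": "filtered",
                         "parental_fc": parental_fc, "f1_fc": np.nan})
            continue
        f1_fc = (a + 1.0) / (b + 1.0)
        rows.append({"gene_id": gid,
                     "label": st.cis_trans_classify(parental_fc, f1_fc, cfg),
                     "parental_fc": parental_fc, "f1_fc": f1_fc})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model scoring over a dataset


def score_all_elements(ds: sim.SyntheticDataset, model: sm.ConvNet,
                       cfg: PipelineConfig,
                       element_ids: list[str] | None = None
                       ) -> dict[str, sm.ImportanceTrack]:
    """Importance tracks (strainA sequences) for the requested elements."""
    wanted = set(element_ids) if element_ids is not None else None
    tracks = {}
    genome = ds.genomes[sim.STRAIN_A]
    for iv in ds.intervals:
        if wanted is not None and iv.id not in wanted:
            continue
        seq = genome[iv.start:iv.end]
        if len(seq) != cfg.seq_len_bp:
            continue
        tracks[iv.id] = sm.importance_scores(model, seq, iv.id, iv.chrom,
                                             iv.start, cfg)
    return tracks


def training_set(ds: sim.SyntheticDataset, cfg: PipelineConfig, seed: int
                 ) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Active-element sequences (strainA) and GC-matched backgrounds."""
    genome = ds.genomes[sim.STRAIN_A]
    active = set(ds.truth_elements.loc[
        ds.truth_elements["mechanism"] != "background", "element_id"])
    ivs = [iv for iv in ds.intervals
           if iv.id in active and iv.end - iv.start == cfg.seq_len_bp]
    bgs = sm.sample_gc_matched_background({sim.CHROM: genome}, ivs, cfg, seed)
    return ([genome[iv.start:iv.end] for iv in ivs],
            [genome[iv.start:iv.end] for iv in bgs],
            np.array([iv.center for iv in ivs]),
            np.array([iv.center for iv in bgs]))


def train_importance_ensemble(ds: sim.SyntheticDataset, cfg: PipelineConfig,
                              seed: int, n_members: int = 4
                              ) -> tuple[list[sm.TrainedModel],
                                         dict[str, sm.ImportanceTrack]]:
    """Train an ensemble of classifiers and combine their importance tracks.

    Member k trains with seed ``seed + k``; the returned tracks are the
    normalized ensemble average (see :func:`strainwise.seqmodel
    .combine_tracks`), which is what variant prioritization should use."""
    genome = ds.genomes[sim.STRAIN_A]
    pos, neg, pc, nc = training_set(ds, cfg, seed + 1000)
    models, track_sets = [], []
    for k in range(n_members):
        tm = sm.train_classifier(pos, neg, pc, nc, cfg, seed + k,
                                 span=len(genome))
        models.append(tm)
        track_sets.append(score_all_elements(ds, tm.model, cfg))
    weights = [max(m.val_auroc - 0.5, 0.02) for m in models]
    return models, sm.combine_tracks(track_sets, cfg, weights)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# pipeline


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 params: sim.GeneratorParams | None = None,
                 seed: int | None = None, n_decoys: int = 20,
                 train_model: bool = True, n_members: int = 4) -> Path:
    """Run the full synthetic strain-pair analysis and write all outputs.

    Stage order: simulate -> call-elements -> compare-strains -> cis-trans ->
    motif-test -> train-model -> score-variants -> connectivity -> report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    params = params or sim.GeneratorParams(seed=seed)

    ds = sim.generate(params)
    data_dir = out / "data"
    sim.write_dataset(ds, data_dir)

    meta = {"config": cfg.config_hash(), "seed": seed}

    # element calling, per strain
    states = element_state_table(ds.signals, cfg)
    states.to_csv(out / "element_states.tsv", sep="\t", index=False)

    # strain comparison: categories and tiers
    categories = categorize_pair_elements(ds.signals, cfg)
    categories.to_csv(out / "categories.tsv", sep="\t", index=False)
    stim = ds.signals[(ds.signals["assay"] == el.H3K27AC)
                      & (ds.signals["condition"] == el.STIM)]
    piv = stim.pivot_table(index="element_id", columns="strain",
                           values="value", aggfunc="mean")
    enhancer_ids = {iv.id for iv in ds.intervals if iv.id.startswith("el")}
    active = [e for e in piv.index if e in enhancer_ids]
    tiers = st.differential_tiers(piv.loc[active, sim.STRAIN_A],
                                  piv.loc[active, sim.STRAIN_B], cfg)
    tiers.to_csv(out / "tiers.tsv", sep="\t", index=False)

    by_id = {iv.id: iv for iv in ds.intervals}
    groups = {"similar": [by_id[e] for e in tiers.loc[tiers["similar"],
                                                      "element_id"]]}
    for t in cfg.differential_tiers:
        col = f"tier_gt_{t:g}"
        groups[col] = [by_id[e] for e in tiers.loc[tiers[col], "element_id"]]
    fractions = st.variant_overlap_fraction(groups, ds.variants, cfg)
    pd.DataFrame([{"group": k, "fraction": v} for k, v in fractions.items()]
                 ).to_csv(out / "variant_fractions.tsv", sep="\t", index=False)

    # cis / trans
    ct = cis_trans_table(ds.expression, ds.f1_counts, cfg)
    ct.to_csv(out / "cis_trans.tsv", sep="\t", index=False)

    # motif mutation test on strain-differential induced elements
    diff_ids = differential_element_ids(ds.signals, cfg)
    shift = sim.make_liftover(ds.variants)
    pairs = []
    genome_a, genome_b = ds.genomes[sim.STRAIN_A], ds.genomes[sim.STRAIN_B]
    for eid in diff_ids:
        iv = by_id.get(eid)
        if iv is None or not eid.startswith("el"):
            continue
        seq_a = genome_a[iv.start:iv.end]
        seq_b = genome_b[shift(iv.start):shift(iv.end)]
        pairs.append(mo.SequencePair(eid, seq_a, seq_b))
    pwms = list(params.ldtf_pwms) + list(params.sdtf_pwms) \
        + sim.make_decoy_pwms(n_decoys, seed=seed + 1)
    motif_rows = []
    results = []
    if len(pairs) >= 10:
        for pwm in pwms:
            res = mo.motif_mutation_test(pairs, pwm)
            results.append(res)
            motif_rows.append({"motif": res.motif,
                               "signed_logp": res.signed_logp,
                               "p": res.p, "n_nonzero": res.n_nonzero})
    pd.DataFrame(motif_rows).to_csv(out / "motif_results.tsv", sep="\t",
                                    index=False)
    if results:
        clusters = mo.cluster_motifs(results, cfg)
        pd.DataFrame([{"members": ",".join(c.members),
                       "mean_signed_logp": c.mean_signed_logp,
                       "representative": c.representative}
                      for c in clusters]).to_csv(out / "motif_clusters.tsv",
                                                 sep="\t", index=False)

    # sequence model
    attribution = pd.DataFrame()
    flagged = pd.DataFrame()
    model_info: dict = {}
    if train_model:
        models, tracks = train_importance_ensemble(ds, cfg, seed,
                                                   n_members=n_members)
        models[0].log.to_csv(out / "training_log.tsv", sep="\t", index=False)
        model_info = {"val_auroc": models[0].val_auroc,
                      "test_auroc": models[0].test_auroc,
                      "member_test_aurocs": [m.test_auroc for m in models],
                      "architecture": models[0].architecture}
        models[0].model.save(out / "model.npz")
        flagged, n_outside = sm.prioritize_variants(ds.variants, tracks,
                                                    ds.intervals, cfg)
        flagged.to_csv(out / "flagged_variants.tsv", sep="\t", index=False)
        model_info["variants_outside_windows"] = n_outside

        flagged_ids = {
            t.element_id for t in tracks.values()
            if not flagged.empty and any(
                (flagged["predicted_functional"])
                & (flagged["pos"] >= t.start)
                & (flagged["pos"] < t.start + len(t.scores)))}
        tier_groups = {k: [iv.id for iv in v] for k, v in groups.items()}
        enrich = sm.category_enrichment(tier_groups, flagged_ids,
                                        [iv.id for iv in ds.intervals
                                         if iv.id in enhancer_ids])
        pd.DataFrame([{"group": k, "log2_enrichment": v}
                      for k, v in enrich.items()]
                     ).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # connectivity
    tss = ds.tss
    annotated = el.annotate_context(ds.intervals, tss, cfg.promoter_window_bp)
    classified = cn.classify_interactions(ds.interactions, annotated, cfg)
    states_a = {r["element_id"]: r[f"state_{sim.STRAIN_A}"]
                for _, r in states.iterrows()}
    try:
        table, pvals = cn.promoter_enhancer_contingency(classified, annotated,
                                                        states_a)
        table.to_csv(out / "contingency.tsv", sep="\t")
        (out / "contingency_tests.json").write_text(json.dumps(pvals, indent=2))
    except ValueError:
        pass
    if train_model and not flagged.empty:
        attribution = cn.attribute_differential_enhancers(
            [e for e in diff_ids if e in enhancer_ids], flagged, classified,
            annotated, cfg)
        attribution.to_csv(out / "attribution.tsv", sep="\t", index=False)

    # manifest
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "stages": {
            "elements": len(states),
            "categories": int(categories["category"].notna().sum()),
            "cis_trans": len(ct),
            "motif_results": len(motif_rows),
            "interactions": len(ds.interactions),
        },
        "model": model_info,
        "digests": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report(out, ds)
    return out


# --------------------------------------------------------------------------
# report


def _count_table(series: pd.Series, title: str) -> str:
    counts = series.value_counts()
    lines = [f"### {title}", "", "| value | count |", "|---|---|"]
    for k, v in counts.items():
        lines.append(f"| {k} | {v} |")
    lines.append("")
    return "\n".join(lines)


def report(out_dir: str | Path, ds: sim.SyntheticDataset | None = None) -> Path:
    """Assemble the summary report from the stage outputs in ``out_dir``."""
    out = Path(out_dir)
    parts = [f"# strainwise run report", ""]

    def maybe(path: str) -> pd.DataFrame | None:
        p = out / path
        return pd.read_csv(p, sep="\t", comment="#") if p.exists() else None

    truth_elements = ds.truth_elements if ds is not None \
        else maybe("data/truth_elements.tsv")

    states = maybe("element_states.tsv")
    if states is not None:
        for col in [c for c in states.columns if c.startswith("state_")]:
            parts.append(_count_table(states[col], f"Element states ({col})"))

    cats = maybe("categories.tsv")
    if cats is not None:
        filled = cats["category"].fillna("(ineligible)")
        parts.append(_count_table(filled, "Strain-differential categories"))
        if truth_elements is not None:
            truth = truth_elements.set_index("element_id")["mechanism"]
            merged = cats.dropna(subset=["category"]).copy()
            merged["truth"] = merged["element_id"].map(truth)
            conf = pd.crosstab(merged["truth"], merged["category"],
                               dropna=False)
            parts += ["### Category confusion matrix (truth x called)", "",
                      conf.to_markdown(), ""]

    fr = maybe("variant_fractions.tsv")
    if fr is not None:
        parts += ["### Variant-containing fraction by tier", "",
                  fr.to_markdown(index=False), ""]

    en = maybe("enrichment.tsv")
    if en is not None:
        parts += ["### Top-variant enrichment by tier (log2)", "",
                  en.to_markdown(index=False), ""]

    ct = maybe("cis_trans.tsv")
    if ct is not None:
        parts.append(_count_table(ct["label"], "cis/trans labels"))

    mr = maybe("motif_results.tsv")
    if mr is not None and not mr.empty:
        top = mr.reindex(mr["signed_logp"].abs()
                         .sort_values(ascending=False).index).head(10)
        parts += ["### Motif-mutation association (top 10)", "",
                  top.to_markdown(index=False), ""]

    at = maybe("attribution.tsv")
    if at is not None and not at.empty:
        pct = (at["attribution"].value_counts(normalize=True) * 100).round(1)
        parts += ["### Differential-enhancer attribution (%)", "",
                  pct.to_frame("percent").to_markdown(), ""]

    path = out / "report.md"
    path.write_text("\n".join(parts))
    return path
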