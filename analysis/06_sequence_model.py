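#!/usr/bin/env python
"""Train the sequence-model ensemble and flag predicted-functional variants.

Writes results/flagged_variants.tsv, results/enrichment.tsv and
results/kmer_enrichment.tsv; prints flag rates against ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from strainwise import pipeline as pl
from strainwise import seqmodel as sm
from strainwise import simulate as sim
from strainwise import strains as st
from strainwise.config import load_config

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--members", type=int, default=5)
    args = ap.parse_args()
    cfg = load_config()
    ds = sim.read_dataset(args.data)

    models, tracks = pl.train_importance_ensemble(ds, cfg, seed=args.seed,
                                                  n_members=args.members)
    print("member test auROCs:",
          [round(m.test_auroc, 3) for m in models])

    flagged, n_outside = sm.prioritize_variants(ds.variants, tracks,
                                                ds.intervals, cfg)
    flagged.to_csv(args.out / "flagged_variants.tsv", sep="\t", index=False)
    merged = flagged.merge(ds.truth_variants, on=["chrom", "pos"])
    causal = merged[merged["causal"]]
    silent = merged[~merged["causal"] & (merged["element_id"] != "")]
    print(f"causal variants flagged: {causal['predicted_functional'].mean():.1%}"
          f" of {len(causal)}; silent: "
          f"{silent['predicted_functional'].mean():.1%} of {len(silent)}"
          f" ({n_outside} variants outside scored windows)")

    # tiered enrichment of elements with top-scoring variants
    stim = ds.signals[(ds.signals["assay"] == "H3K27ac")
                      & (ds.signals["condition"] == "stimulated")]
    piv = stim.pivot_table(index="element_id", columns="strain", values="value")
    enh = [e for e in piv.index if e.startswith("el")]
    tiers = st.differential_tiers(piv.loc[enh, sim.STRAIN_A],
                                  piv.loc[enh, sim.STRAIN_B], cfg)
    groups = {"similar": tiers.loc[tiers["similar"], "element_id"].tolist()}
    for t in cfg.differential_tiers:
        groups[f">{t:g}"] = tiers.loc[tiers[f"tier_gt_{t:g}"],
                                      "element_id"].tolist()
    fl = flagged[flagged["predicted_functional"]]
    flagged_ids = {t.element_id for t in tracks.values()
                   if ((fl["pos"] >= t.start)
                       & (fl["pos"] < t.start + len(t.scores))).any()}
    enrichment = sm.category_enrichment(groups, flagged_ids, enh)
    table = pd.DataFrame([{"group": k, "log2_enrichment": v}
                          for k, v in enrichment.items()])
    table.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    # 5-mer interpretation of the first member
    seqs = {eid: ds.genomes[sim.STRAIN_A][t.start:t.start + len(t.scores)]
            for eid, t in tracks.items()}
    kmers = sm.kmer_interpretation(list(tracks.values()), seqs, cfg)
    kmers.to_csv(args.out / "kmer_enrichment.tsv", sep="\t", index=False)
    print("top 5-mers:", kmers.head(5)["kmer"].tolist())


if __name__ == "__main__":
    main()
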