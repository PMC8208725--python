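#!/usr/bin/env python
"""Categorize strain-differential enhancers and tabulate variant fractions.

Writes results/categories.tsv, results/tiers.tsv,
results/variant_fractions.tsv and prints the truth confusion matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from strainwise import pipeline as pl
from strainwise import simulate as sim
from strainwise import strains as st
from strainwise.config import load_config

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    cfg = load_config()
    ds = sim.read_dataset(args.data)

    cats = pl.categorize_pair_elements(ds.signals, cfg)
    cats.to_csv(args.out / "categories.tsv", sep="\t", index=False)
    print("categories:", cats["category"].value_counts(dropna=False).to_dict())

    truth = ds.truth_elements.set_index("element_id")["mechanism"]
    merged = cats.dropna(subset=["category"]).copy()
    merged["truth"] = merged["element_id"].map(truth)
    print(pd.crosstab(merged["truth"], merged["category"]))

    stim = ds.signals[(ds.signals["assay"] == "H3K27ac")
                      & (ds.signals["condition"] == "stimulated")]
    piv = stim.pivot_table(index="element_id", columns="strain", values="value")
    enh = [e for e in piv.index if e.startswith("el")]
    tiers = st.differential_tiers(piv.loc[enh, sim.STRAIN_A],
                                  piv.loc[enh, sim.STRAIN_B], cfg)
    tiers.to_csv(args.out / "tiers.tsv", sep="\t", index=False)

    by_id = {iv.id: iv for iv in ds.intervals}
    groups = {"similar": [by_id[e] for e in
                          tiers.loc[tiers["similar"], "element_id"]]}
    for t in cfg.differential_tiers:
        groups[f">{t:g}"] = [by_id[e] for e in
                             tiers.loc[tiers[f"tier_gt_{t:g}"], "element_id"]]
    fractions = st.variant_overlap_fraction(groups, ds.variants, cfg)
    table = pd.DataFrame([{"group": k, "n": len(groups[k]),
                           "variant_fraction": v}
                          for k, v in fractions.items()])
    table.to_csv(args.out / "variant_fractions.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
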