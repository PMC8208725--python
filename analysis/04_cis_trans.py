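#!/usr/bin/env python
"""Classify genes as cis / trans from parental and F1 hybrid allelic ratios.

Writes results/cis_trans.tsv and reports recovery of the planted labels.
"""

import argparse
from pathlib import Path

from strainwise import pipeline as pl
from strainwise import simulate as sim
from strainwise.config import load_config

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    cfg = load_config()
    ds = sim.read_dataset(args.data)

    out = pl.cis_trans_table(ds.expression, ds.f1_counts, cfg)
    out.to_csv(args.out / "cis_trans.tsv", sep="\t", index=False)
    print("labels:", out["label"].value_counts().to_dict())

    truth = ds.truth_genes.set_index("gene_id")["regulation"]
    called = out.set_index("gene_id")["label"]
    for cls in ("cis", "trans"):
        genes = truth[truth == cls].index
        if len(genes):
            rate = sum(called.get(g) == cls for g in genes) / len(genes)
            print(f"planted {cls} genes recovered: {rate:.1%} of {len(genes)}")


if __name__ == "__main__":
    main()
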