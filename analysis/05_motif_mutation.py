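#!/usr/bin/env python
"""Motif-mutation association on strain-differential elements.

Scores the packaged motifs plus random decoys on homologous sequence pairs
(responsive strain = positive) and writes results/motif_results.tsv and
results/motif_clusters.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from strainwise import motifs as mo
from strainwise import pipeline as pl
from strainwise import simulate as sim
from strainwise.config import load_config

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()
    cfg = load_config()
    ds = sim.read_dataset(args.data)

    diff = pl.differential_element_ids(ds.signals, cfg)
    shift = sim.make_liftover(ds.variants)
    by_id = {iv.id: iv for iv in ds.intervals}
    ga, gb = ds.genomes[sim.STRAIN_A], ds.genomes[sim.STRAIN_B]
    pairs = [mo.SequencePair(e, ga[by_id[e].start:by_id[e].end],
                             gb[shift(by_id[e].start):shift(by_id[e].end)])
             for e in diff if e in by_id and e.startswith("el")]
    print(f"{len(pairs)} strain-differential element pairs")

    params = sim.GeneratorParams()
    pwms = (sim.default_ldtf_pwms() + sim.default_sdtf_pwms()
            + sim.make_decoy_pwms(20, seed=args.seed + 1,
                                  avoid=sim.planted_instance_strings(params)))
    results = [mo.motif_mutation_test(pairs, pwm) for pwm in pwms]
    table = pd.DataFrame([{"motif": r.motif, "signed_logp": r.signed_logp,
                           "p": r.p, "n_nonzero": r.n_nonzero}
                          for r in results]).sort_values(
        "signed_logp", key=abs, ascending=False)
    table.to_csv(args.out / "motif_results.tsv", sep="\t", index=False)
    print(table.head(6).to_string(index=False))

    clusters = mo.cluster_motifs(results, cfg)
    pd.DataFrame([{"members": ",".join(c.members),
                   "mean_signed_logp": c.mean_signed_logp,
                   "representative": c.representative} for c in clusters]
                 ).to_csv(args.out / "motif_clusters.tsv", sep="\t",
                          index=False)
    print(f"{len(clusters)} motif clusters "
          f"(top: {clusters[0].representative} "
          f"{clusters[0].mean_signed_logp:+.1f})")


if __name__ == "__main__":
    main()
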