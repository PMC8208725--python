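#!/usr/bin/env python
"""Assemble the summary report from the tables under results/."""

import argparse
from pathlib import Path

from strainwise import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    path = pl.report(args.out)
    print(f"report written to {path}")


if __name__ == "__main__":
    main()
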