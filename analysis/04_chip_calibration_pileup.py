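#!/usr/bin/env python
"""Spike-in calibrated ChIP-seq: occupancy ratio and centromere pileup.

Thin driver over the packaged ``chip`` stage: simulates a two-genome
spike-in experiment, estimates the occupancy ratio from the four read
totals, calibrates the experimental coverage, and averages it around the
centromere midpoints (+/-3 kb at 50 bp bins).

Outputs: <out>/chip_pileup.csv
"""

import argparse

from mitoquant.pipeline_io import load_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/04_chip")
    args = ap.parse_args()
    cfg = load_config(overrides={
        "seed": args.seed,
        "out_dir": args.out,
        "stages": ["chip"],
        "chip": {"enrichment": 5.0, "total_reads": 1_000_000},
    })
    for path in run_pipeline(cfg):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
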