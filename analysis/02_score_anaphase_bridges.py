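#!/usr/bin/env python
"""Score synthetic anaphase cells for DAPI / nucleolar bridges.

Thin driver over the packaged ``bridges`` stage: simulates anaphase fields
with and without a chromatin bridge, computes the min-of-slab-maxima bridge
statistic between the two DNA masses, and classifies each cell against the
4000 a.u. (DAPI) / 5200 a.u. (Nop1) thresholds.

Outputs: <out>/bridges.csv
"""

import argparse

from mitoquant.pipeline_io import load_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/02_bridges")
    args = ap.parse_args()
    cfg = load_config(overrides={
        "seed": args.seed,
        "out_dir": args.out,
        "stages": ["bridges"],
        "bridges": {"n_scenes": 8},
    })
    for path in run_pipeline(cfg):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
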