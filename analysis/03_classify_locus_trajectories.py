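#!/usr/bin/env python
"""Classify GFP-dot separation trajectories into the three dynamic categories.

Thin driver over the packaged ``loci`` stage: simulates distance-versus-time
series for not_separated / breathing / separated cells and applies the
2 um separation threshold with the 0.25 um return-to-zero tolerance.

Outputs: <out>/loci.csv
"""

import argparse

from mitoquant.pipeline_io import load_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/03_loci")
    args = ap.parse_args()
    cfg = load_config(overrides={
        "seed": args.seed,
        "out_dir": args.out,
        "stages": ["loci"],
        "loci": {"n_cells_per_category": 20},
    })
    for path in run_pipeline(cfg):
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
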