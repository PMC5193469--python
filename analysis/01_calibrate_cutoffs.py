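"""Calibrate deletion/imbalance cutoffs on simulated control tissue.

Simulates five non-neoplastic brain control samples per probe pair
(pure diploid nuclei through the lossy detection model, 100 nuclei
each as in a manual count), applies the mean + 3 SD rule, and writes
the calibrated cutoff YAML.  With the default control noise model the
9p deletion cutoff lands near the published 30% and the 10q cutoff
near 25%.

Usage: python analysis/01_calibrate_cutoffs.py [--seed 1] [--out results/cutoffs.yaml]
"""

import argparse
from pathlib import Path

import numpy as np

from oligofish.caller import calibrate_cutoffs
from oligofish.chromosomes import CHROM_PAIRS
from oligofish.io import write_cutoffs
from oligofish.simulate import simulate_normal_controls


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cutoffs.yaml"))
    args = ap.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    summaries = {cid: simulate_normal_controls(cid, n_samples=5, n_nuclei=100,
                                               rng=rng)
                 for cid in CHROM_PAIRS}
    cutoffs = calibrate_cutoffs(summaries)
    write_cutoffs(cutoffs, args.out)
    print(f"mean+3SD cutoffs from 5 simulated controls (seed={args.seed}):")
    for cid, cut in cutoffs.per_chrom.items():
        print(f"  {cid}: deletion {cut.deletion_cutoff:.1f}%  "
              f"imbalance {cut.imbalance_cutoff:.1f}%")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
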