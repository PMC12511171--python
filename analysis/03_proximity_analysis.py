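#!/usr/bin/env python
"""Fixed-radius (30 μm) tumor–immune proximity analysis.

For every patient and region, counts the immune cells within 30 μm of each
tumor cell, bins the counts (1–4, 5–9, ≥10), and tabulates the fraction of
tumor cells per bin plus the un-normalized per-area density variant.
Prints the cohort-median core fractions next to the homogeneous-Poisson
null prediction at the cohort-median intensities: with no built-in
tumor–immune clustering the two agree, which is the generator's null
fidelity at work.
"""

import argparse
from pathlib import Path

from gliospatial.pipeline import PipelineConfig, run_proximity
from gliospatial.proximity import poisson_bin_probability

CORE_MEDIANS = {"IBA1": 512.0, "CD8": 14.0, "FOXP3": 1.7}
BINS = {"b1_4": (1, 4), "b5_9": (5, 9), "b10plus": (10, None)}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--radius", type=float, default=30.0)
    args = parser.parse_args()

    config = PipelineConfig(outdir=args.outdir, seed=args.seed)
    table = run_proximity(config)
    core = table.query("region_label == 'CORE'")
    print(f"tumor-core proximity fractions at r = {args.radius} μm "
          "(cohort median vs Poisson null at the median intensity):")
    for neighbor_class, intensity in CORE_MEDIANS.items():
        for label, bin_ in BINS.items():
            observed = core.query(
                "neighbor_class == @neighbor_class and bin_label == @label"
            )["fraction"].median()
            null = poisson_bin_probability(intensity, args.radius, bin_)
            print(f"  {neighbor_class:>6} {label:<8} observed {observed:8.4f}   null {null:8.4f}")


if __name__ == "__main__":
    main()
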