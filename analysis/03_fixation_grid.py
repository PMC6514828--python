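#!/usr/bin/env python
"""Wright–Fisher fixation-proportion grid under the founding-bottleneck
demography.

Evaluates the full 11,200-cell parameter grid (5 bottleneck sizes x 5
expanded sizes x 8 selection durations x 4 coefficients x 14 starting
frequencies, 100 replicates per cell) and writes results/fixation_grid.tsv
plus a summary of how fixation depends on selection strength and starting
frequency.  --quick runs a reduced grid for smoke-testing.
"""

import argparse
import time

from _inputs import RESULTS
from fadsevo.wf_sim import run_grid


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=100)
    parser.add_argument("--quick", action="store_true")
    args = parser.parse_args()

    kwargs = {}
    if args.quick:
        kwargs = dict(
            bottleneck_sizes=(100, 500),
            expanded_sizes=(2_000, 10_000),
            durations=(67, 534),
            p0_values=(0.3, 0.6, 0.95),
        )
    t0 = time.time()
    grid = run_grid(replicates=args.replicates, seed=args.seed, **kwargs)
    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / "fixation_grid.tsv"
    grid.to_tsv(out)
    print(f"{len(grid)} cells in {time.time() - t0:.0f}s -> {out}")

    t = grid.table
    summary = (
        t.groupby(["s", "p0"])["prop_fixed"].mean().unstack("p0").round(3)
    )
    summary.to_csv(RESULTS / "fixation_by_s_and_p0.tsv", sep="\t")
    print("\nmean fixation proportion by selection coefficient and p0:")
    print(summary.to_string())
    strongest = t[(t.bottleneck_size == t.bottleneck_size.min()) & (t.s > 0)]
    weakest = t[(t.bottleneck_size == t.bottleneck_size.max()) & (t.s > 0)]
    print(
        f"\nstrongest bottleneck mean fixation (s>0): "
        f"{strongest.prop_fixed.mean():.3f}; "
        f"weakest: {weakest.prop_fixed.mean():.3f}"
    )


if __name__ == "__main__":
    main()
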