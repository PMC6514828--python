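#!/usr/bin/env python
"""PBS selection scan of the focal gene region.

Runs the genome-background Z-score scan on the null panel (calibration
check) and on the sweep panel (power check), and reports the top window
site of each.  Writes results/pbs_scan_null.tsv and
results/pbs_scan_sweep.tsv.
"""

import argparse

import pandas as pd

from _inputs import RESULTS, ensure_inputs
from fadsevo.pbs_scan import pbs_scan
from fadsevo.util import PBS_SCAN_REGION


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    paths = ensure_inputs(args.seed)

    for label in ("null", "sweep"):
        panel = pd.read_csv(paths[f"panel_{label}"], sep="\t")
        res = pbs_scan(panel, PBS_SCAN_REGION, window=500_000)
        out = RESULTS / f"pbs_scan_{label}.tsv"
        res.to_csv(out, sep="\t", index=False)
        window = res[~res["Z"].isna()]
        top = window.loc[window["PBS"].idxmax()]
        n_sig = int((window["P_BONF"] < 0.05).sum())
        print(
            f"{label:5s}: {len(window)} window sites, {n_sig} significant "
            f"(Bonferroni p < 0.05); top site POS={int(top['POS'])} "
            f"PBS={top['PBS']:.3f} p={top['P_BONF']:.3g} -> {out}"
        )


if __name__ == "__main__":
    main()
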