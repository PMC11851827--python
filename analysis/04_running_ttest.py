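#!/usr/bin/env python
"""Sliding paired t-tests over 162 consecutive 2-ms epochs (−25..300 ms,
20-ms windows): the three pairwise emotion comparisons and the mouth
comparison.  Reports which time ranges reach each significance tier."""

import argparse
from pathlib import Path

from erpface import io
from erpface.erp import condition_average
from erpface.running import build_epoch_grid, running_paired_ttest


def _ranges(res, window_ms):
    sig = res[res["tier"] != "none"]
    if sig.empty:
        return "none"
    lo, hi = sig["epoch_start_ms"].min(), sig["epoch_start_ms"].max() + window_ms
    best = res["p"].min()
    return f"{len(sig)}/162 epochs in {lo:.0f}..{hi:.0f} ms (min p = {best:.2e})"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/clustered"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    clustered = io.read_internal(args.data)
    args.results.mkdir(parents=True, exist_ok=True)
    grid = build_epoch_grid((-25.0, 300.0), 2.0, 10, clustered[0].fs)
    window_ms = grid.window_samples * 1000.0 / clustered[0].fs

    by: dict = {}
    for factor in ("emotion", "mouth"):
        for epochs in clustered:
            for erp in condition_average(epochs, factor):
                by.setdefault(erp.condition, []).append(erp)

    comparisons = [
        ("fearful", "happy"),
        ("fearful", "neutral"),
        ("happy", "neutral"),
        ("open", "closed"),
    ]
    for a, b in comparisons:
        res = running_paired_ttest(by[(a,)], by[(b,)], grid)
        res.to_csv(
            args.results / f"running_{a}_vs_{b}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        print(f"{a:>7} vs {b:<7}: significant {_ranges(res, window_ms)}")


if __name__ == "__main__":
    main()
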