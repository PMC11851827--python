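#!/usr/bin/env python
"""Condition and grand-average ERP waveforms plus windowed peak tables.

Writes smoothed grand averages split by emotion and by mouth display,
and the per-participant P100 (max, 80–120 ms) and N170 (min, 100–200 ms)
amplitude/latency tables that feed the ANOVA stage."""

import argparse
from pathlib import Path

import pandas as pd

from erpface import io
from erpface.erp import (
    condition_average,
    grand_average,
    measure_peak,
    peak_table,
    smooth_moving_average,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/clustered"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    clustered = io.read_internal(args.data)
    args.results.mkdir(parents=True, exist_ok=True)
    times = clustered[0].times

    for factor in ("emotion", "mouth"):
        per_level: dict = {}
        for epochs in clustered:
            for erp in condition_average(epochs, factor):
                per_level.setdefault(erp.condition, []).append(erp)
        table = {"time_ms": times}
        for cond in sorted(per_level):
            g = grand_average(per_level[cond])
            table[cond[0]] = smooth_moving_average(g.waveform)
            for comp in ("P100", "N170"):
                pk = measure_peak(table[cond[0]], times, comp)
                print(
                    f"grand {factor}={cond[0]:<8} {comp}: "
                    f"{pk.amplitude:+6.2f} uV at {pk.latency:5.1f} ms "
                    f"(n={g.n_participants})"
                )
        pd.DataFrame(table).to_csv(
            args.results / f"grand_{factor}.tsv", sep="\t", index=False, float_format="%.6g"
        )

    for comp in ("P100", "N170"):
        tab = peak_table(clustered, comp)
        tab.to_csv(args.results / f"peaks_{comp.lower()}.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"wrote grand waveforms and peak tables to {args.results}/")


if __name__ == "__main__":
    main()
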