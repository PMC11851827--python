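#!/usr/bin/env python
"""Preprocess every participant: 3–45 Hz zero-phase band-pass with 60 and
120 Hz notches, whole-epoch demeaning, 150 μV peak-to-peak trial
rejection, and averaging of the occipitotemporal cluster into a single
virtual channel.  Writes cluster-averaged epochs to scratch/ and the
rejection log to results/."""

import argparse
from pathlib import Path

import pandas as pd

from erpface import io
from erpface.preprocess import PreprocessSettings, preprocess_participant


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/dataset"))
    ap.add_argument("--out", type=Path, default=Path("scratch/clustered"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--ptp-threshold", type=float, default=150.0)
    args = ap.parse_args()

    dataset = io.read_internal(args.data)
    settings = PreprocessSettings(ptp_threshold=args.ptp_threshold)
    clustered, logs = [], []
    for epochs in dataset:
        c, rlog = preprocess_participant(epochs, settings)
        clustered.append(c)
        logs.append(rlog.to_frame())
    io.export_dataset(clustered, args.out, format="internal")
    args.results.mkdir(parents=True, exist_ok=True)
    log = pd.concat(logs, ignore_index=True)
    log.to_csv(args.results / "rejection_log.tsv", sep="\t", index=False)
    kept = sum(c.n_trials for c in clustered)
    total = sum(d.n_trials for d in dataset)
    print(f"preprocessed {len(dataset)} participants: kept {kept}/{total} trials")
    print(f"rejected {len(log)} trials (log: {args.results / 'rejection_log.tsv'})")


if __name__ == "__main__":
    main()
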