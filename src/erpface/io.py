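"""Dataset I/O: internal epoch format and BrainVision triplets.

Internal format — one directory per participant holding:

* ``voltages.npy``: little-endian float32, trials × channels × samples, μV;
* ``metadata.tsv``: participant_id, trial_index, emotion, mouth, onset_sample;
* ``recording.json``: sampling rate, epoch window (ms), channel names.

BrainVision export lays each participant's epochs end to end into a
continuous multiplexed IEEE-float-32 recording (.eeg) with a text header
(.vhdr) and one stimulus marker per trial (.vmrk) encoding the 3 × 2 cell,
so the segmentation path can be exercised from files a standard EEG reader
(``mne.io.read_raw_brainvision``) understands.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EMOTIONS, META_COLUMNS, MOUTHS, ContinuousRecording, EpochSet

#: Stimulus-marker codes for the six design cells (S 1 … S 6).
CELL_CODES = {
    (emotion, mouth): i + 1
    for i, (emotion, mouth) in enumerate(
        (e, m) for e in EMOTIONS for m in MOUTHS
    )
}
CODE_CELLS = {v: k for k, v in CELL_CODES.items()}


# ---------------------------------------------------------------------------
# internal format
# ---------------------------------------------------------------------------

def _participant_dir(root: Path, participant_id: str) -> Path:
    return Path(root) / str(participant_id)


def write_internal(dataset: list[EpochSet], root: str | Path) -> list[Path]:
    """Write one directory per participant; returns the directories."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for epochs in dataset:
        d = _participant_dir(root, epochs.participant_id)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "voltages.npy", epochs.voltages.astype("<f4"))
        epochs.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
        sidecar = {
            "fs_hz": epochs.fs,
            "time_start_ms": float(epochs.times[0]),
            "n_samples": int(epochs.n_samples),
            "channels": list(epochs.channels),
        }
        (d / "recording.json").write_text(json.dumps(sidecar, indent=1))
        written.append(d)
    return written


def read_internal(root: str | Path) -> list[EpochSet]:
    """Read every participant directory under ``root`` (sorted by name)."""
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "voltages.npy").exists())
    if not dirs:
        raise FileNotFoundError(f"no participant directories under {root}")
    dataset = []
    for d in dirs:
        volts = np.load(d / "voltages.npy").astype(np.float64)
        meta = pd.read_csv(d / "metadata.tsv", sep="\t")
        sidecar = json.loads((d / "recording.json").read_text())
        times = sidecar["time_start_ms"] + np.arange(sidecar["n_samples"]) * 1000.0 / sidecar["fs_hz"]
        dataset.append(EpochSet(volts, times, sidecar["channels"], sidecar["fs_hz"], meta))
    return dataset


# ---------------------------------------------------------------------------
# BrainVision triplet writer (continuous, IEEE_FLOAT_32 multiplexed)
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """\
Brain Vision Data Exchange Header File Version 1.0
; Written by erpface

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """\
Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,0
{marker_lines}
"""


def write_brainvision(dataset: list[EpochSet], root: str | Path) -> list[Path]:
    """Write each participant as a continuous .vhdr/.eeg/.vmrk triplet.

    Epochs are concatenated back to back; each trial contributes one
    ``Stimulus, S <code>`` marker at its onset sample, where the code maps
    the (emotion, mouth) cell via :data:`CELL_CODES`.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for epochs in dataset:
        stem = str(epochs.participant_id)
        n_trials, n_ch, n_samp = epochs.voltages.shape
        # continuous data: channels × (trials·samples)
        cont = np.transpose(epochs.voltages, (0, 2, 1)).reshape(-1, n_ch)
        cont.astype("<f4").tofile(root / f"{stem}.eeg")

        channel_lines = "\n".join(
            f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(epochs.channels)
        )
        vhdr = _VHDR_TEMPLATE.format(
            stem=stem,
            n_channels=n_ch,
            sampling_interval_us=int(round(1e6 / epochs.fs)),
            channel_lines=channel_lines,
        )
        (root / f"{stem}.vhdr").write_text(vhdr, encoding="utf-8")

        onset_offset = epochs.time_index(0.0)
        marker_lines = []
        for i, row in epochs.metadata.iterrows():
            code = CELL_CODES[(row["emotion"], row["mouth"])]
            pos = i * n_samp + onset_offset + 1  # 1-based positions
            marker_lines.append(
                f"Mk{i + 2}=Stimulus,S{code:>3},{pos},1,0"
            )
        vmrk = _VMRK_TEMPLATE.format(stem=stem, marker_lines="\n".join(marker_lines))
        (root / f"{stem}.vmrk").write_text(vmrk, encoding="utf-8")
        written.append(root / f"{stem}.vhdr")
    return written


def read_brainvision(vhdr_path: str | Path) -> ContinuousRecording:
    """Read a BrainVision triplet into a :class:`ContinuousRecording` (μV)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    stim = {
        desc: code for desc, code in event_id.items() if desc.startswith("Stimulus")
    }
    rows, samples = [], []
    pid = Path(vhdr_path).stem
    for onset, _, code in events:
        desc = next((d for d, c in event_id.items() if c == code), "")
        if not desc.startswith("Stimulus"):
            continue
        cell_code = int(desc.split("S")[-1])
        emotion, mouth = CODE_CELLS[cell_code]
        samples.append(int(onset))
        rows.append((pid, len(rows), emotion, mouth, int(onset)))
    meta = pd.DataFrame(rows, columns=list(META_COLUMNS))
    return ContinuousRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        event_samples=np.asarray(samples, dtype=int),
        event_meta=meta,
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def export_dataset(dataset: list[EpochSet], path: str | Path, format: str = "internal") -> list[Path]:
    """Write a simulated dataset to disk; see module docstring for layouts."""
    if format == "internal":
        return write_internal(dataset, path)
    if format == "brainvision":
        return write_brainvision(dataset, path)
    raise ValueError(f"unknown export format {format!r}; use 'internal' or 'brainvision'")
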