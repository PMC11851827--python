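"""Condition ERPs, grand averages, 5-point smoothing and P100/N170 peaks.

Per participant, trials are averaged within each level of a factor
(emotion, mouth display, or the full 3 × 2 cell); grand averages then
weight every participant equally regardless of surviving trial counts.
Peak measures follow fixed search windows: the P100 amplitude is the
maximum voltage in 80–120 ms, the N170 amplitude the minimum voltage in
100–200 ms; latency is the time of that extremum, earliest sample on ties.
"""

from __future__ import annotations

import numpy as np

from .containers import ConditionERP, EpochSet, GrandERP, PeakMeasure

#: Component search windows in ms: (low, high, 'max'|'min').
PEAK_WINDOWS = {
    "P100": (80.0, 120.0, "max"),
    "N170": (100.0, 200.0, "min"),
}


def condition_average(epochs: EpochSet, factor: str = "emotion") -> list[ConditionERP]:
    """Average a participant's (cluster-averaged) trials per factor level.

    ``factor`` is ``'emotion'`` (3 levels), ``'mouth'`` (2) or ``'cell'``
    (the 6 emotion × mouth combinations).  Requires single-channel data.
    """
    if epochs.n_channels != 1:
        raise ValueError("condition_average expects cluster-averaged (single-channel) epochs")
    if factor == "cell":
        keys = ["emotion", "mouth"]
    elif factor in ("emotion", "mouth"):
        keys = [factor]
    else:
        raise ValueError(f"unknown factor {factor!r}")
    pid = str(epochs.metadata["participant_id"].iloc[0])
    out = []
    grouped = epochs.metadata.groupby(keys, sort=True, observed=True)
    for level, sub in grouped:
        idx = sub.index.to_numpy()
        if len(idx) == 0:
            raise ValueError(f"factor level {level!r} has no trials")
        wave = epochs.voltages[idx, 0, :].mean(axis=0)
        cond = level if isinstance(level, tuple) else (level,)
        out.append(ConditionERP(pid, tuple(cond), wave, epochs.times, len(idx)))
    from .containers import EMOTIONS, MOUTHS

    expected = {
        "emotion": {(e,) for e in EMOTIONS},
        "mouth": {(m,) for m in MOUTHS},
        "cell": {(e, m) for e in EMOTIONS for m in MOUTHS},
    }[factor]
    missing = sorted(expected - {e.condition for e in out})
    if missing:
        raise ValueError(f"factor {factor!r} level(s) with no trials: {missing}")
    return out


def grand_average(erps: list[ConditionERP]) -> GrandERP:
    """Unweighted across-participant mean of same-condition ERPs."""
    if not erps:
        raise ValueError("no ERPs to average")
    cond = erps[0].condition
    times = erps[0].times
    for e in erps[1:]:
        if e.condition != cond:
            raise ValueError(f"mixed condition keys: {cond!r} vs {e.condition!r}")
        if len(e.times) != len(times) or not np.allclose(e.times, times):
            raise ValueError("mismatched time grids across participants")
    wave = np.mean([e.waveform for e in erps], axis=0)
    return GrandERP(cond, wave, times.copy(), n_participants=len(erps))


def smooth_moving_average(waveform: np.ndarray, n_points: int = 5) -> np.ndarray:
    """Centered n-point moving mean (10 ms for 5 points at 500 Hz).

    Edges shrink the window symmetrically so output length equals input
    length and a constant waveform is preserved exactly.
    """
    if n_points % 2 == 0:
        raise ValueError("n_points must be odd")
    waveform = np.asarray(waveform, dtype=float)
    n = len(waveform)
    if n_points > n:
        raise ValueError("smoothing window longer than the waveform")
    half = n_points // 2
    out = np.empty(n)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = waveform[i - k : i + k + 1].mean()
    return out


def measure_peak(
    waveform: np.ndarray,
    times: np.ndarray,
    component: str,
    window: tuple[float, float] | None = None,
) -> PeakMeasure:
    """Windowed extremum of a waveform as a :class:`PeakMeasure`.

    Ties are broken by the earliest time point.  The window is closed on
    both ends and must lie inside the time vector.
    """
    if component not in PEAK_WINDOWS:
        raise ValueError(f"unknown component {component!r}; expected one of {list(PEAK_WINDOWS)}")
    lo, hi, kind = PEAK_WINDOWS[component]
    if window is not None:
        lo, hi = window
    times = np.asarray(times, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    if lo < times[0] or hi > times[-1]:
        raise ValueError(f"search window [{lo:g}, {hi:g}] ms outside the time vector")
    mask = (times >= lo) & (times <= hi)
    seg, seg_t = waveform[mask], times[mask]
    i = int(np.argmax(seg)) if kind == "max" else int(np.argmin(seg))  # argmax/argmin: first on ties
    return PeakMeasure(component, float(seg[i]), float(seg_t[i]), (lo, hi))


def peak_table(
    datasets: list[EpochSet],
    component: str,
    smoothed: bool = False,
    window: tuple[float, float] | None = None,
):
    """Per-participant × cell amplitude/latency table for one component.

    Returns a tidy DataFrame (participant, emotion, mouth, amplitude_uv,
    latency_ms) computed from each participant's cell-wise ERPs —
    unsmoothed by default, since the amplitude definition is the raw
    window extremum; set ``smoothed=True`` to measure on 5-point-smoothed
    waveforms instead.
    """
    import pandas as pd

    rows = []
    for epochs in datasets:
        for erp in condition_average(epochs, "cell"):
            wave = smooth_moving_average(erp.waveform) if smoothed else erp.waveform
            pk = measure_peak(wave, erp.times, component, window)
            emotion, mouth = erp.condition
            rows.append((erp.participant_id, emotion, mouth, pk.amplitude, pk.latency))
    return pd.DataFrame(
        rows, columns=["participant", "emotion", "mouth", "amplitude_uv", "latency_ms"]
    )
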