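"""Sliding-window ("running p-value") paired t-tests between conditions.

The waveform is reduced to a grid of short consecutive epochs — by
default 162 epochs of 2 ms from −25 ms to 300 ms, each summarising a
forward-looking window of 10 samples (20 ms at 500 Hz) by its mean.  For
each epoch, a two-sided paired t-test across participants compares the
two conditions' windowed means; p-values are classified into the display
tiers none / 0.05 / 0.01 / 0.001 (strict inequalities).

No multiple-comparison correction is applied: the procedure is a visual
screening tool and some epochs will reach significance by chance alone;
the result frame carries an advisory attribute saying so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import ConditionERP

ADVISORY = (
    "uncorrected sliding t-tests: with many epochs some will cross "
    "significance thresholds by chance alone"
)

TIER_NONE = "none"


@dataclass(frozen=True)
class EpochGrid:
    """Start times (ms) of consecutive analysis epochs plus window length.

    Windows start at each grid time and extend forward ``window_samples``
    consecutive samples; the first sample used is the first one at or
    after the start time.
    """

    starts: np.ndarray
    step: float
    window_samples: int
    interval: tuple[float, float]

    @property
    def n_epochs(self) -> int:
        return len(self.starts)


def build_epoch_grid(
    interval: tuple[float, float] = (-25.0, 300.0),
    step: float = 2.0,
    window_samples: int = 10,
    fs: float = 500.0,
) -> EpochGrid:
    """Epoch grid over ``interval`` (ms): count = floor(span / step).

    ``step`` must be an integer multiple of the sample period so that
    epoch starts advance on the sample grid.
    """
    period = 1000.0 / fs
    if step <= 0 or abs(step / period - round(step / period)) > 1e-9:
        raise ValueError(
            f"step {step:g} ms must be a positive integer multiple of the "
            f"sample period {period:g} ms"
        )
    span = interval[1] - interval[0]
    if span <= 0:
        raise ValueError("interval end must exceed interval start")
    n = int(np.floor(span / step + 1e-9))
    starts = interval[0] + step * np.arange(n)
    return EpochGrid(starts, float(step), int(window_samples), (float(interval[0]), float(interval[1])))


def windowed_means(waveform: np.ndarray, times: np.ndarray, grid: EpochGrid) -> np.ndarray:
    """Mean of ``window_samples`` consecutive samples from each grid start."""
    times = np.asarray(times, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    out = np.empty(grid.n_epochs)
    for j, start in enumerate(grid.starts):
        i0 = int(np.searchsorted(times, start - 1e-9))
        i1 = i0 + grid.window_samples
        if i0 < 0 or i1 > len(waveform):
            raise ValueError(
                f"epoch starting {start:g} ms needs samples beyond the available data"
            )
        out[j] = waveform[i0:i1].mean()
    return out


def classify_tiers(p: np.ndarray) -> np.ndarray:
    """Map p-values to display tiers with strict thresholds."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    tiers = np.full(p.shape, TIER_NONE, dtype=object)
    tiers[p < 0.05] = "0.05"
    tiers[p < 0.01] = "0.01"
    tiers[p < 0.001] = "0.001"
    return tiers


def running_paired_ttest(
    erps_a: list[ConditionERP],
    erps_b: list[ConditionERP],
    grid: EpochGrid,
) -> pd.DataFrame:
    """Per-epoch paired t-test (two-sided, df = n − 1) between conditions.

    ``erps_a`` and ``erps_b`` hold one ERP per participant, in matching
    participant order.  Returns a frame with columns ``epoch_start_ms``,
    ``mean_diff_uv``, ``t``, ``p``, ``tier``, ``degenerate`` (zero-variance
    differences get t = 0, p = 1 and a degenerate flag), plus ``n`` and an
    ``advisory`` attribute.
    """
    if len(erps_a) != len(erps_b) or len(erps_a) < 2:
        raise ValueError("need the same >= 2 participants in both condition lists")
    ids_a = [e.participant_id for e in erps_a]
    ids_b = [e.participant_id for e in erps_b]
    if ids_a != ids_b:
        raise ValueError(f"participant mismatch between conditions: {ids_a} vs {ids_b}")
    n = len(erps_a)
    means_a = np.stack([windowed_means(e.waveform, e.times, grid) for e in erps_a])
    means_b = np.stack([windowed_means(e.waveform, e.times, grid) for e in erps_b])
    diff = means_a - means_b
    md = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    # zero-variance differences (identical or constant-offset conditions):
    # tolerance absorbs float cancellation noise
    degenerate = sd <= 1e-10 * np.maximum(1.0, np.abs(md))
    t = np.zeros(grid.n_epochs)
    ok = ~degenerate
    t[ok] = md[ok] / (sd[ok] / np.sqrt(n))
    p = np.ones(grid.n_epochs)
    p[ok] = 2 * st.t.sf(np.abs(t[ok]), df=n - 1)
    result = pd.DataFrame(
        {
            "epoch_start_ms": grid.starts,
            "mean_diff_uv": md,
            "t": t,
            "p": p,
            "tier": classify_tiers(p),
            "degenerate": degenerate,
            "n": n,
        }
    )
    result.attrs["advisory"] = ADVISORY
    return result
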