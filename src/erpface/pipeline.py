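"""End-to-end orchestration: simulate → preprocess → ERP → statistics.

A run is fully determined by its :class:`RunConfig` (serialisable to
JSON) and writes, under the output directory:

* ``manifest.json`` — config, config hash, master seed;
* ``rejection_log.tsv`` — all participants' rejected trials;
* ``grand_<factor>.tsv`` — grand-average waveforms per condition;
* ``running_<a>_vs_<b>.tsv`` — sliding t-tests for the three emotion
  pairs and the mouth pair;
* ``peaks_<component>.tsv`` and ``anova_<component>.tsv`` — amplitude
  tables and ANOVA tables for P100 and N170;
* ``mc_result.json`` + ``mc_null_delays.tsv`` — Monte Carlo latency test.

The master seed fans out to named sub-streams (simulation, permutation)
so stages can be rerun in isolation; reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp, latency, preprocess, running
from .anova import fit_both_components
from .containers import EpochSet
from .synth import SimConfig, simulate_dataset

log = logging.getLogger("erpface")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: preprocess.PreprocessSettings = field(
        default_factory=preprocess.PreprocessSettings
    )
    grid_interval: tuple[float, float] = (-25.0, 300.0)
    grid_step: float = 2.0
    grid_window_samples: int = 10
    mc: latency.McConfig = field(default_factory=latency.McConfig)
    out_dir: str = "results/run"
    master_seed: int = 0

    def resolved(self) -> "RunConfig":
        """Fan the master seed out to the stage sub-streams."""
        ss = np.random.SeedSequence(self.master_seed).spawn(2)
        sim_seed = int(ss[0].generate_state(1)[0] % (2**31))
        mc_seed = int(ss[1].generate_state(1)[0] % (2**31))
        cfg = dataclasses.replace(self)
        cfg.sim = dataclasses.replace(self.sim, seed=sim_seed)
        cfg.mc = dataclasses.replace(self.mc, seed=mc_seed)
        return cfg

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _grand_frames(clustered: list[EpochSet], factor: str):
    """Grand-average table and the per-participant ERP lists for a factor."""
    per_level: dict = {}
    for epochs in clustered:
        for e in erp.condition_average(epochs, factor):
            per_level.setdefault(e.condition, []).append(e)
    times = clustered[0].times
    table = {"time_ms": times}
    for cond, erps in sorted(per_level.items()):
        g = erp.grand_average(erps)
        table["_".join(cond)] = erp.smooth_moving_average(g.waveform)
    return pd.DataFrame(table), per_level


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a summary dict (also persisted)."""
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": json.loads(cfg.to_json()),
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "master_seed": cfg.master_seed,
        "units": {"time": "ms relative to stimulus onset", "amplitude": "uV"},
    }
    stage = "simulate"
    try:
        dataset = simulate_dataset(cfg.sim)

        stage = "preprocess"
        clustered, logs = [], []
        for epochs in dataset:
            c, rlog = preprocess.preprocess_participant(epochs, cfg.preprocess)
            clustered.append(c)
            logs.append(rlog.to_frame())
        _write_tsv(pd.concat(logs, ignore_index=True), out / "rejection_log.tsv")

        stage = "erp"
        for factor in ("emotion", "mouth"):
            frame, _ = _grand_frames(clustered, factor)
            _write_tsv(frame, out / f"grand_{factor}.tsv")
        p100 = erp.peak_table(clustered, "P100")
        n170 = erp.peak_table(clustered, "N170")
        _write_tsv(p100, out / "peaks_p100.tsv")
        _write_tsv(n170, out / "peaks_n170.tsv")

        stage = "running_stats"
        grid = running.build_epoch_grid(
            cfg.grid_interval, cfg.grid_step, cfg.grid_window_samples, cfg.sim.fs
        )
        _, by_emotion = _grand_frames(clustered, "emotion")
        _, by_mouth = _grand_frames(clustered, "mouth")
        pairs = [(("fearful",), ("happy",)), (("fearful",), ("neutral",)), (("happy",), ("neutral",))]
        for a, b in pairs:
            res = running.running_paired_ttest(by_emotion[a], by_emotion[b], grid)
            _write_tsv(res, out / f"running_{a[0]}_vs_{b[0]}.tsv")
        res = running.running_paired_ttest(by_mouth[("open",)], by_mouth[("closed",)], grid)
        _write_tsv(res, out / "running_open_vs_closed.tsv")

        stage = "ranova"
        anova_p100, anova_n170 = fit_both_components(p100, n170)
        for name, tab in (("p100", anova_p100), ("n170", anova_n170)):
            tab.reset_index().to_csv(
                out / f"anova_{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )

        stage = "latency_mc"
        mc = latency.mc_null(clustered, cfg.mc)
        null = np.atleast_2d(mc.null_ms.T).T
        _write_tsv(
            pd.DataFrame(null, columns=[f"delay_ms_{i}" for i in range(null.shape[1])]),
            out / "mc_null_delays.tsv",
        )
        mc_summary = {
            "observed_ms": [float(x) for x in mc.observed_ms],
            "exceedance": [int(x) for x in mc.exceedance],
            "p": [float(x) for x in mc.p],
            "p_annotation": mc.p_annotation,
            "iterations": mc.iterations,
            "mode": mc.mode,
            "fallback_count": mc.fallback_count,
        }
        (out / "mc_result.json").write_text(json.dumps(mc_summary, indent=1))
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.exception("pipeline failed in stage %s", stage)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    summary = {
        "out_dir": str(out),
        "n_participants": len(dataset),
        "mc": mc_summary,
        "anova_n170_mouth_p": float(anova_n170.loc["Mouth", "p"]),
        "anova_p100_interaction_p": float(anova_p100.loc["Emotion:Mouth", "p"]),
    }
    return summary
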