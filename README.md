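# erpface

Event-related-potential (ERP) analysis of emotional-face processing, built
as a fully testable pipeline over synthetic EEG.

When people view faces, posterior EEG shows a stereotyped sequence of
stimulus-locked deflections: a positive **P100** (~100 ms, early visual
processing) and a negative **N170** (~170 ms over occipitotemporal sites,
face-sensitive structural encoding).  A recurring question is whether the
N170 responds to the *emotion* of a face or to low-level structural
features that co-vary with emotion — in particular an open mouth with
exposed teeth.  This package implements the complete analysis chain for a
3 (emotion: fearful / happy / neutral) × 2 (mouth: open / closed)
within-participant design with 42 participants and 288 balanced trials
each:

1. **Synthetic data** (`erpface.synth`) — Gaussian-windowed P100/N170/P2
   templates with configurable condition effects (open-mouth N170
   amplitude delta, fearful latency advance, P100 interaction delta),
   white + 1/f noise and participant heterogeneity, so every downstream
   estimate has a known ground truth.
2. **Preprocessing** (`erpface.preprocess`) — segmentation of continuous
   recordings into 2-s epochs (−0.5…+1.5 s at 500 Hz), zero-phase 3–45 Hz
   band-pass with 60/120 Hz notches, demeaning, automatic 150 μV
   peak-to-peak trial rejection, occipitotemporal cluster averaging.
3. **ERP measures** (`erpface.erp`) — per-participant condition averages,
   equal-weight grand averages, 5-point (10 ms) moving-average smoothing,
   and windowed peaks: P100 = max in 80–120 ms, N170 = min in 100–200 ms.
4. **Running t-tests** (`erpface.running`) — paired t-tests across
   participants on 20-ms windowed means over 162 consecutive 2-ms epochs
   from −25 to 300 ms, with significance tiers p < .05 / .01 / .001
   (uncorrected, as a temporal screening display).
5. **Repeated-measures ANOVA** (`erpface.anova`) — the classical
   seven-source within-subject 3 × 2 decomposition; each fixed effect `A`
   is tested as `F = MS_A / MS_{Participant×A}`, with η² reported both as
   `SS_A / ΣSS` (all seven rows) and as partial
   `SS_A / (SS_A + SS_error)`.
6. **Monte Carlo latency test** (`erpface.latency`) — the permutation
   test for the N170 latency delay of the fearful condition: trials are
   relabelled into three equal pseudo-conditions; each grand average
   gets a *band-refined mean-time latency* (mean time of the samples
   between the N170 minimum and 200 ms whose amplitude lies in −3…+1 μV);
   the null distribution of
   `Δ = mean(lat_happy, lat_neutral) − lat_fearful` over 10,000
   relabelings yields an inclusive exceedance p-value for the observed Δ.

I/O covers an internal epoch format (float32 array + TSV metadata + JSON
sidecar) and BrainVision `.vhdr/.eeg/.vmrk` triplets (written natively,
read through `mne`).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (large intermediates go to `scratch/`, tables to `results/`):

```bash
python analysis/01_simulate.py        # 42 participants × 288 trials
python analysis/02_preprocess.py
python analysis/03_erp_waveforms.py
python analysis/04_running_ttest.py
python analysis/05_ranova.py
python analysis/06_latency_mc.py
```

With the default generator effects (0.4 μV open-mouth N170 delta, −2 ms
fearful latency advance, 0.25 μV P100 interaction), stage 05 prints:

```
P100 amplitude ANOVA:
  Emotion       df= 2  SS=   0.181  F=  1.173  p=0.3147  eta2=0.0002
  Mouth         df= 1  SS=   0.242  F=  3.038  p=0.0888  eta2=0.0003
  Emotion:Mouth df= 2  SS=   0.548  F=  3.786  p=0.0268  eta2=0.0006

N170 amplitude ANOVA:
  Emotion       df= 2  SS=   0.110  F=  0.679  p=0.5100  eta2=0.0001
  Mouth         df= 1  SS=   5.294  F=105.442  p=0.0000  eta2=0.0036
  Emotion:Mouth df= 2  SS=   0.116  F=  0.933  p=0.3976  eta2=0.0001
```

i.e. exactly the qualitative fingerprint the design encodes: the N170
amplitude is driven by mouth display (highly significant yet with a tiny
total-SS η², because between-participant variance dominates the SS
total), emotion does not modulate amplitudes, and the P100 shows a small
emotion × mouth interaction.  Stage 06 prints:

```
observed delay +2.00 ms; 0/10000 null draws >= observed; p = 0.0000 (< 1/iterations)
```

the injected one-sample (2 ms) fearful latency advance recovered exactly,
far outside the permutation null.

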