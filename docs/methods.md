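# Methods

This note documents the models, conventions and numerical choices behind
`erpface`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where genuinely open choices were resolved.

## Synthetic ERP model

Each trial of the generator is

```
x(t) = Σ_c  s_c · (A_c + δ_cond + u_p) · exp(−(t − μ_c − Δ_cond − j)² / 2σ_c²)  +  ε(t)
```

a sum of Gaussian-windowed deflections plus noise.  The default component
set is the standard posterior visual sequence:

| component | polarity `s` | latency `μ` | amplitude `A` | width `σ` |
|---|---|---|---|---|
| P100 | +1 | 100 ms | 4 μV | 12 ms |
| N170 | −1 | 170 ms | 6 μV | 15 ms |
| P2   | +1 | 230 ms | 4 μV | 25 ms |

The P2 is not analysed, but it is load-bearing for the latency test: it
pulls the waveform up through the −3…+1 μV refinement band before the
fixed 200-ms segment end.  Without a post-N170 positive deflection the
refined segment would always terminate at the 200-ms cap, the mean-time
latency would not be shift-equivariant, and a pure latency shift could
not be recovered even at zero noise.  Gaussian shapes were chosen for
their closed-form peak values, which make exactness tests possible.

Condition effects (`EffectSpec`):

* `n170_open_mouth_amp_delta` (default **0.4 μV**) — extra N170 magnitude
  on open-mouth trials.  The default is sized so that, against the
  default noise, the Mouth main effect at n = 42 is highly significant
  while its total-SS η² stays in the same tiny range as published tables
  of this design (~0.003): a deliberately "small but robust" effect.
* `fearful_latency_shift` (default **−2 ms**, one sample at 500 Hz) —
  signed shift of *all* component latencies on fearful trials.
* `p100_interaction_delta` (default **0.25 μV**) — extra P100 amplitude
  on fearful × open-mouth trials; a simple interaction pattern (it also
  induces small main effects, as any single-cell bump does).

Noise has three parts, all additive: per-sample white noise (default
**10 μV** per channel), spectrally shaped 1/f ("pink") noise normalised
to unit per-sample variance before scaling (default **5 μV**), and a
per-participant amplitude offset applied to every component magnitude
(SD **2 μV**).  Channels of the simulated cluster share the template and
receive independent noise, so an 8-channel cluster average has
`√(10² + 5²)/√8 ≈ 4 μV` per-sample noise; a 48-trial cell ERP then has
~0.6 μV — the regime in which published participant-level amplitude error
terms of this design live.  Trial-to-trial latency jitter exists
(`latency_jitter_sd`) but defaults to 0 so latency-recovery tests are
exact on the sample grid.

Determinism: one master seed; participant `i` draws from
`default_rng([seed, i])`, so any subset of participants reproduces
bit-identically.

What the generator does **not** model: ocular/muscle artifacts, channel
covariance, drifting baselines, latency variability between participants,
or any stimulus-level structure beyond the 3 × 2 metadata.  Passing tests
therefore demonstrate correctness of the *analysis machinery* and
recoverability of injected effects — not robustness to every pathology of
real EEG.

## Preprocessing

* Epochs: −0.5…+1.5 s around onset at 500 Hz (1000 samples); t = 0 at
  stimulus onset; times reported in ms; sample indices 0-based; windows
  closed on both ends.
* Band-pass: 4th-order Butterworth, 3–45 Hz, applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase — symmetric deflections keep their
  argmin/argmax exactly, which the tests assert.
* Notches: zero-phase IIR notch at 60 and 120 Hz, 2 Hz bandwidth, by
  default; `notch_method="dft"` instead subtracts the least-squares
  sine+cosine fit over the whole epoch, removing a stationary line
  component exactly.  Filter contracts are verified on the composite
  magnitude response (≥40 dB at the notches, unity ±10 % at 10 Hz) and
  empirically on the steady-state central portion of a 2-s epoch, where
  forward–backward edge transients have died out.
* Demeaning: whole-epoch per-trial, per-channel mean subtraction
  (a pre-stimulus baseline window is available via
  `demean_mode="baseline"`; whole-epoch is the default because the
  amplitude measures sit on a 3-Hz high-passed signal where the choice is
  nearly immaterial).
* Trial rejection is an automatic peak-to-peak criterion (default
  150 μV on any channel) rather than manual inspection: reproducible,
  loggable, testable.  The log is emitted even when empty.
* Cluster: unweighted mean over {P7, P8, PO7, PO8, O1, O2, P5, P6} (a
  conventional occipitotemporal set; configurable).

## Statistical procedures

**Running t-tests.**  Windows start at each grid time and extend forward
10 samples (20 ms); starts advance in 2-ms steps over −25…300 ms, giving
`floor(325/2) = 162` epochs.  Start-aligned (rather than centered)
windows are a documented convention; data beyond 300 ms exist in the
2-s epoch, so end windows are fully populated.  Tests are two-sided
paired t (df = n−1).  Zero-variance difference vectors (identical or
constant-offset conditions) get t = 0, p = 1 and a `degenerate` flag; the
detection tolerance `sd ≤ 1e−10·max(1, |mean|)` absorbs float
cancellation.  No multiple-comparison correction is applied — the
procedure is a display/screening tool and the result carries an advisory
attribute saying exactly that.

**rANOVA.**  Classical seven-source decomposition for the fully
within-subject 3 × 2 design; each fixed effect is tested against its
participant-interaction mean square.  No sphericity correction by default
(Greenhouse–Geisser ε is available for the 3-level factor).  Two η²
variants are reported because published tables of this design sometimes
label `SS_effect / ΣSS(all rows)` as "partial η²": `eta2` (total-SS
denominator, the table-matching default) and `eta2_partial`
(`SS_effect/(SS_effect+SS_error)`).  The discrepancy is surfaced, not
silently resolved.  Degenerate 0/0 cases (zero effect variance) define
F = 0.  Correctness is pinned by two independent routes: a brute-force
loop decomposition and `statsmodels` `AnovaRM`.

**Monte Carlo latency test.**  The latency value of a grand waveform is
computed as: N170 peak = argmin in 100–200 ms (earliest on ties); segment
= peak → 200 ms; retain samples with amplitude in −3…+1 μV (endpoints
inclusive; retained samples need not be contiguous); latency = mean of
the retained samples' *time* coordinates — the only reading of
"averaging the refined segments" that yields a time rather than a
voltage.  An amplitude-weighted mean time is available behind
`time_weighting="amplitude"`.  The delay statistic defaults to
`mean(lat_happy, lat_neutral) − lat_fearful` (averaged mode); a pairwise
mode returns `(lat_happy − lat_fearful, lat_neutral − lat_fearful)` with
one exceedance count each, because per-comparison counts are sometimes
reported even when the procedure defines a single averaged delay.
Exceedance is one-sided and inclusive (null ≥ observed); zero exceedance
is annotated "< 1/iterations" rather than presented as p = 0 evidence.
Empty refined segments raise in strict mode; in pipeline mode
(`strict=False`) the peak time is used and counted in `fallback_count`,
so long permutation runs do not abort.  Grand averages inside the loop
reuse the same 5-point smoothing as the real-data path.  For throughput
the loop crops trials to the analysis window (up to `segment_end` plus a
smoothing margin) and works in float32; latency arithmetic is float64.

A subtlety worth knowing: amplitude effects leak into the latency
measure.  A condition-specific amplitude change (e.g. the P100
interaction delta), after 3-Hz high-pass filtering, shifts the waveform
near the band edges by ~0.01 μV, which can flip one knife-edge sample in
or out of the refined segment and move the mean-time latency by ~1 ms.
This is a property of the band-refinement method itself, not of the
implementation; latency-recovery checks therefore inject the latency
shift in isolation.

## Problem sizes

Defaults mirror the study design (42 participants × 288 trials × 2-s
epochs at 500 Hz; 10,000 Monte Carlo iterations in the analysis driver).
Tests and the acceptance script use the package's own smaller-but-
sufficient sizes: 2-channel clusters where channel count is immaterial
(all statistics act on the cluster average), 2,000 Monte Carlo iterations
for the power check, 50 replicates × 200 iterations for null
calibration, and reduced participant/trial counts in property tests.
These are stated choices, and every number printed in the README was
produced by the code at the sizes shown there.

## Known limitations

* The generator's identical-template channels make cluster averaging a
  pure noise reducer; real clusters mix heterogeneous topographies.
* The null calibration of the Monte Carlo p-value assumes exchangeable
  trials within participant; slow nonstationarities (drift) would break
  this in real data.
* Peak-based amplitude measures are biased outward by noise (extremum of
  a noisy curve); the bias is condition-symmetric here and cancels in
  the paired contrasts, but absolute amplitudes should not be
  over-interpreted.
* The band-refinement latency measure is only shift-equivariant while
  both band crossings are interior to [peak, 200 ms]; waveforms that sit
  inside the band at the segment end lose part of the shift (see above).
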