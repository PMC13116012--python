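# Methods

This package implements a time-resolved decoding analysis for
trial-structured intracranial recordings: from raw multichannel signals to
per-region decoding curves with dual permutation validation, and
cross-temporal R² coupling maps with cluster-level significance. Because the
clinical recordings the design is modeled on are not publicly deposited, a
synthetic-data module with known planted ground truth stands in for them, so
every stage is testable end to end.

## 1. Synthetic data model (`synthgen`)

Each channel of each trial is generated as

```
x(t) = pink(t) + Σ_f A_f sin(2π f t + φ) + G(t) · carrier(t)
```

- **Background**: 1/f^β noise (β = 1 by default), synthesized by shaping
  white Gaussian noise in the frequency domain, plus line-noise sinusoids at
  60/120/180 Hz with random phase per trial and channel.
- **Carrier**: a constant-envelope frequency-modulated tone confined to the
  high-gamma band (70–170 Hz). Center frequencies are drawn per trial and
  channel from two anchors at 30% and 70% of the band (100 and 140 Hz for
  the default band) with a slowly varying ±10 Hz deviation. The anchors are
  deliberately kept away from (a) the band edges, where the extraction
  filter's roll-off would modulate the measured envelope, and (b) the 120 Hz
  line harmonic, where the preprocessing notch would carve trial-dependent
  notches into the envelope. Because the carrier has constant unit envelope,
  the gain profile `G` *is* the band envelope, which makes planted effect
  sizes exactly calibratable.
- **Gain field**: `G` is piecewise constant on a grid of eleven 50 ms
  segments covering 0–550 ms (a 100 ms analysis window spans two segments).
  Per segment, `G = g₀ + s + c`, where `g₀ = 2` is the base gain,
  `s ~ N(0, 0.15²)` is shared by all channels of an area (per trial), and
  `c ~ N(0, 0.25²)` is channel-private. The area-shared/channel-private
  split lets group-level decoding benefit from channel pooling while
  region-level couplings remain well defined on area means.

**Planted category effects.** A `PlantedEffect` with Cohen's d adds
`±δ/2` to the shared gain of its area in the segments overlapping its time
window, with sign by category. Since a window is the mean of two independent
segments, the per-channel window-mean gain SD is
`σ_w = sqrt((0.15² + 0.25²)/2)`, and `δ = d · σ_w` realizes the requested d
exactly at the gain level. Verified by an independent envelope oracle
(rectification + low-pass on the carrier-only signal): planted d = 2.0 is
recovered as 1.8–2.1 across seeds.

**Planted couplings.** A `PlantedCoupling` adds `a·z` to the source area's
gain in its source window and `a·z` to the target area's gain in its target
window, with a shared per-trial latent `z ~ N(0,1)`. The weight solves
`ρ = a²/(a² + v)` for the target correlation `ρ = sqrt(target_r2)`, where
`v` is the variance of the area-mean window gain,
`v = (s_sh² + s_ch²/n_ch)/2 + m/n_ch`. The term `m` (config field
`envelope_meas_var`, default 0.030) is a simulation-calibrated allowance for
envelope-extraction measurement noise: without it the R² measured from
extracted envelopes undershoots the target (≈0.34 for a target of 0.5 in
the reference configuration), while fully compensating the measured noise
(≈0.044) pushes the gain-level R² above its tolerance. The default splits
the residual so both the gain-level and the extracted-envelope R² lie
within ±0.12 of the target.

**Artifacts.** Channels receive high impedance (> 10 kΩ) with configurable
probability. Interictal-discharge-like transients (smoothed biphasic pulses
scaled to a channel's robust background) can be injected at a configurable
rate or explicitly via `inject_ied`, with ground truth recorded.

**Speech onsets** are drawn from a normal distribution (mean 881 ms,
SD 228 ms) truncated below at 500 ms.

All randomness derives from a single seed through `numpy.random.SeedSequence`
fan-out, so datasets are exactly reproducible.

## 2. Preprocessing (`preprocess`)

Fixed order, per subject:

1. **Common average reference** over the subject's good channels.
2. **Notch filtering** at 60/120/180 Hz (zero-phase IIR, Q = 35).
3. **Channel exclusion**: impedance strictly above 10 kΩ, or marked bad.
4. **IED trial rejection**: a trial is flagged when any channel's rectified,
   8 ms-smoothed signal exceeds 2× the channel's robust background
   (1.4826 × MAD over all trials' −300..0 ms baselines) for a contiguous
   20–200 ms run (gaps ≤ 2 ms bridged). The 8 ms smoothing (about one
   high-gamma cycle) prevents the oscillatory carrier's zero crossings from
   fragmenting genuine excursions, and slow background excursions from
   chaining isolated peaks into spurious runs. Flags are kept per
   (subject, word); flagged trials are masked downstream, never deleted.
5. **Envelope extraction**: 4th-order Butterworth band-pass 70–170 Hz
   (zero-phase) followed by Hilbert analytic magnitude. A Morlet wavelet
   filterbank (16 centers, 7 cycles, 1/f-weighted and normalized to unit
   response at band center) is available as an alternative; both satisfy
   the unit-tone contract (unit 100 Hz tone → envelope 1.0 ± 0.05).
6. **Baseline normalization**: each channel's envelope is z-scored against
   the pooled −300..0 ms baselines of its non-rejected trials (a per-trial
   variant is available).

## 3. Features and channel selection (`features`)

The envelope is averaged in ten 100 ms windows stepped by 50 ms covering
0–500 ms onset-to-onset (window k spans [50(k−1), 50(k−1)+100) ms and is
labeled by its center, 50k ms). Trials are split 70/30 per category
(selection share `ceil(0.7·n_c)`) with a seeded draw; channel selection sees
only the selection split. Each channel is scored independently by
stratified 5-fold cross-validation of a linear max-margin classifier on its
10 window features and retained iff mean accuracy exceeds 0.50 strictly.

## 4. Group decoding (`decode`)

Retained channels are concatenated per (hemisphere, Brodmann area) across
subjects; rows are words not rejected for any contributing subject (all
words by default; an `evaluation`-only policy is available). Decoding is
stratified 5-fold cross-validation per window with per-fold
standardization fitted on training rows. The default classifier is a linear
SVM (C = 1, hinge loss) implemented as a numba-compiled dual coordinate
descent solver — permutation testing re-fits the full 10-window × 5-fold
grid thousands of times per area, which is two orders of magnitude too slow
with a general-purpose library solver. The solver's predictions agree with
scikit-learn's `LinearSVC(loss="hinge")` (verified in tests). LDA and
random-forest alternatives run through scikit-learn, with a signed-rank
comparison utility.

## 5. Permutation statistics (`permstats`)

Two independent nulls per area:

- **Label-shuffle null** (default 2000 draws): labels are permuted, folds
  re-stratified, and the full decoding curve recomputed. Per-window
  empirical p-values use the add-one (Phipson–Smyth) estimator and are
  Benjamini–Hochberg corrected across the 10 windows, both tails.
- **Time-shuffle threshold** (default 1000 draws): window indices are
  permuted independently per trial and the curve recomputed; the 95th
  percentile of the pooled null accuracies gives an upper (and 5th a lower)
  threshold. Permuting per trial, rather than applying one permutation to
  all trials, is deliberate: a common permutation merely reorders the
  observed curve, making the pooled null identical to the observed
  accuracy multiset and the threshold test vacuous.

A window is significant only if it passes both criteria. Peaks (and
troughs) are the extreme accuracy among significant windows, earliest
window on ties.

## 6. Cross-temporal coupling (`xtcoupling`)

For a source and target region (channel-averaged features, same word set),
cell (i, j) of the 10×10 grid is the squared Pearson correlation between
the source's window-i and the target's window-j values across trials. The
null permutes trial correspondence (preserving both margins); add-one
p-values are BH-corrected across the 100 cells. Clusters are found by
seed-and-grow: seeds need q ≤ 0.05 and R² ≥ 0.20, growth requires q ≤ 0.05
and R² ≥ 0.10, 8-connectivity, minimum 5 cells; overlapping grown sets
merge, and clusters are ranked by peak R². Note that a lone strong cell
cannot survive BH across 100 cells at practical permutation counts
(minimum attainable p is 1/(B+1) > 0.05/100 for B ≤ 2000); detectable
couplings are blobs, which the overlapping-window design produces
naturally. Region peaks at ≤ 250 ms are tagged "early", later ones "late".

## 7. Pipeline and CLI (`pipeline`, `cli`)

`run_pipeline` executes synth-or-load → preprocess → features → selection →
per-area decoding and significance → coupling maps, writing CSV tables
(curves, significance, peak summary, coupling cells, aligned traces), a
cluster JSON, and a manifest (config hash, stage seeds, exclusion counts).
Stage seeds are spawned from the global seed via `SeedSequence`, so runs
are exactly reproducible; per-area failures are logged and recorded as
`failed`/`skipped` status rows without aborting other areas. The
`prespeech` CLI exposes `synth`, `preprocess`, `features`, `decode`,
`stats`, `xtreg`, and `run-all`, with YAML/JSON configs and a `--perms`
override for desk-scale runs.

## Limitations

- The synthetic carrier is a narrowband FM tone rather than broadband
  high-gamma; common-average referencing therefore bleeds a slow-beating
  fraction of other channels' carriers into each channel, attenuating
  pipeline-measured effect sizes to roughly 0.6× the planted d. The planted
  quantities remain exact at the carrier/gain level, which is what the
  generator guarantees and the oracles verify.
- Effects and couplings act on area-shared gain only; channel-heterogeneous
  effect topographies are not modeled.
- The trial-correspondence coupling null assumes exchangeable trials; slow
  session drifts that would violate exchangeability are not simulated.
- Window timing is fixed to the 10-window, 100/50 ms grid; other grids are
  configurable but the planted-effect calibration assumes the 50 ms segment
  alignment.
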