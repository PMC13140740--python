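# Methods

`respstart` analyses how the respiratory cycle modulates reaction times in
a StartReact experiment: visual imperative cues (VRT), cues with a quiet
sound (VART) and cues with a startling sound (VSRT), recorded with surface
EMG from three arm muscles (first dorsal interosseous, 1DI; flexor
digitorum superficialis, FDS; biceps, BIC) alongside a breathing
temperature signal. This note documents the models, the defaults and the
numerical choices, and what the synthetic-data tests do and do not show.

## Respiratory phases

The breathing trace falls during inspiration and rises during expiration,
so inspiration onsets are local maxima and expiration onsets local minima.
Each cycle is divided into six equidistant phases: the inspiration
interval [inspiration onset, expiration onset) into thirds I1, I2, I3
(x = 1..3) and the expiration interval into E1, E2, E3 (x = 4..6). Bins
are half-open with a boundary belonging to the bin that starts there, so
the inspiration onset itself is x = 1 and the expiration onset x = 4; a
cue falling outside every detected cycle gets no phase and the trial is
dropped and counted (reported in QC). Phase is always assigned at the cue
time, not the response time.

### Segmentation

Two stages:

1. **Detection.** Extrema of a moving-average-smoothed copy of the signal
   (window `smooth_window_s`, default 0.25 s, standing in for the analogue
   band-pass of an acquisition chain), kept only above a relative
   prominence threshold (25 % of the 5–95 percentile amplitude), forced to
   alternate, and merged when closer than `min_half_cycle_s` (default
   0.8 s; shorter half-cycles are physiologically implausible and usually
   noise). All thresholds are relative, so labels are invariant to offset
   and positive rescaling.
2. **Refinement.** Smoothed-extremum positions are biased by tens of
   milliseconds when inspiration and expiration durations differ (the
   moving average drags a maximum toward the flatter neighbouring branch).
   Each boundary is therefore re-estimated on the raw signal by
   least-squares fitting two raised-cosine arcs — one per adjacent
   half-cycle, each with free offset and amplitude — that meet at the
   boundary, via a two-pass coordinate descent (coarse grid 40 ms, fine
   grid 10 ms, parabolic interpolation of the error curve). The arc uses
   the steep mid-slope samples, where boundary sensitivity is highest, and
   localises onsets to a few milliseconds on synthetic data. The model is
   a smooth quasi-sinusoidal half-wave, adequate for thermistor-style
   breathing signals; highly non-sinusoidal breathing (plateaus, sighs)
   would reduce refinement accuracy, and refinement can be disabled.

## EMG onset detection

Reaction time is the latency from the cue to the first detectable rise of
rectified EMG above baseline, operationalised as the classic 3-SD rule: a
causal moving-average envelope (5 ms) of the rectified signal must exceed
baseline mean + 3 SD (baseline from the pre-cue window −0.2–0 s of the
same envelope) and stay above it for at least `min_supra_ms` (10 ms),
within an admissible latency window of 20–600 ms after the cue. Choices:

- The envelope exists because individual rectified-EMG samples dip below
  any threshold; averaging over 5 ms converts the variance step of a burst
  into a sustained level shift while delaying detection by well under a
  millisecond at the default signal-to-noise ratio.
- The sustained-crossing rule rejects isolated spikes.
- The latency window bounds physiological reaction times. The lower edge
  is 20 ms: with condition means down to ~126 ms and ~45 ms trial-to-trial
  spread, a higher floor would systematically mis-time the fastest genuine
  responses, while 20 ms still excludes pre-cue artefacts. Latencies are
  reported at sample resolution (0.2 ms at 5 kHz).
- A degenerate baseline (SD = 0) falls back to an infinitesimal threshold
  above the baseline mean, so noiseless step inputs are detected at the
  exact step sample.
- There is no manual verification step; instead a QC table (latency,
  peak/threshold ratio, detected flag per trial and muscle) is exported
  for review. The pipeline is fully automated and deterministic.

## Reaction-time statistics

Trials are pooled across participants for phase means and fits; the test
battery operates at the participant level where pairing matters.

- **Kolmogorov–Smirnov normality screen** on the standardised sample
  against the standard normal CDF (no Lilliefors correction) — this
  motivates the non-parametric battery.
- **Mann–Whitney U** for between-condition contrasts, computed on
  per-participant mean reaction times (n = number of participants per
  group): exact when the pooled sample is ≤ 20 without ties, otherwise the
  tie-corrected normal approximation without continuity correction (so
  identical samples give exactly p = 1). A paired alternative would suit
  the within-subject design; the unpaired form is retained as the default
  to match standard usage of this battery, and both views are reachable
  through the API.
- **One-sample Wilcoxon signed-rank** for the StartReact effect (VART −
  VSRT, positive = startle speeds the response) against zero: zeros
  dropped, exact for n ≤ 25 via the full sign-flip null computed by
  dynamic programming on doubled average ranks (exact also under tied
  magnitudes), tie-corrected normal approximation with continuity
  correction above. Thirteen same-sign effects give the extreme tail
  2/2¹³ ≈ 0.0002.
- **Friedman test** across the six phases on per-participant phase means,
  in the tie-corrected rank form (valid from two treatments); participants
  missing any phase cell are excluded and counted, never imputed.
- **Modulation strength** per participant and condition = SD of the six
  phase means; conditions compared with the paired signed-rank test.

## Two-harmonic phase modulation model

Phase-binned means are fitted with

T(x) = k + A₁ sin(ω(x−1) + θ₁) + A₂ sin(2ω(x−1) + θ₂), ω = 2π/6,

via the linear basis {1, sin ω(x−1), cos ω(x−1), sin 2ω(x−1), cos 2ω(x−1)},
which is orthogonal on the six equally spaced bins: the least-squares
solution is the closed-form discrete Fourier projection, unique, with
residual equal to the Nyquist (third-harmonic) energy of the input.
Amplitudes are reported non-negative with phase carrying orientation
(θ ∈ (−π, π], set to 0 when the amplitude is below 1e−12).

**Landmarks** are the fitted curve evaluated at fixed coordinates — the
inspiration→expiration boundary x = 3.5 (I3–E1), the expiration→
inspiration boundary x = 0.5 ≡ 6.5, mid-inspiration x = 2 and
mid-expiration x = 5 — not at free extrema of the fit. Fixed coordinates
make the landmark exchangeable under phase-label shuffling and avoid the
selection bias of extremum hunting.

**Modulation amplitude** is reported as half the peak-to-trough range of
the fitted curve over one period (0.001-resolution grid), with A₁ and A₂
alongside. A signed single-number amplitude is not well defined for a
two-harmonic curve, so no signed convention is offered.

## Shuffle null for landmarks

Significance of a landmark (of per-phase mean RT, or of the per-phase
StartReact effect) is assessed against B = 10 000 simulated datasets in
which reaction times are randomly re-paired with respiratory phases.
Shuffling is stratified within condition (hence within condition × muscle
for any single-muscle statistic): phase-label and reaction-time multisets
are preserved per stratum, so the null holds condition composition fixed
and targets phase structure alone. Pooling across participants inside a
stratum treats phase assignment as exchangeable between participants; the
output metadata records this choice. For each shuffle the six phase means
are recomputed, the mixture refitted (one matrix product, thanks to the
closed form) and the landmark extracted; the one-sided p-value is the
proportion of simulated values ≥ the observed one for peaks, ≤ it for
troughs — exactly count/B, with an optional (count+1)/(B+1) variant (off
by default) for users who want to avoid p = 0. Direction conventions:
StartReact-effect landmarks use peak at transitions / trough at
mid-phases; reaction-time landmarks use the reverse, since enhancement
means *shorter* RT.

## Transition-vs-mid contrasts

Two focused contrasts on per-participant StartReact effects (a participant
enters only with all four phase cells populated in both conditions;
exclusions are counted):

1. `transition_vs_mid_test` — unpaired Wilcoxon rank-sum (Mann–Whitney) on
   the pooled per-participant effects at the transition cells {I3, E1}
   against the pooled effects at the mid cells {I2, E2}.
2. `transition_ie_specific_test` — a within-participant version specific
   to the inspiration→expiration transition: one-sample signed-rank on the
   per-participant differences mean(I3, E1) − mean(I2, E2).

The two tests answer slightly different questions (population-level pooled
shift vs consistent within-participant enhancement); offering the pooled
test as the primary contrast and the paired test as the
transition-specific follow-up was a design choice where the analysis
battery left the pairing open.

## Synthetic data generator

The generator emulates the study's statistical structure with full ground
truth; defaults are fixed once:

| Parameter | Default | Basis |
|---|---|---|
| participants | 13 | typical cohort for this paradigm |
| schedule | 4 blocks × 3 conditions × 20 trials (240), ITI U(12.5, 15.7) s | standard StartReact protocol with unpredictable cue timing |
| breathing period | 4 s mean, jitter CV 0.1 | conventional adult eupnoea |
| inspiration fraction | 0.4 | inspiration is typically shorter than expiration |
| breathing sampling | 100 Hz, amplitude 1, additive noise SD 0.02 | artefact plumbing; noise 2 % of amplitude |
| RT baselines (ms) | VRT 280/254/223, VART 213/189/159, VSRT 162/151/126 (1DI/FDS/BIC) | study-scale condition means |
| RT phase modulation | first harmonic, trough at x = 3.5; amplitudes VSRT 14.4/9.3/8.6, VART 6.4/1.7/2.2, VRT 3.2/4.5/3.5 ms | study-scale modulation, strongest under startle |
| RT trial noise | SD 45 ms | study-scale trial-to-trial spread |
| EMG | 5 kHz, baseline noise SD 1, burst SD 10 (SNR 10), 150 ms rectangular burst at cue + RT | artefact plumbing |

The breathing waveform is built from piecewise-cosine half-cycles (falling
inspiration, rising expiration) so that inspiration fractions other than
0.5 are representable. Reaction times are baseline + T(x) with k = 0 +
Gaussian noise; non-positive draws are resampled (not truncated) so the
injected mean stays exact. EMG bursts are variance steps with a
rectangular envelope; ground-truth onset samples are recorded. One seed
drives everything: `SeedSequence(seed)` spawns a child per participant,
each spawning (schedule, breathing, RT, EMG) substreams in fixed order,
with the EMG substream spawning one grandchild per muscle.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: startle habituation across blocks,
non-stationary or non-sinusoidal breathing (plateaus, sighs, apnoea),
EMG onset shapes with gradual recruitment ramps, movement and electrode
artefacts, inter-muscle latency correlations beyond the shared phase
modulation, and any coupling between cue timing and breathing. Results on
synthetic data certify the machinery (estimator accuracy, calibration,
determinism), not robustness to messy physiology.

## Pipeline

`PipelineConfig` → `run()` executes simulate-or-load, segmentation, phase
labelling, onset detection, the full statistics battery, fits, landmark
nulls and contrasts, and writes `report.json` plus CSV tables. Every
random element derives from the configured seeds (dataset seed, analysis
seed split per statistic via `SeedSequence`), so a report is
byte-reproducible from its configuration; the report embeds the config and
its SHA-256. Units: seconds for signal time, milliseconds for latencies,
Hz for rates, 0-based sample indices.

Problem sizes used in the shipped test suite are scaled to keep the suite
quick while preserving the estimates' granularity: null calibration uses
200 datasets at B = 500 (binomial band [0.01, 0.10] around the nominal
0.05), enumeration cross-checks use ≤ 8 trials (8! relabellings), the
power check uses 50 replicate studies at the study's own size, and the
reproducibility check runs the full 13-participant pipeline twice at
B = 10 000.

## Known limitations

- Segmentation refinement assumes smooth quasi-sinusoidal half-waves;
  it is validated only on the generator's waveform family.
- The shuffle null pools trials across participants within a stratum;
  a within-participant shuffle variant is not implemented.
- The Mann–Whitney between-condition contrast ignores the within-subject
  design (by construction, to mirror the standard battery).
- No multiple-comparison correction anywhere (the battery reports raw
  p-values); no parametric ANOVA path; no effect sizes beyond ms
  differences.
- `modulation_amplitude` is one convention among several; comparisons with
  other analyses should compare A₁/A₂ directly.
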