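# Methods

This note documents the models, estimators and numerical choices behind
`spikesight`, and what the synthetic-data generator does and does not
emulate.

## Data model

A session holds sorted units (spike times in seconds, per-site average
waveforms), a trial table and, for opto-tagging sessions, light
pulse-train onsets. The task timeline per trial is: visual cue at trial
onset, an optional 10-ms whisker deflection 1 s later (stimulus trials
only), an auditory cue at 2 s, then a 1-s response window. Outcomes are
hit/miss (stimulus trials), CR/FA (no-stimulus trials) and early_lick;
early-lick trials were aborted during acquisition and are excluded from
every analysis by default. All analysis windows are half-open
`[start, end)` so a spike on a shared bin edge is counted exactly once,
and times serialize as decimal text at microsecond precision, which makes
save→load an exact inverse and pipeline output byte-reproducible.

## Unit classification

Each unit is assigned to the recording site whose average waveform has
the largest peak-to-trough amplitude (ties to the lowest site index).
Spike width is the time from the waveform trough (global minimum) to the
first return of the voltage to baseline. The baseline level is the mean
of the first 25 % of samples — the pre-trough reference segment — since
no numerical definition of "baseline level" is standard; the return
crossing is located by linear interpolation between the two bracketing
samples because the classification thresholds are only one–two samples
apart at 30 kHz. Units are FS below 0.26 ms, RS above 0.34 ms, and
excluded in between. Baseline rates are counted in a 2-s window before
the visual cue; log-normal fits are maximum-likelihood normal fits to
log-rate, with zero-rate units excluded from the fit and their count
reported.

## Statistics

Per-neuron modulation uses sign-flip permutation tests on per-trial
(response − baseline) rate differences; group contrasts use label-shuffle
tests on per-unit deltas. The statistic is the (difference of) mean(s).
When the permutation group is small (2ⁿ or C(n, n_a) ≤ n_perm, default
n_perm = 10,000) the null is enumerated exhaustively and the p-value is
exact; otherwise a Monte Carlo sample is drawn and the add-one estimator
(1 + hits)/(1 + draws) keeps p strictly positive. Modulation direction is
assigned from one-sided tests at the configured per-direction level
(0.025 for the broad population summaries, 0.005 for the area-specific
window analyses); both thresholds live in `WindowConfig`. Counts of
modulated units are compared with a 2×2 chi-squared test of equal
proportions *with Yates continuity correction* — the worked example
(3/1,077 vs 17/1,066 → p = 0.0032) is reproduced only with the
correction; the uncorrected test gives ≈ 0.0015. Multiple comparisons use
Benjamini–Hochberg step-up adjustment (via statsmodels).

## PSTHs, evoked responses, latency

PSTHs use 1-ms non-overlapping bins, rate = counts/(n_trials·bin_width),
convolved with a unit-area Gaussian truncated at ±4σ and renormalized;
boundaries are handled by reflective padding, which conserves interior
spike mass to machine precision. Window-based evoked responses are
per-trial rate differences between an area-specific response window and a
mirrored pre-event baseline; the default window table is: wS1/wS2 fast
0–50 ms, all-area early 0–100 ms, wM1/wM2 10–90 ms, tjM1 40–90 ms, ALM
delay 200–1,000 ms, wS1/wS2 late 150–350 ms (all post-whisker,
configurable).

Latency is computed on the baseline-subtracted smoothed PSTH for units
that pass a responsiveness screen (window vs equal pre-stimulus window,
two-sided sign-flip test, α = 0.05): the first bin center at which the
trace reaches half its in-window maximum (half-minimum for suppressed
units, first downward crossing). Baseline for the subtraction is the mean
over the pre-stimulus comparison window. If the half level is already
crossed in the first bin the latency is the first bin center and the
result is flagged. Two resolutions are exposed: 200 ms/σ = 10 ms for all
areas and 100 ms/σ = 5 ms for the short-latency somatosensory areas.

## Opto-tagging

OMI compares the mean rate 100–500 ms after train onset with a −400–0 ms
baseline; significance is a sign-flip test across trains. Fast-window
metrics use the half-open [onset, onset + 10 ms) window per train:
fidelity (% of trains with ≥ 1 spike), mean first-spike latency over
spiking trains, and jitter as the n−1 sample SD of those latencies (the
choice of SD convention is ours; trains, not the individual 100-Hz pulses
within them, are the unit of analysis). Tagged = fidelity > 20 % ∧
latency < 4.5 ms ∧ jitter < 2 ms, all strict; undefined latency or jitter
fails.

## Connectivity

Pearson correlations are computed on trial-by-trial evoked rates (5–55 ms
windows in wS1/wS2, 10–90 ms in wM1/wM2) for units above a 2.5-Hz
in-window rate floor. The STTC uses Δt = 10 ms in a 1-s window centered
on the whisker stimulus, with tiling windows clipped at the interval
edges and merged when overlapping; a term whose denominator 1 − P·T is
zero is dropped from the two-term average; the pipeline averages
per-trial STTC values across trials.

The CCG is normalized so that independent stationary trains give
CCG(τ) = 1 at every lag: coincidence counts are divided by M·θ(τ)·λ₁·λ₂
with θ(τ) = N − |τ| bins and λ in spikes/bin measured inside the analysis
window. Units must exceed 1 Hz in the window. Jitter correction subtracts
the mean CCG of 100 resamples in which, independently within every 25-ms
time slice, the *target* train's slice contents are permuted across
trials as blocks — this preserves each unit's trial-averaged PSTH and
pooled spike count while destroying within-trial fine-timescale
alignment; permuting only one train halves the resampling variance
relative to permuting both. Detection: flank SD pools the corrected CCG
over both flanks (|τ| ∈ [50, 100] ms, population SD); a directional
connection is declared when the corrected CCG at some lag in (0, 10] ms
exceeds 6 flank SDs. The zero lag is excluded to preserve directionality
(the verbal rule "between 0 and 10 ms" is ambiguous; a flag exposes the
choice). Degenerate zero-variance flanks are flagged and never detected.

## Learning modulation index

ΔAP per area × class is the grand average of per-unit evoked deltas with
units pooled across mice; LMI = (ΔAP_E − ΔAP_N)/(|ΔAP_E| + |ΔAP_N|),
reported to two decimals, and the per-area E–I balance change is
LMI_RS − LMI_FS. A per-mouse-weighted aggregate can be formed from the
per-unit tables when mouse identifiers are available.

## Synthetic sessions

The generator produces exact inhomogeneous Poisson spike trains by
thinning, with rate r(t) = max(0, baseline + Σ active templates). An
early refactor enforced a 1-ms refractory dead time; it was removed
because it thins high-rate transients by several percent and breaks the
Poisson contract — only a 0.1-ms minimal separation remains so serialized
times stay strictly increasing. Choices that define the default study
conditions:

- **Baseline rates**: log-normal per class, RS (μ_log = 0.9, σ_log = 1.0;
  median ≈ 2.5 Hz) and FS (1.9, 0.8; median ≈ 6.7 Hz), so FS fire faster
  than RS on average.
- **Spike widths**: Gaussian mixture, FS 0.19 ± 0.02 ms, RS
  0.55 ± 0.08 ms — clearly bimodal with < 0.1 % mass inside the excluded
  band, so classification recovers the true class.
- **Evoked templates**: difference-of-exponentials kernels (5-ms rise,
  20-ms decay; 60/500 ms for ALM delay activity), onset-shifted by an
  area/class latency (sensory before motor, FS before RS). The amplitude
  parametrizes the *mean added rate over the template's quantification
  window*, so window-based estimates recover it directly. Default
  amplitudes per group are the published grand-average window deltas
  (e.g. wM1 RS 1.8 → 0.9 Hz, wM1 FS 3.1 → 7.3 Hz across learning);
  tjM1 suppression uses negative amplitudes with rectification at zero.
  Delay-activity magnitudes are set to reproduce the qualitative pattern
  only — no quantitative distribution is published.
- **Trials**: 40 hit / 10 miss / 40 CR / 10 FA by default, visual cue at
  t = 0, whisker at +1 s, auditory at +2 s, 10-s spacing.
- **Connections**: each presynaptic spike spawns a postsynaptic spike at
  delay + N(0, jitter) with probability = efficacy (default 3 ms, 0.3 ms,
  a pure excess-coincidence coupling).
- **Opto sessions**: 50 trains, 600 ms each, 5-s period. Tagged (FS)
  units get an injected first spike per train (fidelity 0.9, latency
  2 ms, jitter 0.3 ms) and ×8 rate during the light starting 10 ms after
  onset — so the fast tagging window reflects the injected deterministic
  response, not network drive; untagged units are suppressed ×0.4 for the
  train duration. OMI expectations follow directly: (8−1)/(8+1) ≈ 0.78
  tagged, (0.4−1)/(0.4+1) ≈ −0.43 untagged.
- **Seeding**: one master seed; every unit, the trial shuffle and every
  connection draw from counter-indexed substreams, so adding units never
  perturbs existing ones and equal configurations are byte-identical on
  disk.

What the generator does **not** emulate: refractoriness and bursting,
spike-sorting contamination and drift, electrode geometry beyond a fixed
3-site amplitude profile, lick-related movement signals, correlated
trial-to-trial state fluctuations (except where a test constructs them
explicitly), and mouse-level heterogeneity. Passing recovery tests
therefore demonstrate estimator correctness under the assumed
Poisson/log-normal model, not robustness to those real-data features.

## Problem sizes in the test suite

Simulation sizes were chosen as the smallest that leave the checked
effects far from their acceptance margins: e.g. 200 trials per pair and
100 replicates for CCG sensitivity, 10,000 direct null draws for the
detection false-positive rate, 1,000 replicates for permutation-test
calibration, 2,000 units for log-normal recovery from measured rates and
10,000 draws for the pure MLE check, and a two-group pipeline of ~20
units per session for the byte-reproducibility check.

## Known limitations

- STTC significance is not assessed (the upstream analyses use rank
  tests across pairs; per-pair STTC inference is out of scope).
- The latency estimator reports bin centers; sub-millisecond precision
  would require interpolating the half-max crossing.
- The jitter-corrected CCG is a biased estimator of excess coincidences
  at lags beyond the 25-ms jitter window by construction; detection only
  uses lags ≤ 10 ms where the bias is negligible.
- `population_pearson` weights units equally within an area; a
  rate-weighted population rate would differ for very heterogeneous
  populations.
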