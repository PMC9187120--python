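# spikesight

Spike-train analysis for multi-area cortical recordings during
sensorimotor learning.

When mice learn to report a whisker stimulus by delayed licking, the
evoked firing of putative excitatory (regular spiking, RS) and inhibitory
(fast spiking, FS) neurons changes differently across cortical areas:
congruently in some regions, in opposite directions in others, shifting
the local balance of excitation and inhibition. `spikesight` implements
the full analysis chain needed to quantify such changes from sorted
extracellular recordings across six sensorimotor areas (wS1, wS2, wM1,
wM2, ALM, tjM1):

- **Unit classification** — site assignment by largest spike amplitude;
  spike width from trough to baseline return; FS (< 0.26 ms) / RS
  (> 0.34 ms) labels; log-normal baseline-rate fits.
- **Task modulation** — PSTHs (1-ms bins, Gaussian σ = 10 ms), per-trial
  window-based evoked responses, sign-flip permutation tests per neuron,
  modulated-unit fractions, and Novice-vs-Expert group contrasts.
- **Response latency** — time to half-maximum (half-minimum for
  suppressed units) on the smoothed PSTH, with a 200-ms/σ = 10 ms scheme
  for all areas and 100-ms/σ = 5 ms for the fast somatosensory areas.
- **Opto-tagging** — opto modulation index
  OMI = (AP_light − AP_baseline)/(AP_light + AP_baseline) and fast-window
  metrics (fidelity, first-spike latency, jitter); a unit is tagged when
  fidelity > 20 %, latency < 4.5 ms and jitter < 2 ms.
- **Functional connectivity** — trial-by-trial Pearson correlations, the
  spike time tiling coefficient
  STTC = ½[(P_A − T_B)/(1 − P_A T_B) + (P_B − T_A)/(1 − P_B T_A)]
  (Δt = 10 ms), and normalized cross-correlograms
  CCG(τ) = (1/M) Σᵢ Σₜ χ₁ᵢ(t) χ₂ᵢ(t+τ) / (θ(τ) λ₁ λ₂) with jitter
  correction (25-ms windows, 100 resamples); a directional connection is
  detected when the corrected CCG at lags (0, 10] ms exceeds 6 SD of its
  ±50–100 ms flanks.
- **Learning modulation index** —
  LMI = (ΔAP_Expert − ΔAP_Novice)/(|ΔAP_Expert| + |ΔAP_Novice|) per area ×
  class, and the E–I balance change LMI_RS − LMI_FS per area.
- **Synthetic sessions** — a ground-truth generator (inhomogeneous
  Poisson units, log-normal rates, bimodal widths, evoked templates,
  opto responses, injected monosynaptic couplings) so every stage is
  testable at desk scale.

## Worked example

```python
import spikesight as ss

# learning modulation index from grand-average evoked deltas (Hz)
lmi_rs = ss.learning_modulation_index(delta_ap_expert=0.9, delta_ap_novice=1.8)
lmi_fs = ss.learning_modulation_index(delta_ap_expert=7.3, delta_ap_novice=3.1)
print(round(lmi_rs, 2), round(lmi_fs, 2))   # -0.33 0.4

# proportions of detected connections in two groups
res = ss.chi2_proportion_test(3, 1077, 17, 1066)
print(round(res.statistic, 2), f"{res.p_value:.2g}")   # 8.67 0.0032

# spike time tiling coefficient of two trains in a 1-s window
print(round(ss.sttc([0.100, 0.500], [0.105]).value, 4))  # 0.7424
```

The first block says that in wM1 the evoked response of RS units fell
while FS units rose across learning (LMI of opposite sign → the area's
balance tips toward inhibition); the chi-squared test shows the increase
in detected wS2→wM2 connections is unlikely under equal proportions; the
STTC value is the rate-insensitive correlation of two example trains.

End-to-end on synthetic data:

```bash
spikesight run --config examples/pipeline.yaml --out results/
```

writes `evoked_responses_*.csv`, `latencies_*.csv`, `pairs_*.csv`,
`lmi.csv`, `ei_balance.csv` and a `report.json` with per-stage seeds and
file checksums. Runs with identical configuration are byte-identical.

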