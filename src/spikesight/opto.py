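"""Opto-tagging: light-modulation index and fast-window tagging metrics.

Stimulation is a 600-ms, 100-Hz train of blue-light pulses.  Two
complementary quantifications are used:

* a slow-timescale opto modulation index (OMI) comparing the firing rate in
  a light window (100-500 ms after train onset) against a baseline window
  (-400-0 ms before onset), with a sign-flip permutation test across trains
  for significance;
* fast-window metrics over the first 10 ms after train onset, free of
  network effects: fidelity (% of trains with >= 1 spike), mean first-spike
  latency, and jitter (SD of those latencies).  A unit is labeled
  opto-tagged when fidelity > 20%, latency < 4.5 ms, and jitter < 2 ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Unit
from .errors import AnalysisError
from .stats import DEFAULT_N_PERM, permutation_test_paired

LIGHT_WINDOW = (0.100, 0.500)  # s after train onset
BASELINE_WINDOW = (-0.400, 0.0)  # s before train onset
FAST_WINDOW_MS = 10.0

FIDELITY_MIN_PCT = 20.0
LATENCY_MAX_MS = 4.5
JITTER_MAX_MS = 2.0


@dataclass
class OptoRates:
    """Per-train light-window and baseline rates for one unit (Hz)."""

    unit_id: str
    ap_light: float
    ap_baseline: float
    per_trial_light: np.ndarray
    per_trial_baseline: np.ndarray


@dataclass
class TagMetrics:
    unit_id: str
    fidelity_pct: float
    first_spike_latency_ms: float  # NaN when fidelity is 0
    jitter_ms: float  # NaN with < 2 spiking trains
    omi: float = math.nan
    omi_p: float = math.nan
    tagged: bool = False


def opto_rates(unit: Unit, light_onsets: Sequence[float],
               light_window: tuple[float, float] = LIGHT_WINDOW,
               baseline_window: tuple[float, float] = BASELINE_WINDOW) -> OptoRates:
    """Rates in the light and baseline windows around each train onset."""
    onsets = np.asarray(light_onsets, dtype=float)
    if onsets.size == 0:
        raise AnalysisError("opto_rates needs at least one light onset")
    ldur = light_window[1] - light_window[0]
    bdur = baseline_window[1] - baseline_window[0]
    light = np.array([unit.count_in(t + light_window[0], t + light_window[1])
                      for t in onsets]) / ldur
    base = np.array([unit.count_in(t + baseline_window[0], t + baseline_window[1])
                     for t in onsets]) / bdur
    return OptoRates(unit_id=unit.unit_id, ap_light=float(light.mean()),
                     ap_baseline=float(base.mean()),
                     per_trial_light=light, per_trial_baseline=base)


def opto_modulation_index(rates: OptoRates) -> float:
    """OMI = (AP_light - AP_baseline) / (AP_light + AP_baseline), in [-1, 1]."""
    total = rates.ap_light + rates.ap_baseline
    if total == 0:
        warnings.warn(f"unit {rates.unit_id}: OMI undefined (no spikes in "
                      f"either window)", stacklevel=2)
        return math.nan
    return (rates.ap_light - rates.ap_baseline) / total


def omi_significance(rates: OptoRates, n_perm: int = DEFAULT_N_PERM,
                     seed: Optional[int] = None) -> float:
    """Two-sided sign-flip permutation p for the per-train light - baseline
    rate differences."""
    if rates.per_trial_light.size < 2:
        raise AnalysisError("OMI significance needs >= 2 light trains")
    diffs = rates.per_trial_light - rates.per_trial_baseline
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = permutation_test_paired(diffs, n_perm=n_perm, seed=seed)
    return res.p_value


def fast_response_metrics(unit: Unit, light_onsets: Sequence[float],
                          window_ms: float = FAST_WINDOW_MS) -> TagMetrics:
    """Fidelity / first-spike latency / jitter in the half-open window
    [onset, onset + window_ms) after each train onset.

    Latency and jitter are computed over spiking trains only; jitter is the
    n-1 sample standard deviation.
    """
    onsets = np.asarray(light_onsets, dtype=float)
    if onsets.size == 0:
        raise AnalysisError("fast_response_metrics needs at least one onset")
    w = window_ms / 1000.0
    latencies = []
    for t in onsets:
        spikes = unit.spikes_in(t, t + w)
        if spikes.size:
            latencies.append((spikes[0] - t) * 1000.0)
    fidelity = 100.0 * len(latencies) / onsets.size
    if not latencies:
        return TagMetrics(unit_id=unit.unit_id, fidelity_pct=0.0,
                          first_spike_latency_ms=math.nan,
                          jitter_ms=math.nan, tagged=False)
    lat = float(np.mean(latencies))
    jit = float(np.std(latencies, ddof=1)) if len(latencies) > 1 else math.nan
    return TagMetrics(unit_id=unit.unit_id, fidelity_pct=fidelity,
                      first_spike_latency_ms=lat, jitter_ms=jit)


def is_optotagged(metrics: TagMetrics) -> bool:
    """Opto-tagged iff fidelity > 20%, latency < 4.5 ms and jitter < 2 ms
    (strict inequalities; undefined latency or jitter fails)."""
    if math.isnan(metrics.first_spike_latency_ms) or math.isnan(metrics.jitter_ms):
        return False
    return (metrics.fidelity_pct > FIDELITY_MIN_PCT
            and metrics.first_spike_latency_ms < LATENCY_MAX_MS
            and metrics.jitter_ms < JITTER_MAX_MS)


def tag_unit(unit: Unit, light_onsets: Sequence[float],
             n_perm: int = DEFAULT_N_PERM,
             seed: Optional[int] = None) -> TagMetrics:
    """Full tagging record for one unit: fast metrics plus OMI and its
    permutation p-value."""
    metrics = fast_response_metrics(unit, light_onsets)
    rates = opto_rates(unit, light_onsets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics.omi = opto_modulation_index(rates)
    if rates.per_trial_light.size >= 2:
        metrics.omi_p = omi_significance(rates, n_perm=n_perm, seed=seed)
    metrics.tagged = is_optotagged(metrics)
    return metrics
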