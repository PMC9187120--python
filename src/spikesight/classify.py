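"""Waveform-based unit characterization: site assignment, spike width,
RS/FS classification, and baseline-rate statistics.

Spike width is the time from the spike trough (the waveform's global
minimum) to the first return of the voltage to baseline level.  Units with
width < 0.26 ms are labeled fast spiking (FS, putative inhibitory), units
with width > 0.34 ms regular spiking (RS, putative excitatory), and units
with intermediate width are excluded from further analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AnalysisWindow, Trial, TrialTable, Unit, Waveform, classify_width
from .errors import AnalysisError

#: Fraction of leading samples treated as the pre-trough baseline segment.
BASELINE_FRACTION = 0.25


@dataclass
class RateFit:
    """Log-normal fit to a set of baseline firing rates: a normal
    distribution fitted by maximum likelihood to log(rate)."""

    mu_log: float
    sigma_log: float
    n_units: int
    n_zero_excluded: int = 0

    def __post_init__(self):
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")


def assign_unit_site(waveform_per_site: Sequence[Waveform]) -> int:
    """Site whose average waveform has the largest peak-to-trough amplitude.

    Ties are broken in favour of the lowest site index.
    """
    if len(waveform_per_site) == 0:
        raise AnalysisError("assign_unit_site needs at least one site waveform")
    ordered = sorted(waveform_per_site, key=lambda w: w.site_index)
    amplitudes = np.array([w.peak_to_trough for w in ordered])
    return int(ordered[int(np.argmax(amplitudes))].site_index)


def compute_spike_width(waveform: Waveform) -> float:
    """Spike width in ms: trough to first return to baseline level.

    Baseline level is the mean of the first 25% of samples (the pre-trough
    reference segment).  The return crossing is located with linear
    interpolation between the two bracketing samples for sub-sample
    precision.
    """
    v = waveform.samples
    n_base = max(1, int(round(BASELINE_FRACTION * v.size)))
    baseline = float(v[:n_base].mean())

    trough = int(np.argmin(v))
    if np.count_nonzero(v == v[trough]) > 1:
        raise AnalysisError("spike width unmeasurable: waveform trough is not "
                            "a strict global minimum")
    if trough < n_base:
        raise AnalysisError("spike width unmeasurable: trough lies inside the "
                            "baseline reference segment")

    post = v[trough:]
    above = np.nonzero(post >= baseline)[0]
    if above.size == 0:
        raise AnalysisError("spike width unmeasurable: voltage never returns "
                            "to baseline after the trough")
    j = int(above[0])  # first post-trough sample at/above baseline (j >= 1)
    # interpolate within [j-1, j] for the exact baseline crossing
    v0, v1 = post[j - 1], post[j]
    frac = 0.0 if v1 == v0 else (baseline - v0) / (v1 - v0)
    width_samples = (j - 1) + frac
    return float(width_samples / waveform.sampling_rate * 1000.0)


def classify_rs_fs(width_ms: float) -> str:
    """FS if width < 0.26 ms, RS if > 0.34 ms, otherwise ``excluded``."""
    if not width_ms > 0:
        raise AnalysisError(f"spike width must be positive, got {width_ms}")
    return classify_width(width_ms)


def annotate_unit(unit: Unit) -> Unit:
    """Fill ``assigned_site``, ``spike_width_ms`` and ``cell_class`` in place
    from the unit's per-site waveforms."""
    site = assign_unit_site(unit.waveform_per_site)
    wf = next(w for w in unit.waveform_per_site if w.site_index == site)
    width = compute_spike_width(wf)
    unit.assigned_site = site
    unit.spike_width_ms = width
    unit.cell_class = classify_rs_fs(width)
    return unit


def baseline_rate(unit: Unit, trial_table: TrialTable,
                  baseline_window: tuple[float, float] = (-2.0, 0.0),
                  reference: str = "visual") -> float:
    """Mean firing rate (Hz) in a per-trial baseline window.

    The default window is the 2 s preceding the visual trial-onset cue.
    """
    trials = trial_table.select(require_event=reference)
    if not trials:
        raise AnalysisError("baseline_rate needs at least one usable trial")
    dur = baseline_window[1] - baseline_window[0]
    counts = [unit.count_in(t.event_time(reference) + baseline_window[0],
                            t.event_time(reference) + baseline_window[1])
              for t in trials]
    return float(np.mean(counts) / dur)


def fit_lognormal_rates(rates) -> RateFit:
    """Maximum-likelihood normal fit to log(rates).

    Zero rates cannot enter the log and are excluded; the excluded count is
    reported on the fit and in a warning.
    """
    r = np.asarray(rates, dtype=float)
    if np.any(r < 0):
        raise AnalysisError("rates must be non-negative")
    n_zero = int(np.count_nonzero(r == 0))
    pos = r[r > 0]
    if n_zero:
        warnings.warn(f"excluding {n_zero} zero rate(s) from log-normal fit",
                      stacklevel=2)
    if pos.size < 3:
        raise AnalysisError("log-normal fit needs >= 3 positive rates")
    logr = np.log(pos)
    return RateFit(mu_log=float(logr.mean()),
                   sigma_log=float(logr.std(ddof=0)),
                   n_units=int(pos.size),
                   n_zero_excluded=n_zero)
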