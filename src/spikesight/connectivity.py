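"""Interareal coordination: trial-by-trial correlations, the spike time
tiling coefficient (STTC), and jitter-corrected cross-correlogram (CCG)
connection detection.

Pearson correlations are computed between trial-by-trial whisker-evoked
responses of simultaneously recorded pairs (5-55 ms windows in wS1/wS2,
10-90 ms in wM1/wM2; units below 2.5 Hz in the window are excluded).

The STTC is a rate-insensitive pairwise correlation computed in a 1-s
window centered on the whisker stimulus:

    STTC = 1/2 * [ (P_A - T_B)/(1 - P_A*T_B) + (P_B - T_A)/(1 - P_B*T_A) ]

where ``P_A`` is the proportion of spikes from A falling within +/-dt
(10 ms) of a spike in B (and vice versa) and ``T_A`` is the proportion of
the interval tiled by the +/-dt neighbourhoods of A's spikes.

The normalized CCG between a reference and a target unit, over M trials of
N 1-ms bins, is

    CCG(tau) = (1/M) * sum_i sum_t chi1_i(t) * chi2_i(t+tau) / (theta(tau) * lambda1 * lambda2)

with the triangular overlap correction ``theta(tau) = N - |tau|`` (bins)
and mean rates ``lambda`` in spikes/bin, so that independent stationary
trains give CCG = 1 at every lag.  Stimulus-locked and slow comodulation
are removed by subtracting a jittered CCG: the average over 100 resamples
in which, within every 25-ms time slice, the target's slice contents are
permuted across trials (preserving each unit's trial-averaged PSTH).  A
directional connection is detected when the corrected CCG within lags
(0, 10] ms exceeds 6 standard deviations of its flanks (|lag| in
[50, 100] ms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import AnalysisWindow, TrialTable, Unit
from .errors import AnalysisError

#: Minimum in-window mean rate (Hz) for the Pearson pairwise analysis.
RATE_MIN_PEARSON_HZ = 2.5
#: Minimum in-window mean rate (Hz) for inclusion in the CCG analysis.
RATE_MIN_CCG_HZ = 1.0

STTC_DT_S = 0.010
CCG_BIN_S = 0.001
CCG_MAX_LAG_S = 0.100
CCG_WINDOW = (-0.5, 0.5)  # 1-s analysis window centered on whisker onset
JITTER_WINDOW_S = 0.025
N_JITTER_RESAMPLES = 100
DETECTION_LAGS_S = (0.0, 0.010)  # half-open on the left: tau in (0, 10] ms
FLANK_LAGS_S = (0.050, 0.100)
DETECTION_SD_FACTOR = 6.0


# ---------------------------------------------------------------------------
# Trial-by-trial Pearson correlations
# ---------------------------------------------------------------------------

def trial_response_vector(unit: Unit, trial_table: TrialTable,
                          window: AnalysisWindow,
                          outcome_filter: Optional[Sequence[str]] = None
                          ) -> np.ndarray:
    """Per-trial firing rate (Hz) of one unit in its area's evoked window."""
    trials = trial_table.select(outcomes=outcome_filter,
                                require_event=window.reference)
    if not trials:
        raise AnalysisError("trial_response_vector: no usable trials")
    dur = window.response_duration
    return np.array([unit.count_in(t.event_time(window.reference) + window.response[0],
                                   t.event_time(window.reference) + window.response[1]) / dur
                     for t in trials])


def passes_rate_floor(rates: np.ndarray,
                      min_rate_hz: float = RATE_MIN_PEARSON_HZ) -> bool:
    """Inclusion rule for the pairwise Pearson analysis."""
    return float(np.mean(rates)) > min_rate_hz


def pairwise_pearson(vec_a, vec_b) -> float:
    """Sample Pearson correlation of two per-trial response vectors."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.size != b.size:
        raise AnalysisError("pairwise_pearson: vectors must have equal length")
    if a.size < 3:
        raise AnalysisError("pairwise_pearson needs >= 3 trials")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant response vector: correlation undefined",
                      stacklevel=2)
        return math.nan
    return float(sps.pearsonr(a, b).statistic)


def population_pearson(units_a: Sequence[Unit], units_b: Sequence[Unit],
                       trial_table: TrialTable,
                       window_a: AnalysisWindow, window_b: AnalysisWindow,
                       outcome_filter: Optional[Sequence[str]] = None) -> float:
    """Pearson correlation of per-trial across-unit mean responses of two
    simultaneously recorded areas."""
    if not units_a or not units_b:
        raise AnalysisError("population_pearson: an area has no units")
    mean_a = np.mean([trial_response_vector(u, trial_table, window_a,
                                            outcome_filter) for u in units_a],
                     axis=0)
    mean_b = np.mean([trial_response_vector(u, trial_table, window_b,
                                            outcome_filter) for u in units_b],
                     axis=0)
    return pairwise_pearson(mean_a, mean_b)


# ---------------------------------------------------------------------------
# Spike time tiling coefficient
# ---------------------------------------------------------------------------

@dataclass
class STTCResult:
    value: float  # NaN when undefined (an empty train)
    p_a: float = math.nan
    p_b: float = math.nan
    t_a: float = math.nan
    t_b: float = math.nan
    dt_s: float = STTC_DT_S
    interval: tuple[float, float] = (0.0, 1.0)


def _tiling_fraction(train: np.ndarray, interval: tuple[float, float],
                     dt: float) -> float:
    """Fraction of the interval covered by the union of +/-dt neighbourhoods
    of the spikes, clipped at the interval edges."""
    lo = np.clip(train - dt, interval[0], interval[1])
    hi = np.clip(train + dt, interval[0], interval[1])
    covered = 0.0
    cur_lo, cur_hi = lo[0], hi[0]
    for l, h in zip(lo[1:], hi[1:]):
        if l <= cur_hi:
            cur_hi = max(cur_hi, h)
        else:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = l, h
    covered += cur_hi - cur_lo
    return covered / (interval[1] - interval[0])


def _proportion_near(train: np.ndarray, other: np.ndarray, dt: float) -> float:
    """Proportion of ``train`` spikes within +/-dt of any spike in ``other``."""
    idx = np.searchsorted(other, train)
    left = np.where(idx > 0, train - other[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < other.size, other[np.minimum(idx, other.size - 1)] - train,
                     np.inf)
    return float(np.mean(np.minimum(left, right) <= dt + 1e-12))


def sttc(train_a, train_b, interval: tuple[float, float] = (0.0, 1.0),
         dt: float = STTC_DT_S) -> STTCResult:
    """Spike time tiling coefficient of two trains within an interval.

    Undefined (NaN, with a warning) when either train is empty; a term whose
    denominator ``1 - P*T`` is zero is dropped from the average.
    """
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    a = a[(a >= interval[0]) & (a <= interval[1])]
    b = b[(b >= interval[0]) & (b <= interval[1])]
    if a.size == 0 or b.size == 0:
        warnings.warn("STTC undefined: empty spike train in interval",
                      stacklevel=2)
        return STTCResult(value=math.nan, interval=interval, dt_s=dt)

    p_a = _proportion_near(a, b, dt)
    p_b = _proportion_near(b, a, dt)
    t_a = _tiling_fraction(a, interval, dt)
    t_b = _tiling_fraction(b, interval, dt)

    terms = []
    if 1.0 - p_a * t_b != 0.0:
        terms.append((p_a - t_b) / (1.0 - p_a * t_b))
    if 1.0 - p_b * t_a != 0.0:
        terms.append((p_b - t_a) / (1.0 - p_b * t_a))
    value = float(np.mean(terms)) if terms else math.nan
    return STTCResult(value=value, p_a=p_a, p_b=p_b, t_a=t_a, t_b=t_b,
                      dt_s=dt, interval=interval)


# ---------------------------------------------------------------------------
# Cross-correlograms
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrialSpikes:
    """Per-trial binned spike trains over the CCG analysis window.

    Spikes are stored as parallel ``trial_index`` / ``bin_index`` arrays
    (a ragged layout: one entry per spike).  ``rate_per_bin`` is the unit's
    mean rate in spikes/bin over the window, the lambda of the CCG
    normalization.
    """

    trial_index: np.ndarray
    bin_index: np.ndarray
    n_trials: int
    n_bins: int
    bin_width_s: float = CCG_BIN_S

    @property
    def rate_per_bin(self) -> float:
        return self.trial_index.size / (self.n_trials * self.n_bins)

    @property
    def rate_hz(self) -> float:
        return self.rate_per_bin / self.bin_width_s

    @classmethod
    def from_unit(cls, unit: Unit, trial_table: TrialTable,
                  window: tuple[float, float] = CCG_WINDOW,
                  bin_width: float = CCG_BIN_S,
                  reference: str = "whisker",
                  outcome_filter: Optional[Sequence[str]] = None
                  ) -> "BinnedTrialSpikes":
        trials = trial_table.select(outcomes=outcome_filter,
                                    require_event=reference)
        if not trials:
            raise AnalysisError("BinnedTrialSpikes: no usable trials")
        n_bins = int(round((window[1] - window[0]) / bin_width))
        tr_idx, bins = [], []
        for i, t in enumerate(trials):
            t0 = t.event_time(reference)
            rel = unit.spikes_in(t0 + window[0], t0 + window[1]) - t0
            bi = np.floor((rel - window[0]) / bin_width).astype(np.int64)
            bi = bi[(bi >= 0) & (bi < n_bins)]
            tr_idx.append(np.full(bi.size, i, dtype=np.int64))
            bins.append(bi)
        return cls(trial_index=np.concatenate(tr_idx) if tr_idx else np.empty(0, np.int64),
                   bin_index=np.concatenate(bins) if bins else np.empty(0, np.int64),
                   n_trials=len(trials), n_bins=n_bins, bin_width_s=bin_width)

    @classmethod
    def from_arrays(cls, spike_times_per_trial: Sequence[np.ndarray],
                    window: tuple[float, float] = CCG_WINDOW,
                    bin_width: float = CCG_BIN_S) -> "BinnedTrialSpikes":
        """Build directly from per-trial spike-time arrays (times relative to
        the reference event)."""
        n_bins = int(round((window[1] - window[0]) / bin_width))
        tr_idx, bins = [], []
        for i, rel in enumerate(spike_times_per_trial):
            rel = np.asarray(rel, dtype=float)
            bi = np.floor((rel - window[0]) / bin_width).astype(np.int64)
            bi = bi[(bi >= 0) & (bi < n_bins)]
            tr_idx.append(np.full(bi.size, i, dtype=np.int64))
            bins.append(bi)
        return cls(trial_index=np.concatenate(tr_idx) if tr_idx else np.empty(0, np.int64),
                   bin_index=np.concatenate(bins) if bins else np.empty(0, np.int64),
                   n_trials=len(spike_times_per_trial), n_bins=n_bins,
                   bin_width_s=bin_width)


@dataclass
class CCGResult:
    lags_s: np.ndarray
    ccg_raw: np.ndarray
    ccg_jittered: Optional[np.ndarray] = None
    ccg_corrected: Optional[np.ndarray] = None
    n_resamples: int = 0
    flank_sd: float = math.nan
    threshold: float = math.nan
    detected: bool = False
    peak_lag_s: float = math.nan
    degenerate: bool = False
    bin_width_s: float = CCG_BIN_S


def _lag_counts(ta: np.ndarray, ba: np.ndarray, tb: np.ndarray,
                bb: np.ndarray, n_trials: int, max_lag_bins: int) -> np.ndarray:
    """Histogram of same-trial bin differences (target - reference) over
    lags -max_lag..+max_lag, fully vectorized over the ragged pair set."""
    n_lags = 2 * max_lag_bins + 1
    if ta.size == 0 or tb.size == 0:
        return np.zeros(n_lags)
    order = np.argsort(tb, kind="stable")
    tb_s, bb_s = tb[order], bb[order]
    counts_b = np.bincount(tb_s, minlength=n_trials)
    offsets = np.concatenate([[0], np.cumsum(counts_b)])

    nb = counts_b[ta]  # partners per reference spike
    total = int(nb.sum())
    if total == 0:
        return np.zeros(n_lags)
    a_rep = np.repeat(ba, nb)
    starts = np.repeat(offsets[ta], nb)
    run_starts = np.cumsum(nb) - nb
    pos = np.arange(total) - np.repeat(run_starts, nb)
    lags = bb_s[starts + pos] - a_rep
    sel = np.abs(lags) <= max_lag_bins
    return np.bincount(lags[sel] + max_lag_bins, minlength=n_lags).astype(float)


def ccg(reference: BinnedTrialSpikes, target: BinnedTrialSpikes,
        max_lag: float = CCG_MAX_LAG_S,
        min_rate_hz: float = RATE_MIN_CCG_HZ,
        enforce_rate_min: bool = True) -> CCGResult:
    """Raw normalized cross-correlogram at 1-ms lags up to +/-max_lag.

    Positive lags mean the target fires after the reference.  Both units
    must exceed the in-window rate floor (1 Hz) unless
    ``enforce_rate_min=False``.
    """
    if reference.n_trials != target.n_trials or reference.n_bins != target.n_bins:
        raise AnalysisError("ccg: reference and target must share the trial "
                            "grid")
    lam1, lam2 = reference.rate_per_bin, target.rate_per_bin
    if lam1 == 0 or lam2 == 0:
        raise AnalysisError("ccg: a unit has no spikes in the analysis window")
    if enforce_rate_min and (reference.rate_hz <= min_rate_hz
                             or target.rate_hz <= min_rate_hz):
        raise AnalysisError(
            f"ccg: in-window rate at or below the {min_rate_hz} Hz inclusion "
            f"floor (reference {reference.rate_hz:.2f} Hz, target "
            f"{target.rate_hz:.2f} Hz)")

    L = int(round(max_lag / reference.bin_width_s))
    counts = _lag_counts(reference.trial_index, reference.bin_index,
                         target.trial_index, target.bin_index,
                         reference.n_trials, L)
    theta = reference.n_bins - np.abs(np.arange(-L, L + 1))
    raw = counts / (reference.n_trials * theta * lam1 * lam2)
    lags = np.arange(-L, L + 1) * reference.bin_width_s
    return CCGResult(lags_s=lags, ccg_raw=raw,
                     bin_width_s=reference.bin_width_s)


def _jitter_resample(target: BinnedTrialSpikes, rng: np.random.Generator,
                     jitter_bins: int) -> np.ndarray:
    """One resample of the target's trial labels: within every time slice of
    ``jitter_bins`` bins, trial labels are permuted jointly (each trial's
    slice contents move as a block), preserving the pooled PSTH."""
    n_slices = int(np.ceil(target.n_bins / jitter_bins))
    slice_idx = target.bin_index // jitter_bins
    perms = np.empty((n_slices, target.n_trials), dtype=np.int64)
    for s in range(n_slices):
        perms[s] = rng.permutation(target.n_trials)
    return perms[slice_idx, target.trial_index]


def jitter_correct(reference: BinnedTrialSpikes, target: BinnedTrialSpikes,
                   jitter_window: float = JITTER_WINDOW_S,
                   n_resamples: int = N_JITTER_RESAMPLES,
                   seed: Optional[int] = None,
                   max_lag: float = CCG_MAX_LAG_S,
                   min_rate_hz: float = RATE_MIN_CCG_HZ,
                   enforce_rate_min: bool = True) -> CCGResult:
    """Jitter-corrected CCG: raw minus the mean CCG over ``n_resamples``
    jitter resamples of the target train."""
    if reference.n_trials < 2:
        raise AnalysisError("jitter_correct needs >= 2 trials")
    result = ccg(reference, target, max_lag=max_lag, min_rate_hz=min_rate_hz,
                 enforce_rate_min=enforce_rate_min)
    rng = np.random.default_rng(seed)
    jitter_bins = int(round(jitter_window / reference.bin_width_s))
    L = (result.lags_s.size - 1) // 2
    lam1, lam2 = reference.rate_per_bin, target.rate_per_bin
    theta = reference.n_bins - np.abs(np.arange(-L, L + 1))
    norm = reference.n_trials * theta * lam1 * lam2

    acc = np.zeros(result.lags_s.size)
    for _ in range(n_resamples):
        tb_new = _jitter_resample(target, rng, jitter_bins)
        acc += _lag_counts(reference.trial_index, reference.bin_index,
                           tb_new, target.bin_index,
                           reference.n_trials, L)
    result.ccg_jittered = acc / (n_resamples * norm)
    result.ccg_corrected = result.ccg_raw - result.ccg_jittered
    result.n_resamples = n_resamples
    return result


def detect_connection(result: CCGResult,
                      detection_lags: tuple[float, float] = DETECTION_LAGS_S,
                      flank_lags: tuple[float, float] = FLANK_LAGS_S,
                      sd_factor: float = DETECTION_SD_FACTOR
                      ) -> tuple[bool, float]:
    """Directional-connection verdict from a jitter-corrected CCG.

    ``flank_sd`` pools the corrected CCG over both flanks (|lag| in
    [50, 100] ms); a connection is detected when the corrected CCG at some
    lag in (0, 10] ms exceeds ``sd_factor * flank_sd``.  The exactly-zero
    lag is excluded to preserve directionality.  Updates the detection
    fields on ``result`` and returns ``(detected, peak_lag_s)``.
    """
    if result.ccg_corrected is None:
        raise AnalysisError("detect_connection needs a jitter-corrected CCG")
    lags, corr = result.lags_s, result.ccg_corrected
    eps = result.bin_width_s * 1e-6
    flank = (np.abs(lags) >= flank_lags[0] - eps) & \
            (np.abs(lags) <= flank_lags[1] + eps)
    window = (lags > detection_lags[0] + eps) & \
             (lags <= detection_lags[1] + eps)
    flank_sd = float(np.std(corr[flank], ddof=0))
    result.flank_sd = flank_sd
    result.threshold = sd_factor * flank_sd
    if flank_sd == 0:
        result.degenerate = True
        result.detected = False
        result.peak_lag_s = math.nan
        return False, math.nan
    in_window = corr[window]
    peak_i = int(np.argmax(in_window))
    result.peak_lag_s = float(lags[window][peak_i])
    result.detected = bool(in_window[peak_i] > result.threshold)
    return result.detected, result.peak_lag_s
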