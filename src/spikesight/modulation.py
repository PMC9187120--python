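"""PSTHs and window-based quantification of task-evoked firing.

Evoked responses are measured per trial as the firing-rate difference
between a response window and a paired baseline window (half-open windows
relative to a task event), then averaged across trials.  Per-neuron
significance comes from a sign-flip permutation test on the per-trial
differences, so each neuron's test is exact.  Population summaries report
the fraction of significantly positively/negatively modulated units per
area and cell class, and Novice-vs-Expert contrasts use unpaired
permutation tests on the per-unit mean deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisWindow, Trial, TrialTable, Unit
from .errors import AnalysisError
from .stats import (DEFAULT_N_PERM, TestResult, permutation_test_paired,
                    permutation_test_unpaired)


@dataclass
class PSTH:
    """Trial-averaged binned firing rate aligned to a task event.

    1-ms non-overlapping bins by default, optionally filtered with a
    unit-area Gaussian kernel (sigma in seconds; 0 disables smoothing).
    """

    bin_centers_s: np.ndarray
    rate_hz: np.ndarray
    bin_width_s: float
    sigma_s: float
    n_trials: int
    reference_event: str = "whisker"


def _gaussian_kernel(sigma_s: float, bin_width_s: float) -> np.ndarray:
    """Unit-area Gaussian kernel truncated at +/-4 sigma."""
    half = max(1, int(np.ceil(4.0 * sigma_s / bin_width_s)))
    t = np.arange(-half, half + 1) * bin_width_s
    k = np.exp(-0.5 * (t / sigma_s) ** 2)
    return k / k.sum()


def smooth_rate(rate: np.ndarray, sigma_s: float, bin_width_s: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundary padding (mass-preserving
    in the interior)."""
    if sigma_s == 0:
        return rate.copy()
    k = _gaussian_kernel(sigma_s, bin_width_s)
    half = (k.size - 1) // 2
    padded = np.pad(rate, half, mode="reflect")
    return np.convolve(padded, k, mode="valid")


def compute_psth(unit: Unit, trial_table: TrialTable, reference_event: str,
                 span: tuple[float, float], bin_width: float = 0.001,
                 sigma: float = 0.010,
                 outcome_filter: Optional[Sequence[str]] = None) -> PSTH:
    """Peri-stimulus time histogram for one unit.

    ``rate(bin) = total spikes in bin / (n_trials * bin_width)``, then
    convolved with a unit-area Gaussian of the given sigma.
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be > 0")
    trials = trial_table.select(outcomes=outcome_filter,
                                require_event=reference_event)
    if not trials:
        raise AnalysisError(f"no trials pass the outcome filter with a "
                            f"{reference_event!r} event")
    n_bins = int(round((span[1] - span[0]) / bin_width))
    edges = span[0] + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for t in trials:
        t0 = t.event_time(reference_event)
        rel = unit.spikes_in(t0 + span[0], t0 + span[1]) - t0
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(trials) * bin_width)
    rate = smooth_rate(rate, sigma, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    return PSTH(bin_centers_s=centers, rate_hz=rate, bin_width_s=bin_width,
                sigma_s=sigma, n_trials=len(trials),
                reference_event=reference_event)


@dataclass
class EvokedResponse:
    """Window-based evoked-rate change for one unit (response - baseline)."""

    unit_id: str
    window_name: str
    delta_rate_hz: float
    per_trial_deltas: np.ndarray
    p_value: float
    direction: str  # positive | negative | none
    n_trials: int = 0
    area: str = ""
    cell_class: str = ""


def per_trial_window_deltas(unit: Unit, trials: Sequence[Trial],
                            window: AnalysisWindow) -> np.ndarray:
    """Per-trial (response rate - baseline rate) in Hz."""
    deltas = np.empty(len(trials))
    for i, t in enumerate(trials):
        t0 = t.event_time(window.reference)
        resp = unit.count_in(t0 + window.response[0], t0 + window.response[1])
        base = unit.count_in(t0 + window.baseline[0], t0 + window.baseline[1])
        deltas[i] = resp / window.response_duration - base / window.baseline_duration
    return deltas


def evoked_response(unit: Unit, trial_table: TrialTable,
                    window: AnalysisWindow, window_name: str = "",
                    outcome_filter: Optional[Sequence[str]] = None,
                    alpha: float = 0.025, n_perm: int = DEFAULT_N_PERM,
                    seed: Optional[int] = None) -> EvokedResponse:
    """Trial-averaged evoked-rate change with permutation significance.

    ``alpha`` is the per-direction significance level: a unit is labeled
    positively (negatively) modulated when the one-sided sign-flip test in
    that direction falls below ``alpha``.
    """
    trials = trial_table.select(outcomes=outcome_filter,
                                require_event=window.reference)
    if not trials:
        raise AnalysisError(f"event {window.reference!r} absent in all "
                            f"selected trials")
    deltas = per_trial_window_deltas(unit, trials, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_pos = permutation_test_paired(deltas, n_perm=n_perm, seed=seed,
                                          alternative="greater")
        res_neg = permutation_test_paired(deltas, n_perm=n_perm, seed=seed,
                                          alternative="less")
    direction = "none"
    if res_pos.p_value < alpha:
        direction = "positive"
    elif res_neg.p_value < alpha:
        direction = "negative"
    p_two = min(1.0, 2.0 * min(res_pos.p_value, res_neg.p_value))
    return EvokedResponse(unit_id=unit.unit_id, window_name=window_name,
                          delta_rate_hz=float(deltas.mean()),
                          per_trial_deltas=deltas, p_value=p_two,
                          direction=direction, n_trials=len(trials),
                          area=unit.area, cell_class=unit.cell_class)


#: Groups with at most this many units are flagged: fractions of modulated
#: neurons are only reported for groups with more than 5 neurons.
MIN_GROUP_SIZE = 5


def modulated_fractions(responses: Sequence[EvokedResponse]) -> pd.DataFrame:
    """Fractions of positively/negatively modulated units per area x class.

    Counts are retained so the fractions can be compared across groups with
    :func:`spikesight.stats.chi2_proportion_test`.  Rows with
    ``n <= MIN_GROUP_SIZE`` units are flagged as below the reporting floor.
    """
    rows = []
    df = pd.DataFrame([{"area": r.area, "cell_class": r.cell_class,
                        "direction": r.direction} for r in responses])
    if df.empty:
        return pd.DataFrame(columns=["area", "cell_class", "n", "n_positive",
                                     "n_negative", "frac_positive",
                                     "frac_negative", "below_floor"])
    for (area, cls), g in df.groupby(["area", "cell_class"], sort=True):
        n = len(g)
        n_pos = int((g["direction"] == "positive").sum())
        n_neg = int((g["direction"] == "negative").sum())
        rows.append({"area": area, "cell_class": cls, "n": n,
                     "n_positive": n_pos, "n_negative": n_neg,
                     "frac_positive": n_pos / n, "frac_negative": n_neg / n,
                     "below_floor": n <= MIN_GROUP_SIZE})
    return pd.DataFrame(rows)


def compare_groups(responses_a: Sequence[EvokedResponse],
                   responses_b: Sequence[EvokedResponse],
                   n_perm: int = DEFAULT_N_PERM,
                   seed: Optional[int] = None,
                   alternative: str = "two-sided") -> TestResult:
    """Unpaired permutation test on per-unit evoked deltas between two
    populations (e.g. Novice vs. Expert)."""
    a = [r.delta_rate_hz for r in responses_a]
    b = [r.delta_rate_hz for r in responses_b]
    return permutation_test_unpaired(a, b, n_perm=n_perm, seed=seed,
                                     alternative=alternative)


def outcome_contrast(unit: Unit, trial_table: TrialTable,
                     outcomes_a: Sequence[str], outcomes_b: Sequence[str],
                     window: AnalysisWindow,
                     n_perm: int = DEFAULT_N_PERM,
                     seed: Optional[int] = None) -> TestResult:
    """Compare one unit's window rates between two outcome subsets
    (e.g. correct rejection vs. miss) with an unpaired permutation test."""
    trials_a = trial_table.select(outcomes=outcomes_a,
                                  require_event=window.reference)
    trials_b = trial_table.select(outcomes=outcomes_b,
                                  require_event=window.reference)
    if not trials_a or not trials_b:
        raise AnalysisError("outcome_contrast needs both outcome subsets "
                            "non-empty")
    if len(trials_a) == 1 and len(trials_b) == 1:
        warnings.warn("single trial per subset: only 2 distinct labelings",
                      stacklevel=2)

    def rates(trials):
        t0s = [t.event_time(window.reference) for t in trials]
        return [unit.count_in(t0 + window.response[0], t0 + window.response[1])
                / window.response_duration for t0 in t0s]

    return permutation_test_unpaired(rates(trials_a), rates(trials_b),
                                     n_perm=n_perm, seed=seed)
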