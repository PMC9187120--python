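"""Domain types, session container, tabular readers/writers, and analysis windows.

A *session* is one acute recording: a set of sorted units (each a spike train
plus the average extracellular waveform on every recording site), a trial
table describing the behavioural task timeline, and, for opto-tagging
sessions, the onsets of blue-light pulse trains.

Times are stored in seconds and serialized as decimal text at microsecond
precision.  All analysis windows are half-open ``[start, end)`` so that a
spike falling exactly on a shared edge is counted once.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Cortical areas recorded in the six-area sensorimotor dataset; the
#: vocabulary is configurable, these are the defaults.
DEFAULT_AREAS = ("wS1", "wS2", "wM1", "wM2", "ALM", "tjM1")
DEFAULT_LAYERS = ("L2/3", "L5", "L6a", "unknown")
OUTCOMES = ("hit", "miss", "CR", "FA", "early_lick")

#: Spike-width classification thresholds (ms): narrow = fast spiking (FS,
#: putative inhibitory), broad = regular spiking (RS, putative excitatory).
FS_MAX_WIDTH_MS = 0.26
RS_MIN_WIDTH_MS = 0.34

TIME_DECIMALS = 6  # microsecond precision in serialized tables


@dataclass
class Waveform:
    """Average spike waveform on one recording site.

    ``samples`` are baseline-referenced voltages (arbitrary units); the
    global minimum is the spike trough from which width is measured.
    """

    samples: np.ndarray
    sampling_rate: float
    site_index: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("Waveform: samples must be non-empty")
        if self.sampling_rate <= 0:
            raise ValidationError("Waveform: sampling_rate must be > 0")

    @property
    def peak_to_trough(self) -> float:
        return float(self.samples.max() - self.samples.min())


@dataclass
class Unit:
    """One sorted neuron with its spike train and metadata."""

    unit_id: str
    area: str
    layer: str = "unknown"
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    waveform_per_site: list[Waveform] = field(default_factory=list)
    assigned_site: int = -1
    spike_width_ms: float = math.nan
    cell_class: str = "excluded"
    baseline_rate_hz: float = math.nan

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self, areas: Sequence[str] = DEFAULT_AREAS,
                 layers: Sequence[str] = DEFAULT_LAYERS) -> None:
        if self.area not in areas:
            raise ValidationError(f"Unit {self.unit_id}: unknown area {self.area!r}")
        if self.layer not in layers:
            raise ValidationError(f"Unit {self.unit_id}: unknown layer {self.layer!r}")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValidationError(
                f"Unit {self.unit_id}: spike_times must be strictly increasing")
        if self.cell_class not in ("RS", "FS", "excluded"):
            raise ValidationError(
                f"Unit {self.unit_id}: invalid cell_class {self.cell_class!r}")
        if not math.isnan(self.spike_width_ms):
            expected = classify_width(self.spike_width_ms)
            if self.cell_class != expected:
                raise ValidationError(
                    f"Unit {self.unit_id}: cell_class {self.cell_class!r} "
                    f"inconsistent with spike width {self.spike_width_ms} ms "
                    f"(expected {expected!r})")
        if not math.isnan(self.baseline_rate_hz) and self.baseline_rate_hz < 0:
            raise ValidationError(f"Unit {self.unit_id}: negative baseline rate")

    def spikes_in(self, start: float, end: float) -> np.ndarray:
        """Spikes in the half-open window [start, end)."""
        i0, i1 = np.searchsorted(self.spike_times, (start, end), side="left")
        return self.spike_times[i0:i1]

    def count_in(self, start: float, end: float) -> int:
        i0, i1 = np.searchsorted(self.spike_times, (start, end), side="left")
        return int(i1 - i0)


def classify_width(width_ms: float) -> str:
    """RS/FS label from spike width; intermediate widths are excluded."""
    if width_ms < FS_MAX_WIDTH_MS:
        return "FS"
    if width_ms > RS_MIN_WIDTH_MS:
        return "RS"
    return "excluded"


@dataclass
class Trial:
    """One behavioural trial.

    The task timeline is: visual cue (trial onset), optional whisker stimulus
    1 s later in stimulus trials, auditory cue 2 s after the visual cue, then
    a 1-s response window.  ``hit``/``miss`` outcomes require a whisker
    stimulus; ``CR``/``FA`` require its absence; ``early_lick`` trials were
    aborted and are excluded from analyses by default.
    """

    trial_id: int
    visual_onset_s: float
    auditory_onset_s: float
    whisker_onset_s: Optional[float] = None
    outcome: str = "miss"
    first_lick_s: Optional[float] = None
    light_on: bool = False

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"Trial {self.trial_id}: invalid outcome {self.outcome!r}")
        if not self.visual_onset_s < self.auditory_onset_s:
            raise ValidationError(
                f"Trial {self.trial_id}: visual onset must precede auditory onset")
        if self.whisker_onset_s is not None:
            if not (self.visual_onset_s < self.whisker_onset_s < self.auditory_onset_s):
                raise ValidationError(
                    f"Trial {self.trial_id}: whisker onset must lie strictly "
                    f"between visual and auditory onsets")
        if self.outcome in ("hit", "miss") and self.whisker_onset_s is None:
            raise ValidationError(
                f"Trial {self.trial_id}: outcome {self.outcome!r} requires a whisker stimulus")
        if self.outcome in ("CR", "FA") and self.whisker_onset_s is not None:
            raise ValidationError(
                f"Trial {self.trial_id}: outcome {self.outcome!r} requires no whisker stimulus")

    @property
    def has_whisker(self) -> bool:
        return self.whisker_onset_s is not None

    def event_time(self, reference: str) -> Optional[float]:
        """Absolute time of a named reference event, or None if absent."""
        if reference == "visual":
            return self.visual_onset_s
        if reference == "whisker":
            return self.whisker_onset_s
        if reference == "auditory":
            return self.auditory_onset_s
        raise ValueError(f"unknown reference event {reference!r}")


@dataclass
class TrialTable:
    trials: list[Trial] = field(default_factory=list)
    session_id: str = "session"
    group: str = "Expert"  # Novice | Expert

    def validate(self) -> None:
        for t in self.trials:
            t.validate()
        onsets = [t.visual_onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError(
                f"TrialTable {self.session_id}: trial onsets must be increasing")

    def select(self, outcomes: Optional[Sequence[str]] = None,
               require_event: Optional[str] = None,
               include_early_lick: bool = False,
               light_on: Optional[bool] = None) -> list[Trial]:
        """Filter trials.  Aborted early-lick trials are dropped by default."""
        out = []
        for t in self.trials:
            if not include_early_lick and t.outcome == "early_lick":
                continue
            if outcomes is not None and t.outcome not in outcomes:
                continue
            if require_event is not None and t.event_time(require_event) is None:
                continue
            if light_on is not None and t.light_on != light_on:
                continue
            out.append(t)
        return out

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class Session:
    units: list[Unit] = field(default_factory=list)
    trial_table: TrialTable = field(default_factory=TrialTable)
    light_pulses_s: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.light_pulses_s is not None:
            self.light_pulses_s = np.asarray(self.light_pulses_s, dtype=float)

    def validate(self, areas: Sequence[str] = DEFAULT_AREAS,
                 layers: Sequence[str] = DEFAULT_LAYERS) -> None:
        self.trial_table.validate()
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"Session: duplicate unit_ids {dupes}")
        for u in self.units:
            u.validate(areas=areas, layers=layers)
        if self.light_pulses_s is not None and self.light_pulses_s.size > 1:
            if not np.all(np.diff(self.light_pulses_s) > 0):
                raise ValidationError("Session: light pulses must be strictly increasing")

    def units_by(self, area: Optional[str] = None,
                 cell_class: Optional[str] = None) -> list[Unit]:
        out = self.units
        if area is not None:
            out = [u for u in out if u.area == area]
        if cell_class is not None:
            out = [u for u in out if u.cell_class == cell_class]
        return out


# ---------------------------------------------------------------------------
# Analysis-window configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisWindow:
    """A named response window paired with its baseline, both relative to a
    reference task event (seconds, half-open intervals)."""

    response: tuple[float, float]
    baseline: tuple[float, float]
    reference: str = "whisker"
    sigma_s: float = 0.010  # PSTH smoothing for this analysis

    def __post_init__(self):
        if self.response[1] <= self.response[0]:
            raise ValidationError("AnalysisWindow: response end must exceed start")
        if self.baseline[1] <= self.baseline[0]:
            raise ValidationError("AnalysisWindow: baseline end must exceed start")
        if self.sigma_s < 0:
            raise ValidationError("AnalysisWindow: sigma must be >= 0")

    @property
    def response_duration(self) -> float:
        return self.response[1] - self.response[0]

    @property
    def baseline_duration(self) -> float:
        return self.baseline[1] - self.baseline[0]


@dataclass
class WindowConfig:
    """Named analysis windows plus the significance thresholds they pair with.

    ``alpha_modulation`` is the per-direction level used when counting
    positively/negatively modulated units in broad population summaries;
    ``alpha_modulation_strict`` is the stricter level used for the
    area-specific window analyses; ``alpha_latency`` gates the latency
    responsiveness test.
    """

    windows: dict[str, AnalysisWindow] = field(default_factory=dict)
    alpha_modulation: float = 0.025
    alpha_modulation_strict: float = 0.005
    alpha_latency: float = 0.05

    def lookup(self, name: str) -> AnalysisWindow:
        try:
            return self.windows[name]
        except KeyError:
            raise KeyError(f"no analysis window named {name!r}; "
                           f"known: {sorted(self.windows)}") from None


def default_window_config() -> WindowConfig:
    """Window table used throughout the analyses (seconds, relative to the
    reference event; baselines mirror the response-window durations).

    Fast sensory windows in wS1/wS2 (first 50 ms), an all-area early window
    (first 100 ms), early motor windows in wM1/wM2 (10-90 ms), an orofacial
    window in tjM1 (40-90 ms), the delay window in ALM (200-1,000 ms), and
    the late secondary-response window in wS1/wS2 (150-350 ms).
    """
    w: dict[str, AnalysisWindow] = {}
    for area in ("wS1", "wS2"):
        w[f"{area}_fast"] = AnalysisWindow((0.0, 0.050), (-0.050, 0.0), sigma_s=0.005)
        w[f"{area}_late"] = AnalysisWindow((0.150, 0.350), (-0.200, 0.0))
    for area in DEFAULT_AREAS:
        w[f"{area}_early"] = AnalysisWindow((0.0, 0.100), (-0.100, 0.0))
    for area in ("wM1", "wM2"):
        w[f"{area}_early"] = AnalysisWindow((0.010, 0.090), (-0.080, 0.0))
    w["tjM1_early"] = AnalysisWindow((0.040, 0.090), (-0.050, 0.0))
    w["ALM_delay"] = AnalysisWindow((0.200, 1.000), (-0.800, 0.0))
    # trial-by-trial correlation windows for the connectivity analyses
    for area in ("wS1", "wS2"):
        w[f"{area}_corr"] = AnalysisWindow((0.005, 0.055), (-0.050, 0.0))
    for area in ("wM1", "wM2"):
        w[f"{area}_corr"] = AnalysisWindow((0.010, 0.090), (-0.080, 0.0))
    return WindowConfig(windows=w)


# ---------------------------------------------------------------------------
# Session directory I/O (plain-text CSV tables)
# ---------------------------------------------------------------------------

_FLOAT_FMT = f"%.{TIME_DECIMALS}f"


def _round_time(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(float(x), TIME_DECIMALS)


def save_session(session: Session, directory: str) -> None:
    """Write a Session as CSV tables (units, spikes, trials, waveforms and,
    when present, light pulses).  ``load_session`` inverts this exactly for
    times at microsecond precision."""
    session.validate()
    os.makedirs(directory, exist_ok=True)

    units = pd.DataFrame(
        [{"unit_id": u.unit_id, "area": u.area, "layer": u.layer,
          "assigned_site": u.assigned_site, "spike_width_ms": u.spike_width_ms,
          "cell_class": u.cell_class, "baseline_rate_hz": u.baseline_rate_hz}
         for u in session.units],
        columns=["unit_id", "area", "layer", "assigned_site",
                 "spike_width_ms", "cell_class", "baseline_rate_hz"])
    units.to_csv(os.path.join(directory, "units.csv"), index=False,
                 float_format=_FLOAT_FMT)

    spike_rows = [(u.unit_id, t) for u in session.units for t in u.spike_times]
    spikes = pd.DataFrame(spike_rows, columns=["unit_id", "time_s"])
    spikes.to_csv(os.path.join(directory, "spikes.csv"), index=False,
                  float_format=_FLOAT_FMT)

    trials = pd.DataFrame(
        [{"trial_id": t.trial_id, "visual_onset_s": t.visual_onset_s,
          "whisker_onset_s": t.whisker_onset_s,
          "auditory_onset_s": t.auditory_onset_s, "outcome": t.outcome,
          "first_lick_s": t.first_lick_s, "light_on": t.light_on}
         for t in session.trial_table.trials],
        columns=["trial_id", "visual_onset_s", "whisker_onset_s",
                 "auditory_onset_s", "outcome", "first_lick_s", "light_on"])
    trials.to_csv(os.path.join(directory, "trials.csv"), index=False,
                  float_format=_FLOAT_FMT)

    wf_rows = []
    for u in session.units:
        for wf in u.waveform_per_site:
            for i, v in enumerate(wf.samples):
                wf_rows.append((u.unit_id, wf.site_index, i, v,
                                wf.sampling_rate))
    waveforms = pd.DataFrame(
        wf_rows, columns=["unit_id", "site_index", "sample_index", "value",
                          "sampling_rate"])
    waveforms.to_csv(os.path.join(directory, "waveforms.csv"), index=False)

    meta = pd.DataFrame([{"session_id": session.trial_table.session_id,
                          "group": session.trial_table.group}])
    meta.to_csv(os.path.join(directory, "session.csv"), index=False)

    if session.light_pulses_s is not None:
        pulses = pd.DataFrame({"onset_s": np.sort(session.light_pulses_s)})
        pulses.to_csv(os.path.join(directory, "light_pulses.csv"), index=False,
                      float_format=_FLOAT_FMT)


def _require(directory: str, name: str) -> str:
    path = os.path.join(directory, name)
    if not os.path.isfile(path):
        raise FormatError(f"session directory {directory!r} is missing {name}")
    return path


def load_session(directory: str,
                 areas: Sequence[str] = DEFAULT_AREAS,
                 layers: Sequence[str] = DEFAULT_LAYERS) -> Session:
    """Read a session directory written by :func:`save_session`.

    Raises :class:`FormatError` for missing files and
    :class:`ValidationError` (naming the record) for invariant violations.
    """
    units_df = pd.read_csv(_require(directory, "units.csv"),
                           dtype={"unit_id": str})
    spikes_df = pd.read_csv(_require(directory, "spikes.csv"),
                            dtype={"unit_id": str})
    trials_df = pd.read_csv(_require(directory, "trials.csv"))
    wf_df = pd.read_csv(_require(directory, "waveforms.csv"),
                        dtype={"unit_id": str})
    meta_path = os.path.join(directory, "session.csv")
    session_id, group = "session", "Expert"
    if os.path.isfile(meta_path):
        meta = pd.read_csv(meta_path)
        if len(meta):
            session_id = str(meta["session_id"].iloc[0])
            group = str(meta["group"].iloc[0])

    known = set(units_df["unit_id"])
    unknown = sorted(set(spikes_df["unit_id"]) - known)
    if unknown:
        raise ValidationError(f"spikes.csv references unknown unit_ids {unknown}")
    unknown_wf = sorted(set(wf_df["unit_id"]) - known)
    if unknown_wf:
        raise ValidationError(f"waveforms.csv references unknown unit_ids {unknown_wf}")

    spikes_by_unit = {uid: g["time_s"].to_numpy(dtype=float)
                      for uid, g in spikes_df.groupby("unit_id", sort=False)}
    wf_by_unit: dict[str, list[Waveform]] = {}
    if len(wf_df):
        for (uid, site), g in wf_df.groupby(["unit_id", "site_index"], sort=True):
            g = g.sort_values("sample_index")
            wf_by_unit.setdefault(uid, []).append(
                Waveform(samples=g["value"].to_numpy(dtype=float),
                         sampling_rate=float(g["sampling_rate"].iloc[0]),
                         site_index=int(site)))

    units = []
    for row in units_df.itertuples(index=False):
        units.append(Unit(
            unit_id=row.unit_id, area=row.area, layer=row.layer,
            spike_times=np.sort(spikes_by_unit.get(row.unit_id, np.empty(0))),
            waveform_per_site=wf_by_unit.get(row.unit_id, []),
            assigned_site=int(row.assigned_site),
            spike_width_ms=float(row.spike_width_ms),
            cell_class=str(row.cell_class),
            baseline_rate_hz=float(row.baseline_rate_hz)))

    def _opt(x):
        return None if pd.isna(x) else float(x)

    trials = []
    for row in trials_df.itertuples(index=False):
        trials.append(Trial(
            trial_id=int(row.trial_id),
            visual_onset_s=float(row.visual_onset_s),
            whisker_onset_s=_opt(row.whisker_onset_s),
            auditory_onset_s=float(row.auditory_onset_s),
            outcome=str(row.outcome),
            first_lick_s=_opt(row.first_lick_s),
            light_on=bool(row.light_on)))

    light = None
    pulses_path = os.path.join(directory, "light_pulses.csv")
    if os.path.isfile(pulses_path):
        light = pd.read_csv(pulses_path)["onset_s"].to_numpy(dtype=float)

    session = Session(units=units,
                      trial_table=TrialTable(trials=trials,
                                             session_id=session_id, group=group),
                      light_pulses_s=light)
    session.validate(areas=areas, layers=layers)
    return session


def sessions_equal(a: Session, b: Session, time_tol: float = 10 ** -TIME_DECIMALS) -> bool:
    """Field-by-field equality of two sessions, times compared at 1 µs."""
    if len(a.units) != len(b.units) or len(a.trial_table) != len(b.trial_table):
        return False
    for ua, ub in zip(a.units, b.units):
        if (ua.unit_id, ua.area, ua.layer, ua.cell_class) != \
                (ub.unit_id, ub.area, ub.layer, ub.cell_class):
            return False
        if ua.spike_times.size != ub.spike_times.size:
            return False
        if ua.spike_times.size and np.max(np.abs(ua.spike_times - ub.spike_times)) > time_tol:
            return False
    for ta, tb in zip(a.trial_table.trials, b.trial_table.trials):
        da, db = dataclasses.asdict(ta), dataclasses.asdict(tb)
        for k in da:
            va, vb = da[k], db[k]
            if isinstance(va, float) and isinstance(vb, float):
                if abs(va - vb) > time_tol:
                    return False
            elif va != vb:
                return False
    return True
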