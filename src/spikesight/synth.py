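"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the analyses assume:
log-normally distributed baseline rates per cell class, a bimodal
spike-width distribution (narrow FS, broad RS), area- and class-specific
whisker-evoked transients with class-specific onset latencies, delay-period
activity, evoked suppression, opto-tagging light responses, and injected
short-lag monosynaptic couplings.

Units fire as inhomogeneous Poisson processes simulated by thinning:
``r(t) = rectify(baseline + sum of active templates)``, with whisker-aligned
templates present only in stimulus trials.  The evoked kernel is a
difference of exponentials (5-ms rise, 20-ms decay by default) shifted by
the template onset latency; its amplitude parametrizes the *mean added
rate over the template's quantification window*, so window-based evoked
estimates recover the configured amplitude directly.  Suppression templates
carry negative amplitudes and the total rate is rectified at zero.

Randomness uses one master seed; every unit draws from its own counter-based
substream, so adding units or trials does not perturb existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (DEFAULT_AREAS, Session, Trial, TrialTable, Unit, Waveform,
                   classify_width)
from .errors import ConfigError

# Minimal separation enforced between successive spikes.  Kept an order of
# magnitude below a physiological refractory period on purpose: the trains
# are Poisson by contract and a longer dead time would thin high-rate
# transients.  Its only job is to keep spike_times strictly increasing at
# the serialized microsecond precision.
MIN_SEPARATION_S = 0.0001


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvokedTemplate:
    """One additive rate transient aligned to a task event.

    ``amplitude_hz`` is the mean rate added over ``norm_window_ms`` (so a
    window-based evoked-response estimate over that window recovers it);
    negative amplitudes model evoked suppression.
    """

    amplitude_hz: float
    latency_ms: float
    rise_ms: float = 5.0
    decay_ms: float = 20.0
    norm_window_ms: tuple[float, float] = (0.0, 100.0)
    align: str = "whisker"
    outcomes: tuple[str, ...] = ("hit", "miss")

    def _kernel(self, u: np.ndarray) -> np.ndarray:
        """Unnormalized difference-of-exponentials, u in s after onset."""
        tr, td = self.rise_ms / 1000.0, self.decay_ms / 1000.0
        out = np.where(u >= 0, np.exp(-np.maximum(u, 0) / td)
                       - np.exp(-np.maximum(u, 0) / tr), 0.0)
        return out

    @property
    def scale(self) -> float:
        """Scale factor mapping the kernel to amplitude_hz window-mean."""
        grid = np.arange(self.norm_window_ms[0], self.norm_window_ms[1],
                         1.0) / 1000.0
        mean_k = float(self._kernel(grid - self.latency_ms / 1000.0).mean())
        if mean_k <= 0:
            raise ConfigError("template latency leaves no mass in its "
                              "normalization window")
        return self.amplitude_hz / mean_k

    @property
    def span_s(self) -> float:
        """Support used for rate evaluation (onset to ~8 decay constants)."""
        return self.latency_ms / 1000.0 + 8.0 * self.decay_ms / 1000.0

    @property
    def peak_hz(self) -> float:
        tr, td = self.rise_ms / 1000.0, self.decay_ms / 1000.0
        u_star = tr * td / (td - tr) * math.log(td / tr) if td != tr else tr
        return self.scale * float(self._kernel(np.array([u_star]))[0])

    def rate_at(self, u: np.ndarray) -> np.ndarray:
        """Added rate (Hz) at u seconds after the alignment event."""
        return self.scale * self._kernel(u - self.latency_ms / 1000.0)


@dataclass(frozen=True)
class Connection:
    pre_unit: str
    post_unit: str
    efficacy: float
    delay_ms: float = 3.0
    jitter_ms: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.efficacy <= 1.0:
            raise ConfigError("connection efficacy must lie in [0, 1]")
        if self.delay_ms <= 0:
            raise ConfigError("connection delay must be > 0 ms")


@dataclass(frozen=True)
class OptoConfig:
    """Blue-light pulse-train protocol and unit light responses.

    Trains are 600-ms, 100-Hz pulse trains (50% duty cycle); one train per
    'trial'.  Ground-truth GABAergic (tagged) units respond to each train
    onset with a reliable short-latency first spike and an elevated rate for
    the train duration; other units are suppressed by a multiplicative
    factor during the light.
    """

    n_trains: int = 50
    train_period_s: float = 5.0
    train_duration_s: float = 0.6
    pulse_rate_hz: float = 100.0
    duty_cycle: float = 0.5
    tagged_latency_ms: float = 2.0
    tagged_jitter_ms: float = 0.3
    tagged_fidelity: float = 0.9
    tagged_rate_factor: float = 8.0
    suppression_factor: float = 0.4
    tagged_classes: tuple[str, ...] = ("FS",)

    def __post_init__(self):
        if self.n_trains < 1:
            raise ConfigError("opto config needs >= 1 train")
        if not 0.0 <= self.tagged_fidelity <= 1.0:
            raise ConfigError("fidelity must lie in [0, 1]")
        if self.suppression_factor < 0 or self.tagged_rate_factor < 0:
            raise ConfigError("rate factors must be >= 0")


def default_templates(group: str) -> dict[tuple[str, str], tuple[EvokedTemplate, ...]]:
    """Area x class evoked templates for one training group.

    Amplitudes are the group's grand-average window deltas (Hz): fast
    sensory responses in wS1/wS2, early motor responses in wM1/wM2 with the
    learning-related RS/FS reversal, evoked suppression in tjM1, and ALM
    delay activity that emerges with training.  FS onset latencies lead RS
    within each area; sensory areas lead motor areas.
    """
    novice = group == "Novice"

    def t(amp_n, amp_e, lat, win, **kw):
        return EvokedTemplate(amplitude_hz=amp_n if novice else amp_e,
                              latency_ms=lat, norm_window_ms=win, **kw)

    delay_kw = dict(rise_ms=60.0, decay_ms=500.0)
    return {
        ("wS1", "RS"): (t(6.0, 5.3, 8.0, (0.0, 50.0)),),
        ("wS1", "FS"): (t(13.9, 11.9, 6.0, (0.0, 50.0)),),
        ("wS2", "RS"): (t(4.0, 4.3, 11.0, (0.0, 50.0)),),
        ("wS2", "FS"): (t(12.2, 11.5, 8.5, (0.0, 50.0)),),
        ("wM1", "RS"): (t(1.8, 0.9, 22.0, (10.0, 90.0)),),
        ("wM1", "FS"): (t(3.1, 7.3, 17.0, (10.0, 90.0)),),
        ("wM2", "RS"): (t(1.0, 1.5, 28.0, (10.0, 90.0)),),
        ("wM2", "FS"): (t(4.5, 2.7, 23.0, (10.0, 90.0)),),
        ("tjM1", "RS"): (t(0.0, -0.6, 40.0, (40.0, 90.0)),),
        ("tjM1", "FS"): (t(-0.2, -1.5, 40.0, (40.0, 90.0)),),
        ("ALM", "RS"): (t(0.1, 1.4, 120.0, (200.0, 1000.0), **delay_kw),),
        ("ALM", "FS"): (t(0.2, 3.7, 120.0, (200.0, 1000.0), **delay_kw),),
    }


@dataclass
class SimConfig:
    """Full description of one synthetic session."""

    group: str = "Expert"
    session_id: str = "synthetic"
    n_units: dict[tuple[str, str], int] = field(default_factory=dict)
    trial_counts: dict[str, int] = field(
        default_factory=lambda: {"hit": 40, "miss": 10, "CR": 40, "FA": 10})
    #: per-class (mu_log, sigma_log) of the log-normal baseline rates
    baseline_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"RS": (0.9, 1.0), "FS": (1.9, 0.8)})
    #: per-class (mean, sd) of spike width in ms
    width_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"RS": (0.55, 0.08), "FS": (0.19, 0.02)})
    templates: Optional[dict[tuple[str, str], tuple[EvokedTemplate, ...]]] = None
    connections: tuple[Connection, ...] = ()
    opto: Optional[OptoConfig] = None
    trial_spacing_s: float = 10.0
    whisker_delay_s: float = 1.0
    auditory_delay_s: float = 2.0
    first_trial_onset_s: float = 5.0
    waveform_sampling_rate: float = 30_000.0
    seed: int = 0

    def __post_init__(self):
        if not self.n_units:
            self.n_units = {(a, c): (8 if c == "RS" else 4)
                            for a in DEFAULT_AREAS for c in ("RS", "FS")}
        if self.templates is None:
            self.templates = default_templates(self.group)
        self.validate()

    def validate(self) -> None:
        if any(n < 0 for n in self.n_units.values()):
            raise ConfigError("unit counts must be >= 0")
        if any(n < 0 for n in self.trial_counts.values()):
            raise ConfigError("trial counts must be >= 0")
        for cls, (mu, sigma) in self.baseline_lognormal.items():
            if sigma < 0:
                raise ConfigError(f"{cls}: sigma_log must be >= 0")
        for cls, (mean, sd) in self.width_params.items():
            if mean <= 0 or sd < 0:
                raise ConfigError(f"{cls}: invalid width parameters")


@dataclass
class GroundTruth:
    """Generation-time truth keyed by unit id, the oracle for
    parameter-recovery tests."""

    cell_class: dict[str, str] = field(default_factory=dict)
    spike_width_ms: dict[str, float] = field(default_factory=dict)
    baseline_rate_hz: dict[str, float] = field(default_factory=dict)
    evoked: dict[str, tuple[EvokedTemplate, ...]] = field(default_factory=dict)
    connections: tuple[Connection, ...] = ()
    opto_tagged: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def synth_waveform(width_ms: float, amplitude: float = 1.0,
                   noise_sd: float = 0.0, sampling_rate: float = 30_000.0,
                   seed: Optional[int] = None) -> Waveform:
    """Biphasic waveform whose trough-to-baseline-return time is exactly
    ``width_ms`` (up to linear interpolation) at zero noise.

    The trace is flat at baseline, descends linearly to the trough, then
    rises along a single line that crosses baseline ``width_ms`` after the
    trough and decays back from a small positive overshoot.
    """
    if width_ms <= 0:
        raise ConfigError("width_ms must be > 0")
    if amplitude == 0:
        raise ConfigError("zero amplitude: spike width undefined")
    w = width_ms / 1000.0 * sampling_rate  # width in samples (may be fractional)
    if w < 2:
        raise ConfigError("width shorter than 2 samples at this sampling rate")

    descent = 4
    post = int(math.ceil(w)) + 2  # linear rise, crossing baseline inside
    tail = 8
    body = descent + post + tail + 1
    n_pre = max(12, int(math.ceil(body / 2)))  # keeps baseline segment clean
    n = n_pre + body

    v = np.zeros(n)
    trough = n_pre + descent
    v[n_pre:trough + 1] = -amplitude * np.linspace(0, 1, descent + 1)
    u = np.arange(1, post + 1, dtype=float)
    v[trough + 1:trough + post + 1] = -amplitude * (1.0 - u / w)
    peak_val = v[trough + post]
    v[trough + post + 1:] = peak_val * np.exp(-np.arange(1, tail + 1) / 3.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    return Waveform(samples=v, sampling_rate=sampling_rate, site_index=0)


def inject_connection(pre_spike_times, efficacy: float, delay_ms: float,
                      jitter_ms: float, seed: Optional[int] = None
                      ) -> np.ndarray:
    """Spawn post-synaptic spikes: each pre spike independently produces one
    post spike at ``t + delay + Normal(0, jitter)`` with probability
    ``efficacy``."""
    if not 0.0 <= efficacy <= 1.0:
        raise ConfigError("efficacy must lie in [0, 1]")
    if delay_ms <= 0:
        raise ConfigError("delay_ms must be > 0")
    pre = np.asarray(pre_spike_times, dtype=float)
    rng = np.random.default_rng(seed)
    mask = rng.random(pre.size) < efficacy
    out = pre[mask] + delay_ms / 1000.0
    if jitter_ms > 0:
        out = out + rng.normal(0.0, jitter_ms / 1000.0, size=out.size)
    return np.sort(out)


def thin_poisson(rate_fn, t0: float, t1: float, rate_max: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Exact inhomogeneous-Poisson sampling by thinning a homogeneous
    process at ``rate_max``."""
    if rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    keep = rng.random(n_cand) < rate_fn(cand) / rate_max
    return cand[keep]


def _enforce_separation(times: np.ndarray,
                        min_isi: float = MIN_SEPARATION_S) -> np.ndarray:
    if times.size < 2:
        return times
    keep = np.empty(times.size, dtype=bool)
    keep[0] = True
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last >= min_isi:
            keep[i] = True
            last = times[i]
        else:
            keep[i] = False
    return times[keep]


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _build_trials(config: SimConfig, rng: np.random.Generator) -> TrialTable:
    outcomes = []
    for outcome in ("hit", "miss", "CR", "FA", "early_lick"):
        outcomes += [outcome] * config.trial_counts.get(outcome, 0)
    order = rng.permutation(len(outcomes))
    trials = []
    for i, k in enumerate(order):
        outcome = outcomes[k]
        visual = config.first_trial_onset_s + i * config.trial_spacing_s
        has_whisker = outcome in ("hit", "miss")
        whisker = visual + config.whisker_delay_s if has_whisker else None
        auditory = visual + config.auditory_delay_s
        lick = None
        if outcome in ("hit", "FA"):
            lick = auditory + 0.15 + 0.4 * rng.random()
        elif outcome == "early_lick":
            lick = visual + 0.3 + 0.5 * rng.random()
        trials.append(Trial(trial_id=i, visual_onset_s=visual,
                            whisker_onset_s=whisker, auditory_onset_s=auditory,
                            outcome=outcome, first_lick_s=lick))
    return TrialTable(trials=trials, session_id=config.session_id,
                      group=config.group)


def _unit_rate_fn(baseline: float,
                  templates: Sequence[EvokedTemplate],
                  trial_table: TrialTable):
    """Rectified rate function r(t) = max(0, baseline + active templates)."""
    events = []  # (event_time, template)
    for tpl in templates:
        for t in trial_table.trials:
            if t.outcome not in tpl.outcomes:
                continue
            ev = t.event_time(tpl.align)
            if ev is not None:
                events.append((ev, tpl))
    events.sort(key=lambda e: e[0])
    ev_times = np.array([e[0] for e in events])

    def rate(ts: np.ndarray) -> np.ndarray:
        r = np.full(ts.shape, baseline)
        for ev, tpl in events:
            i0, i1 = np.searchsorted(ts, (ev, ev + tpl.span_s))
            if i1 > i0:
                r[i0:i1] += tpl.rate_at(ts[i0:i1] - ev)
        return np.maximum(r, 0.0)

    return rate


def _make_unit(uid: str, area: str, cls: str, config: SimConfig,
               trial_table: TrialTable, span: tuple[float, float],
               counter: int, rate_factor_fn=None
               ) -> tuple[Unit, float, float]:
    """One unit: width, multi-site waveforms, baseline rate, spike train."""
    rng = _substream(config.seed, 1, counter)
    w_mean, w_sd = config.width_params[cls]
    width = max(0.06, float(rng.normal(w_mean, w_sd)))
    mu, sigma = config.baseline_lognormal[cls]
    baseline = float(np.exp(rng.normal(mu, sigma)))

    templates = config.templates.get((area, cls), ())
    rate = _unit_rate_fn(baseline, templates, trial_table)
    if rate_factor_fn is not None:
        inner = rate
        rate = lambda ts: inner(ts) * rate_factor_fn(ts)
    peak_bound = baseline + sum(max(0.0, tpl.peak_hz) for tpl in templates)
    if rate_factor_fn is not None:
        peak_bound *= rate_factor_fn.max_factor
    spikes = thin_poisson(rate, span[0], span[1], peak_bound, rng)
    spikes = _enforce_separation(spikes)

    site_gains = (0.4, 1.0, 0.5)
    waveforms = []
    for s, gain in enumerate(site_gains):
        wf = synth_waveform(width, amplitude=gain,
                            noise_sd=0.01 * gain,
                            sampling_rate=config.waveform_sampling_rate,
                            seed=int(rng.integers(2 ** 31)))
        wf.site_index = s
        waveforms.append(wf)

    unit = Unit(unit_id=uid, area=area, layer="L5", spike_times=spikes,
                waveform_per_site=waveforms, assigned_site=1,
                spike_width_ms=width, cell_class=classify_width(width),
                baseline_rate_hz=baseline)
    return unit, width, baseline


def generate_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Generate a task session and its ground truth.

    Deterministic given ``config.seed``: the same configuration yields a
    byte-identical session directory.
    """
    config.validate()
    trial_table = _build_trials(config, _substream(config.seed, 0))
    n_trials = len(trial_table)
    span = (0.0, config.first_trial_onset_s
            + max(1, n_trials) * config.trial_spacing_s)

    truth = GroundTruth(connections=tuple(config.connections))
    units: list[Unit] = []
    counter = 0
    for (area, cls) in sorted(config.n_units):
        for j in range(config.n_units[(area, cls)]):
            uid = f"{area}_{cls}{j:02d}"
            unit, width, baseline = _make_unit(uid, area, cls, config,
                                               trial_table, span, counter)
            units.append(unit)
            truth.cell_class[uid] = cls
            truth.spike_width_ms[uid] = width
            truth.baseline_rate_hz[uid] = baseline
            truth.evoked[uid] = config.templates.get((area, cls), ())
            counter += 1

    by_id = {u.unit_id: u for u in units}
    for k, conn in enumerate(config.connections):
        if conn.pre_unit not in by_id or conn.post_unit not in by_id:
            raise ConfigError(f"connection references unknown unit "
                              f"{conn.pre_unit!r} or {conn.post_unit!r}")
        pre = by_id[conn.pre_unit]
        post = by_id[conn.post_unit]
        rng = _substream(config.seed, 2, k)
        extra = inject_connection(pre.spike_times, conn.efficacy,
                                  conn.delay_ms, conn.jitter_ms,
                                  seed=int(rng.integers(2 ** 31)))
        merged = np.sort(np.concatenate([post.spike_times, extra]))
        post.spike_times = _enforce_separation(merged)

    session = Session(units=units, trial_table=trial_table)
    session.validate()
    return session, truth


def generate_opto_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Generate an opto-tagging session with 600-ms 100-Hz light trains.

    Tagged units (ground-truth GABAergic classes) respond to each train with
    a first spike at the configured latency/jitter with the configured
    fidelity, and an elevated rate for the remainder of the train (starting
    after the 10-ms tagging window, so the fast response reflects the
    injected spikes); untagged units have their rate multiplied by the
    suppression factor during the light.
    """
    if config.opto is None:
        raise ConfigError("generate_opto_session needs opto parameters")
    opto = config.opto
    trial_rng = _substream(config.seed, 0)
    # no-stimulus trials interleaved with the light trains
    quiet = replace(config, trial_counts={"CR": opto.n_trains},
                    trial_spacing_s=opto.train_period_s,
                    first_trial_onset_s=0.5)
    trial_table = _build_trials(quiet, trial_rng)
    onsets = np.array([0.5 + k * opto.train_period_s + 3.4
                       for k in range(opto.n_trains)])
    span = (0.0, 0.5 + opto.n_trains * opto.train_period_s)

    def light_factor(factor: float, delay_s: float = 0.0):
        def fn(ts: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(onsets + delay_s, ts) - 1
            idx = np.clip(idx, 0, onsets.size - 1)
            in_light = (ts >= onsets[idx] + delay_s) & \
                       (ts < onsets[idx] + opto.train_duration_s)
            return np.where(in_light, factor, 1.0)
        fn.max_factor = max(factor, 1.0)
        return fn

    truth = GroundTruth()
    units: list[Unit] = []
    counter = 0
    for (area, cls) in sorted(config.n_units):
        for j in range(config.n_units[(area, cls)]):
            uid = f"{area}_{cls}{j:02d}"
            tagged = cls in opto.tagged_classes
            factor = (light_factor(opto.tagged_rate_factor, delay_s=0.010)
                      if tagged else light_factor(opto.suppression_factor))
            unit, width, baseline = _make_unit(
                uid, area, cls, config, trial_table, span, counter,
                rate_factor_fn=factor)
            if tagged:
                rng = _substream(config.seed, 3, counter)
                respond = rng.random(onsets.size) < opto.tagged_fidelity
                jit = (rng.normal(0.0, opto.tagged_jitter_ms, onsets.size)
                       if opto.tagged_jitter_ms > 0 else np.zeros(onsets.size))
                lat = (opto.tagged_latency_ms + jit) / 1000.0
                extra = onsets[respond] + np.maximum(lat[respond], 1e-4)
                merged = np.sort(np.concatenate([unit.spike_times, extra]))
                unit.spike_times = _enforce_separation(merged)
            units.append(unit)
            truth.cell_class[uid] = cls
            truth.spike_width_ms[uid] = width
            truth.baseline_rate_hz[uid] = baseline
            truth.opto_tagged[uid] = tagged
            counter += 1

    session = Session(units=units, trial_table=trial_table,
                      light_pulses_s=onsets)
    session.validate()
    return session, truth
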