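"""End-to-end pipeline: simulate/load sessions, classify units, quantify
task modulation and latency, opto-tag, infer connectivity, and compute
learning-modulation indices, with a machine-readable run report.

The pipeline is driven by a single YAML/JSON configuration with per-stage
sections; every random stage logs its seed and all thresholds carry the
analysis defaults.  Two runs with identical configuration (and seeds)
produce byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as uc
from . import connectivity as conn
from . import latency as lat
from . import lmi as lmi_mod
from . import modulation as mod
from . import opto as opto_mod
from .core import (Session, default_window_config, load_session, save_session)
from .errors import ConfigError, SpikesightError
from .synth import Connection, OptoConfig, SimConfig, generate_opto_session, generate_session

log = logging.getLogger("spikesight")

REPORT_SCHEMA_VERSION = 1


def sim_config_from_dict(d: dict[str, Any]) -> SimConfig:
    """Build a SimConfig from a plain (YAML/JSON) mapping."""
    d = dict(d)
    if "n_units" in d:
        flat = {}
        for area, classes in d["n_units"].items():
            for cls, n in classes.items():
                flat[(area, cls)] = int(n)
        d["n_units"] = flat
    for key in ("baseline_lognormal", "width_params"):
        if key in d:
            d[key] = {cls: tuple(v) for cls, v in d[key].items()}
    if "connections" in d:
        d["connections"] = tuple(Connection(**c) for c in d["connections"])
    if "opto" in d and d["opto"] is not None:
        opto = dict(d["opto"])
        if "tagged_classes" in opto:
            opto["tagged_classes"] = tuple(opto["tagged_classes"])
        d["opto"] = OptoConfig(**opto)
    return SimConfig(**d)


@dataclass
class StageRecord:
    name: str
    status: str = "ok"  # ok | skipped | failed
    n_records: int = 0
    seed: Optional[int] = None
    wall_time_s: float = 0.0
    message: str = ""


@dataclass
class RunReport:
    schema_version: int = REPORT_SCHEMA_VERSION
    config: dict[str, Any] = field(default_factory=dict)
    stages: list[StageRecord] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"schema_version": self.schema_version, "config": self.config,
                "stages": [asdict(s) for s in self.stages],
                "manifest": self.manifest}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Stage implementations (thin wrappers over the library modules)
# ---------------------------------------------------------------------------

def classify_stage(session: Session) -> pd.DataFrame:
    """Annotate every unit from its waveforms; per-area RS/FS fractions."""
    for u in session.units:
        if u.waveform_per_site:
            uc.annotate_unit(u)
        u.baseline_rate_hz = uc.baseline_rate(u, session.trial_table)
    rows = []
    for area in sorted({u.area for u in session.units}):
        area_units = session.units_by(area=area)
        n = len(area_units)
        n_rs = sum(u.cell_class == "RS" for u in area_units)
        n_fs = sum(u.cell_class == "FS" for u in area_units)
        rows.append({"area": area, "n": n, "n_RS": n_rs, "n_FS": n_fs,
                     "n_excluded": n - n_rs - n_fs,
                     "frac_RS": n_rs / n, "frac_FS": n_fs / n})
    return pd.DataFrame(rows)


def modulation_stage(session: Session, alpha: float, n_perm: int,
                     seed: int) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    wc = default_window_config()
    responses = []
    rows = []
    for i, u in enumerate(session.units):
        if u.cell_class == "excluded":
            continue
        window = wc.lookup(f"{u.area}_early" if f"{u.area}_early" in wc.windows
                           else f"{u.area}_fast")
        name = f"{u.area}_early"
        if u.area == "ALM" and "ALM_delay" in wc.windows:
            window, name = wc.lookup("ALM_delay"), "ALM_delay"
        r = mod.evoked_response(u, session.trial_table, window,
                                window_name=name,
                                outcome_filter=("hit", "miss"),
                                alpha=alpha, n_perm=n_perm, seed=seed + i)
        responses.append(r)
        rows.append({"unit_id": r.unit_id, "area": r.area,
                     "cell_class": r.cell_class, "window": r.window_name,
                     "delta_rate_hz": r.delta_rate_hz, "p_value": r.p_value,
                     "direction": r.direction, "n_trials": r.n_trials})
    fractions = mod.modulated_fractions(responses)
    return pd.DataFrame(rows), fractions, responses


def latency_stage(session: Session, n_perm: int, seed: int) -> pd.DataFrame:
    rows = []
    for i, u in enumerate(session.units):
        if u.cell_class == "excluded":
            continue
        fast = u.area in ("wS1", "wS2")
        res = lat.response_latency(
            u, session.trial_table,
            window_ms=100.0 if fast else 200.0,
            sigma_ms=5.0 if fast else 10.0,
            outcome_filter=("hit", "miss"), n_perm=n_perm, seed=seed + i)
        rows.append({"unit_id": u.unit_id, "area": u.area,
                     "cell_class": u.cell_class, "responsive": res.responsive,
                     "latency_ms": res.latency_ms, "mode": res.mode,
                     "window_ms": res.window_ms, "sigma_ms": res.sigma_ms})
    return pd.DataFrame(rows)


def optotag_stage(session: Session, n_perm: int, seed: int) -> pd.DataFrame:
    if session.light_pulses_s is None or session.light_pulses_s.size == 0:
        raise ConfigError("session has no light pulses")
    rows = []
    for i, u in enumerate(session.units):
        m = opto_mod.tag_unit(u, session.light_pulses_s, n_perm=n_perm,
                              seed=seed + i)
        rows.append({"unit_id": u.unit_id, "area": u.area,
                     "cell_class": u.cell_class,
                     "fidelity_pct": m.fidelity_pct,
                     "latency_ms": m.first_spike_latency_ms,
                     "jitter_ms": m.jitter_ms, "omi": m.omi,
                     "omi_p": m.omi_p, "tagged": m.tagged})
    return pd.DataFrame(rows)


def connectivity_stage(session: Session, pairs: list[tuple[str, str]],
                       n_resamples: int, seed: int) -> pd.DataFrame:
    """STTC, trial-by-trial Pearson and jitter-corrected CCG detection for
    sensory->motor unit pairs (reference = sensory RS units)."""
    wc = default_window_config()
    rows = []
    k = 0
    for pre_area, post_area in pairs:
        pre_units = [u for u in session.units_by(area=pre_area)
                     if u.cell_class == "RS"]
        post_units = [u for u in session.units_by(area=post_area)
                      if u.cell_class in ("RS", "FS")]
        win_pre = wc.lookup(f"{pre_area}_corr")
        win_post = wc.lookup(f"{post_area}_corr")
        binned = {}
        for u in pre_units + post_units:
            binned[u.unit_id] = conn.BinnedTrialSpikes.from_unit(
                u, session.trial_table, outcome_filter=("hit", "miss"))
        for pre in pre_units:
            vec_pre = conn.trial_response_vector(
                pre, session.trial_table, win_pre,
                outcome_filter=("hit", "miss"))
            for post in post_units:
                vec_post = conn.trial_response_vector(
                    post, session.trial_table, win_post,
                    outcome_filter=("hit", "miss"))
                pearson_ok = (conn.passes_rate_floor(vec_pre)
                              and conn.passes_rate_floor(vec_post))
                r = conn.pairwise_pearson(vec_pre, vec_post) if pearson_ok \
                    else math.nan

                # trial-averaged STTC in the 1-s window around the whisker
                sttc_vals = []
                whisker_trials = session.trial_table.select(
                    outcomes=("hit", "miss"), require_event="whisker")
                for t in whisker_trials:
                    t0 = t.event_time("whisker")
                    a = pre.spikes_in(t0 - 0.5, t0 + 0.5) - t0
                    b = post.spikes_in(t0 - 0.5, t0 + 0.5) - t0
                    if a.size and b.size:
                        sttc_vals.append(
                            conn.sttc(a, b, interval=(-0.5, 0.5)).value)
                sttc_mean = float(np.mean(sttc_vals)) if sttc_vals else math.nan

                detected, peak, flank_sd = False, math.nan, math.nan
                try:
                    res = conn.jitter_correct(binned[pre.unit_id],
                                              binned[post.unit_id],
                                              n_resamples=n_resamples,
                                              seed=seed + k)
                    detected, peak = conn.detect_connection(res)
                    flank_sd = res.flank_sd
                except SpikesightError:
                    pass
                rows.append({"pre_unit": pre.unit_id, "post_unit": post.unit_id,
                             "pre_area": pre_area, "post_area": post_area,
                             "post_class": post.cell_class,
                             "pearson_r": r, "sttc": sttc_mean,
                             "detected": detected,
                             "peak_lag_ms": peak * 1000.0 if not math.isnan(peak) else math.nan,
                             "flank_sd": flank_sd})
                k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: dict[str, Any] | str,
                 output_dir: Optional[str] = None) -> RunReport:
    """Run the configured stages and write result tables plus report.json.

    ``config`` is a mapping or a path to a YAML/JSON file.  Stage failures
    are isolated: the report carries an error entry and later independent
    stages still run.
    """
    if isinstance(config, str):
        with open(config) as f:
            config = yaml.safe_load(f)
    cfg = dict(config)
    out = output_dir or cfg.get("output_dir", "spikesight_out")
    os.makedirs(out, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    report = RunReport(config=_jsonable(cfg))

    def run_stage(name, fn):
        rec = StageRecord(name=name)
        t0 = time.perf_counter()
        try:
            rec.n_records = fn(rec)
            log.info("stage %s: %d records", name, rec.n_records)
        except SpikesightError as exc:
            rec.status = "failed"
            rec.message = str(exc)
            log.error("stage %s failed: %s", name, exc)
        rec.wall_time_s = round(time.perf_counter() - t0, 3)
        report.stages.append(rec)
        return rec

    sessions: dict[str, Session] = {}
    responses: dict[str, list] = {}

    for group_key in ("novice", "expert"):
        section = cfg.get("simulate", {}).get(group_key) \
            if "simulate" in cfg else None
        load_dir = cfg.get("sessions", {}).get(group_key) \
            if "sessions" in cfg else None
        if section is None and load_dir is None:
            continue

        def make_session(rec, section=section, load_dir=load_dir,
                         group_key=group_key):
            if load_dir is not None:
                sessions[group_key] = load_session(load_dir)
            else:
                sim = sim_config_from_dict(section)
                rec.seed = sim.seed
                gen = generate_opto_session if sim.opto is not None \
                    else generate_session
                session, _ = gen(sim)
                sessions[group_key] = session
                save_session(session,
                             os.path.join(out, f"session_{group_key}"))
            return len(sessions[group_key].units)

        run_stage(f"session_{group_key}", make_session)

    for group_key, session in sessions.items():
        def do_classify(rec, session=session, group_key=group_key):
            table = classify_stage(session)
            _write_csv(table, os.path.join(out, f"rs_fs_fractions_{group_key}.csv"))
            return len(table)

        run_stage(f"classify_{group_key}", do_classify)

        mod_cfg = cfg.get("modulation", {})

        def do_modulation(rec, session=session, group_key=group_key):
            rec.seed = master_seed + 100
            table, fractions, resp = modulation_stage(
                session, alpha=float(mod_cfg.get("alpha", 0.025)),
                n_perm=int(mod_cfg.get("n_perm", 2000)), seed=rec.seed)
            responses[group_key] = resp
            _write_csv(table, os.path.join(out, f"evoked_responses_{group_key}.csv"))
            _write_csv(fractions, os.path.join(out, f"fractions_{group_key}.csv"))
            return len(table)

        run_stage(f"modulation_{group_key}", do_modulation)

        lat_cfg = cfg.get("latency", {})

        def do_latency(rec, session=session, group_key=group_key):
            rec.seed = master_seed + 200
            table = latency_stage(session,
                                  n_perm=int(lat_cfg.get("n_perm", 2000)),
                                  seed=rec.seed)
            _write_csv(table, os.path.join(out, f"latencies_{group_key}.csv"))
            return len(table)

        run_stage(f"latency_{group_key}", do_latency)

        if session.light_pulses_s is not None:
            def do_optotag(rec, session=session, group_key=group_key):
                rec.seed = master_seed + 300
                table = optotag_stage(session, n_perm=2000, seed=rec.seed)
                _write_csv(table, os.path.join(out, f"tag_metrics_{group_key}.csv"))
                return len(table)

            run_stage(f"optotag_{group_key}", do_optotag)

        conn_cfg = cfg.get("connectivity")
        if conn_cfg and conn_cfg.get("pairs"):
            def do_connectivity(rec, session=session, group_key=group_key,
                                conn_cfg=conn_cfg):
                rec.seed = master_seed + 400
                pairs = [tuple(p) for p in conn_cfg["pairs"]]
                table = connectivity_stage(
                    session, pairs,
                    n_resamples=int(conn_cfg.get("n_resamples", 100)),
                    seed=rec.seed)
                _write_csv(table, os.path.join(out, f"pairs_{group_key}.csv"))
                return len(table)

            run_stage(f"connectivity_{group_key}", do_connectivity)
        else:
            report.stages.append(StageRecord(
                name=f"connectivity_{group_key}", status="skipped",
                message="no pairs configured"))

    if "novice" in responses and "expert" in responses:
        def do_lmi(rec):
            records, balances = lmi_mod.lmi_table(responses["novice"],
                                                  responses["expert"])
            _write_csv(lmi_mod.lmi_frame(records), os.path.join(out, "lmi.csv"))
            _write_csv(pd.DataFrame([asdict(b) for b in balances]),
                       os.path.join(out, "ei_balance.csv"))
            return len(records)

        run_stage("lmi", do_lmi)
    else:
        report.stages.append(StageRecord(name="lmi", status="skipped",
                                         message="needs both groups"))

    for name in sorted(os.listdir(out)):
        path = os.path.join(out, name)
        if os.path.isfile(path) and name.endswith(".csv"):
            report.manifest[name] = _sha256(path)
    with open(os.path.join(out, "report.json"), "w") as f:
        json.dump(report.to_dict(), f, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
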