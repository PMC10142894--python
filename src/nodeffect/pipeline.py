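"""End-to-end orchestration: sessions in, group comparison report out.

A run executes, for every session: artifact rejection -> sliding pNN50 ->
event-locked effects + matched nod-free baseline -> pooled three-condition
comparison.  All intermediate tables are written as CSV next to a JSON
report; given the same config, inputs and seed the outputs are identical
apart from the report's ``meta`` block (timestamp).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effect import EffectConfig, EffectResult, baseline_effects, global_trend, nodding_effects
from .errors import ConfigurationError
from .hrv import MetricSeries, compute_pnn50, reject_artifacts
from .io import (Condition, EventTrack, RRISeries, StudyConfig, read_events_csv,
                 read_events_elan_export, read_rri_csv, write_events_csv, write_rri_csv)
from .simulate import SimParams, simulate_cohort

logger = logging.getLogger("nodeffect")


@dataclass
class RunReport:
    """Everything needed to audit and reproduce one pipeline run."""

    config: dict
    sessions: list
    comparison: dict
    version: str = __version__
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "sessions": self.sessions,
                "comparison": self.comparison, "version": self.version,
                "seed": self.seed, "meta": self.meta}


def _sim_params_from_dict(d: dict) -> SimParams:
    known = {f.name for f in fields(SimParams)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown simulate group keys: {sorted(unknown)}")
    if "condition" in d:
        d = {**d, "condition": Condition(d["condition"])}
    if "cue_times" in d and d["cue_times"] is not None:
        d = {**d, "cue_times": list(d["cue_times"])}
    return replace(SimParams(), **d)


def build_sessions(config: StudyConfig) -> list[tuple[RRISeries, EventTrack]]:
    """Load sessions from disk, or simulate the cohort the config describes."""
    if config.simulate is not None:
        block = config.simulate
        try:
            n_per_group = [int(n) for n in block["n_per_group"]]
            templates = [_sim_params_from_dict(dict(g)) for g in block["groups"]]
        except KeyError as exc:
            raise ConfigurationError(f"simulate block missing key {exc}") from exc
        cohort = simulate_cohort(n_per_group, templates, seed=config.seed)
        return [(s.rri, s.events) for s in cohort]
    if not config.sessions:
        raise ConfigurationError("config references zero sessions")
    out = []
    for spec in config.sessions:
        if spec.rri_path is None or spec.events_path is None:
            raise ConfigurationError(f"session {spec.session_id}: missing rri_path/events_path")
        rri = read_rri_csv(spec.rri_path, session_id=spec.session_id)
        if spec.events_format == "elan":
            events = read_events_elan_export(spec.events_path, spec.nod_tier,
                                             spec.sleep_tier, session_id=spec.session_id,
                                             condition=spec.condition, half=spec.half)
        else:
            events = read_events_csv(spec.events_path, session_id=spec.session_id,
                                     condition=spec.condition, half=spec.half)
        out.append((rri, events))
    return out


def analyze_sessions(sessions: list[tuple[RRISeries, EventTrack]],
                     config: StudyConfig):
    """Per-session metrics and effect samples; returns (samples, conditions, summaries)."""
    eff_cfg = EffectConfig(t0_s=config.t0_s, sleep_policy=config.sleep_policy,
                           baseline_stride=config.baseline_stride)
    all_samples = []
    conditions: dict[str, Condition] = {}
    summaries = []
    per_session: dict[str, tuple[MetricSeries, EffectResult, EffectResult]] = {}
    for rri, events in sessions:
        sid = rri.session_id
        conditions[sid] = events.condition
        n_rejected = 0
        if config.artifact_rejection:
            rri, report = reject_artifacts(rri)
            n_rejected = len(report)
        pnn50 = compute_pnn50(rri, window_beats=config.window_beats)
        nod_res = nodding_effects(pnn50, events, eff_cfg)
        base_res = baseline_effects(pnn50, events, eff_cfg)
        all_samples.extend(nod_res.samples)
        all_samples.extend(base_res.samples)
        try:
            n_all = global_trend(pnn50)
        except Exception:
            n_all = float("nan")
        summaries.append({
            "session_id": sid,
            "condition": events.condition.value,
            "half": events.half,
            "n_beats": len(rri),
            "n_rejected_beats": n_rejected,
            "n_nods": len(events.nods),
            "n_nod_effects": len(nod_res),
            "n_nod_exclusions": len(nod_res.exclusions),
            "n_baseline": len(base_res),
            "n_all_per_s": n_all,
            "exclusions": [{"t": t, "reason": r} for t, r in nod_res.exclusions],
        })
        per_session[sid] = (pnn50, nod_res, base_res)
    return all_samples, conditions, summaries, per_session


def effects_to_frame(samples, conditions) -> pd.DataFrame:
    return pd.DataFrame({
        "session_id": [s.session_id for s in samples],
        "condition": [conditions[s.session_id].value for s in samples],
        "kind": [s.kind for s in samples],
        "anchor_t": [s.anchor_t for s in samples],
        "ns": [s.ns for s in samples],
        "n_all": [s.n_all for s in samples],
        "n": [s.n for s in samples],
    })


def run_pipeline(config: StudyConfig, out_dir: str | Path | None = None) -> RunReport:
    """Run the full analysis and write effects CSV + report JSON to out_dir."""
    from .stats import compare_conditions      # local import avoids cycle

    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions = build_sessions(config)
    samples, conditions, summaries, per_session = analyze_sessions(sessions, config)
    comparison = compare_conditions(samples, conditions, alpha=config.alpha,
                                    omnibus_alpha=config.omnibus_alpha)
    df = effects_to_frame(samples, conditions)
    df.to_csv(out / "effects.csv", index=False, float_format="%.10g")
    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    for sid, (pnn50, _, _) in per_session.items():
        pd.DataFrame({"time_s": pnn50.t, "value": pnn50.value,
                      "valid": pnn50.valid.astype(int)}).to_csv(
            metrics_dir / f"{sid}_pnn50.csv", index=False, float_format="%.6f")
    cfg_echo = {k: (v if not isinstance(v, list) else [getattr(s, "__dict__", s) for s in v])
                for k, v in config.__dict__.items()}
    cfg_echo["sessions"] = [dict(d, condition=Condition(d["condition"]).value)
                            for d in cfg_echo.get("sessions", [])]
    report = RunReport(
        config=cfg_echo,
        sessions=summaries,
        comparison=comparison.to_dict(),
        seed=config.seed,
        meta={"created_utc": datetime.now(timezone.utc).isoformat()},
    )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d sessions, %d effect samples -> %s",
                len(sessions), len(samples), out)
    return report


def write_simulated_cohort(cohort, out_dir: str | Path) -> None:
    """Emit one CSV pair per simulated session plus a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = {}
    for s in cohort:
        sid = s.rri.session_id
        write_rri_csv(s.rri, out / f"{sid}_rri.csv")
        write_events_csv(s.events, out / f"{sid}_events.csv")
        truth[sid] = {"effect_delta": s.truth["effect_delta"],
                      "event_windows": s.truth["event_windows"],
                      "n_clamped": s.truth["n_clamped"]}
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def plot_session(pnn50: MetricSeries, events: EventTrack, out: str | Path):
    """Plot the pNN50 trace with nod markers, sleep spans and the global trend.

    Mirrors the per-participant figure style of event-locked HRV analyses:
    metric trace, event onsets as red points on the trace, sleep as shaded
    spans, and the session-wide OLS trend as a dashed line.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tv, vv = pnn50.t_valid, pnn50.value_valid
    if len(tv) == 0:
        raise ConfigurationError("cannot plot an empty metric series")
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(tv, vv, lw=0.8, color="C0", label="pNN50")
    if len(tv) >= 2:
        slope, intercept = np.polyfit(tv, vv, 1)
        ax.plot(tv, intercept + slope * tv, "--", color="C9",
                label=f"trend {slope:+.2e} /s")
    nod_y = np.interp(events.nods, tv, vv) if len(events.nods) else np.zeros(0)
    ax.plot(events.nods, nod_y, "o", ms=5, color="red", label="nod", zorder=5)
    for i, (a, b) in enumerate(events.sleep):
        ax.axvspan(a, b, color="gray", alpha=0.25,
                   label="sleep" if i == 0 else None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pNN50")
    ax.set_title(f"{events.session_id} ({events.condition.value})")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return fig
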