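"""Synthetic study sessions: RR-interval streams plus nod/sleep annotations.

One session emulates a participant watching a lecture segment while wearing a
chest ECG sensor: beat-to-beat RR intervals (RRI) around 700-1000 ms with a
slow baseline drift, low-frequency (Mayer-wave) and high-frequency
(respiratory) sinusoidal modulation, and AR(1) short-term variability.  Nod
events either arrive as a sparse homogeneous Poisson process (spontaneous
nodding) or at explicit cue times (nodding on command).

The ground-truth event effect is injected as a multiplicative change of the
AR innovation scale — ``sd_noise_ms * (1 + effect_delta)`` — for
``effect_duration_s`` after each nod onset (overlapping windows take their
union).  Because pNN50 is driven by successive-difference variability, a
negative ``effect_delta`` lowers pNN50 inside the window, mimicking
parasympathetic suppression (arousal); a positive one raises it.  The
injected windows are recorded in ``SimSession.truth`` so downstream
estimators can be validated against known signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .io import Condition, EventTrack, RRISeries

#: physiological clamp bounds for a single inter-beat interval, ms
RRI_BOUNDS_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated session.

    ``drift`` is either a constant baseline slope (ms per s) or a sequence of
    ``(time_s, offset_ms)`` knots interpolated piecewise-linearly and added
    to ``mean_rri_ms``.  For the forced condition supply ``cue_times`` (or
    ``cue_period_s`` to cue periodically); otherwise spontaneous nods are
    drawn as a Poisson process at ``nod_rate_per_min``.
    """

    duration_s: float = 3600.0
    mean_rri_ms: float = 850.0
    drift: float | Sequence[tuple[float, float]] = 0.0
    sd_noise_ms: float = 25.0
    ar_coeff: float = 0.3
    lf_amp_ms: float = 15.0
    lf_freq_hz: float = 0.095
    hf_amp_ms: float = 20.0
    hf_freq_hz: float = 0.28
    lf_phase: float | None = None      # None: drawn uniform per session
    hf_phase: float | None = None
    nod_rate_per_min: float = 0.3
    cue_times: Sequence[float] | None = None
    cue_period_s: float | None = None
    effect_delta: float = 0.0
    effect_duration_s: float = 60.0
    sleep_intervals: Sequence[tuple[float, float]] = field(default_factory=tuple)
    condition: Condition = Condition.WITH_VIDEO_NOT_FORCED
    session_id: str = "sim"
    half: str = "second"
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s < 0:
            raise ParameterError(f"duration_s must be >= 0, got {self.duration_s}")
        if self.sd_noise_ms < 0:
            raise ParameterError(f"sd_noise_ms must be >= 0, got {self.sd_noise_ms}")
        if not (0 <= self.ar_coeff < 1):
            raise ParameterError(f"ar_coeff must be in [0, 1), got {self.ar_coeff}")
        if self.effect_duration_s <= 0:
            raise ParameterError(f"effect_duration_s must be > 0, got {self.effect_duration_s}")
        if not (-1 <= self.effect_delta <= 1):
            raise ParameterError(f"effect_delta must be in [-1, 1], got {self.effect_delta}")
        for name in ("lf_freq_hz", "hf_freq_hz"):
            f = getattr(self, name)
            if not (0 < f < 0.5):
                raise ParameterError(f"{name} must be in (0, 0.5) Hz, got {f}")
        if self.nod_rate_per_min < 0:
            raise ParameterError(f"nod_rate_per_min must be >= 0, got {self.nod_rate_per_min}")


@dataclass(frozen=True)
class SimSession:
    """A simulated session plus the ground truth used to generate it."""

    rri: RRISeries
    events: EventTrack
    truth: dict


def _baseline(params: SimParams, t: float) -> float:
    if isinstance(params.drift, (int, float)):
        return params.mean_rri_ms + float(params.drift) * t
    knots = np.asarray(params.drift, dtype=float)
    return params.mean_rri_ms + float(np.interp(t, knots[:, 0], knots[:, 1]))


def _merge_windows(starts: np.ndarray, dur: float) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for s in np.sort(starts):
        a, b = float(s), float(s) + dur
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _draw_events(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.cue_times is not None:
        cues = np.asarray(params.cue_times, dtype=float)
        return cues[(cues >= 0) & (cues <= params.duration_s)]
    if params.cue_period_s is not None:
        return np.arange(params.cue_period_s, params.duration_s, params.cue_period_s)
    rate_per_s = params.nod_rate_per_min / 60.0
    if rate_per_s == 0 or params.duration_s == 0:
        return np.zeros(0)
    # homogeneous Poisson process: exponential inter-event gaps
    n_cap = max(16, int(3 * rate_per_s * params.duration_s + 30))
    gaps = rng.exponential(1.0 / rate_per_s, size=n_cap)
    times = np.cumsum(gaps)
    while times[-1] < params.duration_s:
        gaps = rng.exponential(1.0 / rate_per_s, size=n_cap)
        times = np.concatenate([times, times[-1] + np.cumsum(gaps)])
    return times[times < params.duration_s]


def simulate_session(params: SimParams) -> SimSession:
    """Generate one session; deterministic given ``params.seed``.

    Beat times are cumulative sums of the generated RRIs.  Each RRI is
    baseline(t) + LF/HF sinusoids + AR(1) noise, rounded to integer ms (the
    sensor's 1 kHz ECG resolution) and clamped to physiological bounds.  The
    AR innovation applied to the interval starting at time t is scaled by
    ``1 + effect_delta`` when t lies inside any event effect window.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    # stream order is fixed (phases, events, then beat noise) for determinism
    lf_ph = rng.uniform(0, 2 * math.pi) if params.lf_phase is None else params.lf_phase
    hf_ph = rng.uniform(0, 2 * math.pi) if params.hf_phase is None else params.hf_phase
    events = _draw_events(params, rng)
    windows = _merge_windows(events, params.effect_duration_s)

    lo, hi = RRI_BOUNDS_MS
    sin = math.sin
    lf_w = 2.0 * math.pi * params.lf_freq_hz
    hf_w = 2.0 * math.pi * params.hf_freq_hz
    lf_a, hf_a = params.lf_amp_ms, params.hf_amp_ms
    ar, sd = params.ar_coeff, params.sd_noise_ms
    scale_in = sd * (1.0 + params.effect_delta)
    flat_drift = isinstance(params.drift, (int, float))
    mean_plus_slope = params.mean_rri_ms
    slope = float(params.drift) if flat_drift else 0.0

    rri: list[float] = []
    t = 0.0
    x = 0.0
    n_clamped = 0
    widx = 0
    chunk = rng.standard_normal(4096).tolist()
    ci = 0
    n_chunk = len(chunk)
    while t < params.duration_s:
        while widx < len(windows) and t >= windows[widx][1]:
            widx += 1
        in_window = widx < len(windows) and windows[widx][0] <= t
        if ci >= n_chunk:
            chunk = rng.standard_normal(4096).tolist()
            ci = 0
        x = ar * x + (scale_in if in_window else sd) * chunk[ci]
        ci += 1
        base = mean_plus_slope + slope * t if flat_drift else _baseline(params, t)
        r = base + lf_a * sin(lf_w * t + lf_ph) + hf_a * sin(hf_w * t + hf_ph) + x
        rc = r if lo <= r <= hi else (lo if r < lo else hi)
        if rc != r:
            n_clamped += 1
        rc = round(rc)
        t += rc / 1000.0
        rri.append(rc)
    rri_arr = np.asarray(rri, dtype=float)
    t_arr = np.cumsum(rri_arr) / 1000.0
    series = RRISeries(params.session_id, t_arr, rri_arr)
    track = EventTrack(session_id=params.session_id, condition=params.condition,
                       nods=events, sleep=list(params.sleep_intervals), half=params.half)
    truth = {
        "effect_delta": params.effect_delta,
        "event_windows": [(float(e), float(e) + params.effect_duration_s) for e in track.nods],
        "merged_windows": windows,
        "n_clamped": n_clamped,
    }
    return SimSession(rri=series, events=track, truth=truth)


def study_templates(duration_s: float = 3600.0,
                    effect_delta_not_forced: float = -0.3,
                    effect_delta_forced: float = 0.3,
                    nod_rate_per_min: float = 0.5,
                    cue_period_s: float = 120.0,
                    **common) -> list[SimParams]:
    """The three condition templates of the study design, one session = one
    60-minute lecture half.

    * no-nodding-video: no nods (this group supplies the nod-free baseline
      pool; spontaneous nodding without any prompt is rare).
    * with-video / not forced: sparse spontaneous nods, Poisson at
      ``nod_rate_per_min`` (default 0.5/min, ~30 per half), each lowering
      successive-difference variability (``effect_delta_not_forced`` < 0,
      the arousal direction).
    * with-video / forced: cued nods every ``cue_period_s`` (default 120 s,
      ~30 per half) raising variability (``effect_delta_forced`` > 0).

    Cue spacing is kept above ``effect_duration_s``: when consecutive effect
    windows overlap they merge, and a change that covers the whole recording
    has no event-locked signature to recover.
    """
    base = dict(duration_s=duration_s, half="second", **common)
    return [
        SimParams(condition=Condition.NO_NODDING_VIDEO, nod_rate_per_min=0.0,
                  effect_delta=0.0, **base),
        SimParams(condition=Condition.WITH_VIDEO_NOT_FORCED,
                  nod_rate_per_min=nod_rate_per_min,
                  effect_delta=effect_delta_not_forced, **base),
        SimParams(condition=Condition.WITH_VIDEO_FORCED,
                  cue_period_s=cue_period_s,
                  effect_delta=effect_delta_forced, **base),
    ]


def simulate_cohort(n_per_group: Sequence[int],
                    group_params: Sequence[SimParams],
                    seed: int = 0) -> list[SimSession]:
    """Simulate ``n_per_group[i]`` sessions from each template, independently seeded.

    Per-session seeds are spawned reproducibly from the master seed via
    ``numpy.random.SeedSequence``, so distinct sessions get independent
    streams and the whole cohort is a pure function of ``seed``.
    """
    if len(n_per_group) != len(group_params):
        raise ParameterError("n_per_group and group_params must have equal length")
    for n in n_per_group:
        if n < 1:
            raise ParameterError(f"n_per_group entries must be >= 1, got {n}")
    children = np.random.SeedSequence(seed).spawn(int(sum(n_per_group)))
    sessions: list[SimSession] = []
    k = 0
    for n, template in zip(n_per_group, group_params):
        for si in range(n):
            child_seed = int(children[k].generate_state(1)[0])
            k += 1
            p = replace(template, seed=child_seed,
                        session_id=f"{template.condition.value}_{si:02d}")
            sessions.append(simulate_session(p))
    return sessions
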