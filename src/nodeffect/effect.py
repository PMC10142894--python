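"""Event-locked, trend-corrected slope statistics on a pNN50 series.

For a nod at time t the statistic is

    N = Ns - Nall,      Ns = (pNN50(t + t0) - pNN50(t)) / t0

where t0 (default 60 s) is the assumed latency of the autonomic response,
pNN50(x) is the metric sample anchored at the latest valid beat at or before
x, and Nall is the ordinary-least-squares slope of the whole session's pNN50
against time.  Because anchors snap to the beat grid, Ns is divided by the
actual elapsed time between the two anchored samples (= t0 on a regular
grid); this keeps "slope" exact — a perfectly linear series yields
Ns = slope, hence N = 0, at every event time.  Because the pNN50 window is trailing, the sample at t is
computed entirely from pre-nod beats while the sample at t + t0 covers the
minute following the nod; subtracting Nall removes the participant's global
drowsiness/arousal drift.  Negative N means pNN50 is falling faster than the
session trend — read as increased arousal after the event.

The matched baseline applies the identical statistic at probe times far from
any nod, giving the no-event distribution of N for the same recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .hrv import MetricSeries
from .io import EventTrack

logger = logging.getLogger("nodeffect")


@dataclass(frozen=True)
class EffectConfig:
    """Knobs of the event-locked statistic.

    ``baseline_guard_s`` is the nod-free margin required *before* a baseline
    probe (the trailing metric window must not touch a nod); ``None`` means
    "equal to t0_s".  ``sleep_policy='exclude'`` drops samples whose
    [anchor, anchor + t0] span intersects a sleep interval.
    ``baseline_stride`` thins the baseline probe grid (every k-th valid beat).
    """

    t0_s: float = 60.0
    sleep_policy: str = "include"
    baseline_guard_s: float | None = None
    baseline_stride: int = 1

    def __post_init__(self) -> None:
        if self.t0_s <= 0:
            raise ParameterError(f"t0_s must be > 0, got {self.t0_s}")
        if self.baseline_guard_s is not None and self.baseline_guard_s < 0:
            raise ParameterError(f"baseline_guard_s must be >= 0, got {self.baseline_guard_s}")
        if self.sleep_policy not in ("include", "exclude"):
            raise ParameterError(f"sleep_policy must be include|exclude, got {self.sleep_policy!r}")
        if self.baseline_stride < 1:
            raise ParameterError(f"baseline_stride must be >= 1, got {self.baseline_stride}")

    @property
    def guard_s(self) -> float:
        return self.t0_s if self.baseline_guard_s is None else self.baseline_guard_s


@dataclass(frozen=True)
class EffectSample:
    """One event-locked (or baseline) effect value, in units of 1/s."""

    session_id: str
    anchor_t: float
    kind: str                 # "nod" | "baseline"
    ns: float
    n_all: float
    n: float
    t0_s: float

    @property
    def arousal_increasing(self) -> bool:
        """Negative effect = pNN50 falling faster than trend = arousal up."""
        return self.n < 0


@dataclass
class EffectResult:
    """Effect samples plus the per-event exclusion log (nothing is dropped silently)."""

    samples: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)   # (anchor_t, reason)

    def __iter__(self) -> Iterator[EffectSample]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def values(self) -> np.ndarray:
        return np.array([s.n for s in self.samples])


def global_trend(pnn50: MetricSeries) -> float:
    """OLS slope (per second) of pNN50 against time over all valid samples."""
    t, v = pnn50.t_valid, pnn50.value_valid
    if len(t) < 2:
        raise InsufficientDataError(
            f"global trend needs >= 2 valid samples, got {len(t)}")
    return float(np.polyfit(t, v, 1)[0])


def _anchor_indices(tv: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Index of the latest valid sample at or before each x (-1 if none)."""
    return np.searchsorted(tv, x, side="right") - 1


def nod_slope(pnn50: MetricSeries, t: float, t0_s: float = 60.0) -> float:
    """Slope (Ns) of pNN50 from the event time t to t + t0, per second.

    Both anchors resolve to the latest valid sample at or before the
    requested time (no interpolation, so the trailing-window semantics —
    pre-event window at t, post-event window at t + t0 — are preserved).
    """
    if t0_s <= 0:
        raise ParameterError(f"t0_s must be > 0, got {t0_s}")
    tv, vv = pnn50.t_valid, pnn50.value_valid
    if len(tv) == 0:
        raise InsufficientDataError("no valid pNN50 samples")
    if t < tv[0]:
        raise InsufficientDataError(f"anchor {t} s precedes first valid sample at {tv[0]} s")
    if t + t0_s > tv[-1]:
        raise InsufficientDataError(
            f"anchor {t} + t0 {t0_s} s beyond last valid sample at {tv[-1]} s")
    i0, i1 = _anchor_indices(tv, np.array([t, t + t0_s]))
    if i1 == i0:
        raise InsufficientDataError(f"anchors at {t} and {t + t0_s} s resolve to the same sample")
    # slope over the ACTUAL elapsed time between the two anchored samples:
    # on an uneven beat grid this (not the nominal t0) is what makes an
    # exactly linear series give Ns == its slope for every t
    return float((vv[i1] - vv[i0]) / (tv[i1] - tv[i0]))


def _intersects_sleep(track: EventTrack, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Boolean mask: [start, end] span intersects any sleep interval."""
    hit = np.zeros(len(start), dtype=bool)
    for a, b in track.sleep:
        hit |= (start <= b) & (end >= a)
    return hit


def nodding_effects(pnn50: MetricSeries, events: EventTrack,
                    cfg: EffectConfig | None = None) -> EffectResult:
    """One trend-corrected effect sample per includable nod.

    Nods whose anchors cannot be resolved (too close to the recording edges)
    are excluded with a logged reason, never silently; every nod appears
    either in ``samples`` or in ``exclusions``.
    """
    cfg = cfg or EffectConfig()
    result = EffectResult()
    nods = events.nods
    if len(nods) == 0:
        logger.warning("%s: no nods; empty effect list", events.session_id)
        return result
    tv, vv = pnn50.t_valid, pnn50.value_valid
    if len(tv) < 2:
        for t in nods:
            result.exclusions.append((float(t), "fewer than 2 valid pNN50 samples"))
        return result
    n_all = global_trend(pnn50)
    sleep_hit = (_intersects_sleep(events, nods, nods + cfg.t0_s)
                 if cfg.sleep_policy == "exclude" else np.zeros(len(nods), dtype=bool))
    for t, in_sleep in zip(nods, sleep_hit):
        t = float(t)
        if t < tv[0]:
            result.exclusions.append((t, "before first valid pNN50 sample"))
            continue
        if t + cfg.t0_s > tv[-1]:
            result.exclusions.append((t, "t + t0 beyond last valid pNN50 sample"))
            continue
        if in_sleep:
            result.exclusions.append((t, "span intersects sleep interval"))
            continue
        i0, i1 = _anchor_indices(tv, np.array([t, t + cfg.t0_s]))
        if i1 == i0:
            result.exclusions.append((t, "both anchors resolve to the same sample"))
            continue
        ns = float((vv[i1] - vv[i0]) / (tv[i1] - tv[i0]))
        result.samples.append(EffectSample(events.session_id, t, "nod",
                                           ns, n_all, ns - n_all, cfg.t0_s))
    for t, reason in result.exclusions:
        logger.info("%s: nod at %.1f s excluded: %s", events.session_id, t, reason)
    return result


def baseline_effects(pnn50: MetricSeries, events: EventTrack,
                     cfg: EffectConfig | None = None) -> EffectResult:
    """The same statistic evaluated at nod-free probe times.

    Every valid pNN50 sample time s is a candidate probe; s is eligible when
    no nod lies in [s - guard, s + t0] (so neither the trailing window at s
    nor the one at s + t0 overlaps a nod) and both anchors resolve.  With no
    nods in the track, every valid interior sample qualifies.
    """
    cfg = cfg or EffectConfig()
    result = EffectResult()
    tv, vv = pnn50.t_valid, pnn50.value_valid
    if len(tv) < 2:
        logger.warning("%s: fewer than 2 valid pNN50 samples; empty baseline", events.session_id)
        return result
    n_all = global_trend(pnn50)
    probes = tv[:: cfg.baseline_stride]
    pvals = vv[:: cfg.baseline_stride]
    inside = probes + cfg.t0_s <= tv[-1]
    nods = events.nods
    if len(nods):
        n_hit = (np.searchsorted(nods, probes + cfg.t0_s, side="right")
                 - np.searchsorted(nods, probes - cfg.guard_s, side="left"))
        eligible = inside & (n_hit == 0)
    else:
        eligible = inside
    if cfg.sleep_policy == "exclude":
        eligible &= ~_intersects_sleep(events, probes, probes + cfg.t0_s)
    if not eligible.any():
        logger.warning("%s: no eligible nod-free probes; empty baseline", events.session_id)
        return result
    sel = np.nonzero(eligible)[0]
    i1 = _anchor_indices(tv, probes[sel] + cfg.t0_s)
    t1 = tv[i1]
    ok = t1 > probes[sel]       # anchors must be distinct samples
    sel, i1, t1 = sel[ok], i1[ok], t1[ok]
    ns_arr = (vv[i1] - pvals[sel]) / (t1 - probes[sel])
    for s, ns in zip(probes[sel], ns_arr):
        result.samples.append(EffectSample(events.session_id, float(s), "baseline",
                                           float(ns), n_all, float(ns) - n_all, cfg.t0_s))
    return result
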