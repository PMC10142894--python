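"""Reading and writing RR-interval recordings, behavioural annotations and study configs.

All times are seconds from the start of the session recording; RR intervals
(RRI) are milliseconds.  Two plain-text dialects are supported for events:
a simple ``kind,start_s,end_s`` CSV and the tab-delimited export produced by
the ELAN annotation tool ("Export as tab-delimited text").

Event semantics: one annotated interval on the nod tier counts as exactly one
nod, anchored at the interval's begin time — a bout of several head bobs
labelled as a single interval is a single event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger("nodeffect")

#: tolerance (s) for checking that t[k] - t[k-1] matches rri[k]/1000;
#: pairs violating it are treated as gaps (e.g. after artifact rejection)
ADJACENCY_TOL_S = 5e-3


class Condition(str, Enum):
    """The three viewing conditions of the study design."""

    NO_NODDING_VIDEO = "no_nodding_video"
    WITH_VIDEO_NOT_FORCED = "with_video_not_forced"
    WITH_VIDEO_FORCED = "with_video_forced"


@dataclass(frozen=True)
class RRISeries:
    """Time-stamped inter-beat intervals for one continuous recording.

    ``t[k]`` is the occurrence time (s) of beat *k*; ``rri[k]`` is the
    interval (ms) ending at that beat.  A pair of consecutive beats is
    *adjacent* when the time axis is consistent with the interval, i.e.
    ``|t[k] - t[k-1] - rri[k]/1000| <= ADJACENCY_TOL_S``; non-adjacent pairs
    mark gaps (artifact removals) and are skipped by successive-difference
    statistics.
    """

    session_id: str
    t: np.ndarray
    rri: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        rri = np.asarray(self.rri, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "rri", rri)
        if t.shape != rri.shape or t.ndim != 1:
            raise ValidationError("t and rri must be 1-d arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            bad = np.nonzero(np.diff(t) <= 0)[0] + 1
            raise ValidationError(f"beat times not strictly increasing at indices {bad.tolist()[:10]}")
        if len(rri) and np.any(rri <= 0):
            bad = np.nonzero(rri <= 0)[0]
            raise ValidationError(f"non-positive rri at indices {bad.tolist()[:10]}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def pair_adjacent(self) -> np.ndarray:
        """Boolean array of length n-1: True where beats k-1,k are contiguous."""
        if len(self.t) < 2:
            return np.zeros(0, dtype=bool)
        return np.abs(np.diff(self.t) - self.rri[1:] / 1000.0) <= ADJACENCY_TOL_S


def _normalize_sleep(sleep: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sort and merge sleep intervals; reject start >= end."""
    spans = sorted((float(a), float(b)) for a, b in sleep)
    for a, b in spans:
        if a >= b:
            raise ValidationError(f"sleep interval with start >= end: ({a}, {b})")
    merged: list[tuple[float, float]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass(frozen=True)
class EventTrack:
    """Nod onsets and sleep spans for one session, with its condition label."""

    session_id: str
    condition: Condition
    nods: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sleep: list = field(default_factory=list)
    half: str = "second"

    def __post_init__(self) -> None:
        nods = np.unique(np.asarray(self.nods, dtype=float))
        object.__setattr__(self, "nods", nods)
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "sleep", _normalize_sleep(self.sleep))
        if self.half not in ("first", "second"):
            raise ValidationError(f"half must be 'first' or 'second', got {self.half!r}")


# ---------------------------------------------------------------------------
# RRI CSV  (columns: time_s,rri_ms ; time_s optional)
# ---------------------------------------------------------------------------

def read_rri_csv(path: str | Path, session_id: str | None = None,
                 on_invalid: str = "raise") -> RRISeries:
    """Read an RRI recording from CSV.

    The file must carry an ``rri_ms`` column; ``time_s`` is optional and is
    reconstructed as the cumulative sum of ``rri_ms``/1000 when absent.
    Rows breaking time monotonicity are rejected: ``on_invalid='raise'``
    raises, ``'drop'`` removes them with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "rri_ms" not in df.columns:
        raise FormatError(f"{path}: missing required column 'rri_ms'")
    sid = session_id if session_id is not None else path.stem
    rri = df["rri_ms"].to_numpy(dtype=float)
    if len(rri) == 0:
        return RRISeries(sid, np.zeros(0), np.zeros(0))
    bad = np.nonzero(~(rri > 0))[0]
    if len(bad):
        raise ValidationError(f"{path}: non-positive rri_ms at rows {(bad + 2).tolist()[:20]}")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        keep = np.ones(len(t), dtype=bool)
        last = -np.inf
        for k in range(len(t)):
            if t[k] > last:
                last = t[k]
            else:
                keep[k] = False
        if not keep.all():
            rows = (np.nonzero(~keep)[0] + 2).tolist()
            if on_invalid == "drop":
                logger.warning("%s: dropped %d non-monotonic rows: %s", path, len(rows), rows[:20])
                t, rri = t[keep], rri[keep]
            else:
                raise ValidationError(f"{path}: non-monotonic time_s at rows {rows[:20]}")
    else:
        t = np.cumsum(rri) / 1000.0
    return RRISeries(sid, t, rri)


def write_rri_csv(series: RRISeries, path: str | Path) -> None:
    """Write an RRI recording as CSV with ms precision on both columns."""
    df = pd.DataFrame({"time_s": series.t, "rri_ms": series.rri})
    df.to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# Events CSV  (kind,start_s,end_s ; header comments carry session metadata)
# ---------------------------------------------------------------------------

def write_events_csv(track: EventTrack, path: str | Path) -> None:
    """Write nod/sleep events as CSV; session metadata in '#' header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# session_id={track.session_id}\n")
        fh.write(f"# condition={track.condition.value}\n")
        fh.write(f"# half={track.half}\n")
        fh.write("kind,start_s,end_s\n")
        for t in track.nods:
            fh.write(f"nod,{t:.3f},\n")
        for a, b in track.sleep:
            fh.write(f"sleep,{a:.3f},{b:.3f}\n")


def read_events_csv(path: str | Path, session_id: str | None = None,
                    condition: Condition | str | None = None,
                    half: str | None = None) -> EventTrack:
    """Read a ``kind,start_s,end_s`` events CSV.

    Metadata from ``#`` header lines is used unless overridden by arguments.
    Out-of-order nods are sorted and duplicates removed, with a warning.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, int]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("#").strip().split("=", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    nods: list[float] = []
    sleep: list[tuple[float, float]] = []
    header_seen = False
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        line = line.strip()
        if not line:
            continue
        if not header_seen:
            if line.replace(" ", "") != "kind,start_s,end_s":
                raise FormatError(f"{path}:{lineno}: expected header 'kind,start_s,end_s'")
            header_seen = True
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected kind,start_s[,end_s]")
        kind = parts[0]
        try:
            start = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable start_s {parts[1]!r}") from exc
        if kind == "nod":
            nods.append(start)
        elif kind == "sleep":
            if len(parts) < 3 or not parts[2]:
                raise FormatError(f"{path}:{lineno}: sleep row requires end_s")
            try:
                end = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable end_s {parts[2]!r}") from exc
            sleep.append((start, end))
        else:
            raise FormatError(f"{path}:{lineno}: unknown kind {kind!r} (expected nod or sleep)")
    arr = np.asarray(nods, dtype=float)
    if len(arr) > 1 and np.any(np.diff(arr) <= 0):
        n_dup = len(arr) - len(np.unique(arr))
        if n_dup:
            logger.warning("%s: removed %d duplicate nod times", path, n_dup)
        if np.any(np.diff(np.asarray(nods)) < 0):
            logger.warning("%s: nod times out of order; sorted ascending", path)
    sid = session_id or meta.get("session_id") or path.stem
    cond = condition or meta.get("condition") or Condition.NO_NODDING_VIDEO
    return EventTrack(session_id=sid, condition=Condition(cond), nods=arr,
                      sleep=sleep, half=half or meta.get("half", "second"))


# ---------------------------------------------------------------------------
# ELAN tab-delimited export
# ---------------------------------------------------------------------------

def read_events_elan_export(path: str | Path, nod_tier: str, sleep_tier: str | None = None,
                            session_id: str | None = None,
                            condition: Condition | str = Condition.NO_NODDING_VIDEO,
                            half: str = "second") -> EventTrack:
    """Parse an ELAN "Export as tab-delimited text" file into an EventTrack.

    Expected columns per line: tier name, begin time, end time, annotation
    value (tab-separated; times as seconds with millisecond decimals).  Each
    annotated interval on ``nod_tier`` becomes one nod at its begin time;
    intervals on ``sleep_tier`` become sleep spans.
    """
    path = Path(path)
    nods: list[float] = []
    sleep: list[tuple[float, float]] = []
    tiers_seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            tier = parts[0].strip()
            tiers_seen.add(tier)
            if tier != nod_tier and tier != sleep_tier:
                continue
            try:
                begin = float(parts[1])
                end = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable time in {parts[1:3]!r}") from exc
            if tier == nod_tier:
                nods.append(begin)
            else:
                sleep.append((begin, end))
    if tiers_seen and nod_tier not in tiers_seen:
        raise ConfigurationError(
            f"{path}: nod tier {nod_tier!r} not found; tiers present: {sorted(tiers_seen)}")
    if sleep_tier is not None and tiers_seen and sleep_tier not in tiers_seen:
        raise ConfigurationError(
            f"{path}: sleep tier {sleep_tier!r} not found; tiers present: {sorted(tiers_seen)}")
    return EventTrack(session_id=session_id or path.stem, condition=Condition(condition),
                      nods=np.asarray(nods, dtype=float), sleep=sleep, half=half)


# ---------------------------------------------------------------------------
# Study configuration (YAML)
# ---------------------------------------------------------------------------

@dataclass
class SessionSpec:
    session_id: str
    condition: Condition
    half: str = "second"
    rri_path: str | None = None
    events_path: str | None = None
    events_format: str = "csv"          # "csv" or "elan"
    nod_tier: str = "nod"
    sleep_tier: str | None = None


@dataclass
class StudyConfig:
    """Everything needed to run the pipeline on one study.

    Either ``sessions`` references recording/annotation files on disk, or
    ``simulate`` holds a synthetic-cohort block (see :mod:`nodeffect.simulate`).
    """

    sessions: list[SessionSpec] = field(default_factory=list)
    simulate: dict | None = None
    window_beats: int = 100
    t0_s: float = 60.0
    alpha: float = 0.05
    omnibus_alpha: float | None = None
    sleep_policy: str = "include"
    baseline_stride: int = 1
    artifact_rejection: bool = True
    out_dir: str = "nodeffect_out"
    seed: int = 0


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a StudyConfig from YAML."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sessions = []
    for s in raw.get("sessions", []) or []:
        try:
            spec = SessionSpec(
                session_id=str(s["session_id"]),
                condition=Condition(s["condition"]),
                half=s.get("half", "second"),
                rri_path=s.get("rri_path"),
                events_path=s.get("events_path"),
                events_format=s.get("events_format", "csv"),
                nod_tier=s.get("nod_tier", "nod"),
                sleep_tier=s.get("sleep_tier"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: session entry missing key {exc}") from exc
        except ValueError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc
        for p in (spec.rri_path, spec.events_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{path}: referenced file does not exist: {p}")
        sessions.append(spec)
    cfg = StudyConfig(
        sessions=sessions,
        simulate=raw.get("simulate"),
        window_beats=int(raw.get("window_beats", 100)),
        t0_s=float(raw.get("t0_s", 60.0)),
        alpha=float(raw.get("alpha", 0.05)),
        omnibus_alpha=(None if raw.get("omnibus_alpha") is None else float(raw["omnibus_alpha"])),
        sleep_policy=raw.get("sleep_policy", "include"),
        baseline_stride=int(raw.get("baseline_stride", 1)),
        artifact_rejection=bool(raw.get("artifact_rejection", True)),
        out_dir=raw.get("out_dir", "nodeffect_out"),
        seed=int(raw.get("seed", 0)),
    )
    if not cfg.sessions and cfg.simulate is None:
        raise ConfigurationError(f"{path}: config references zero sessions and no simulate block")
    return cfg
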