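"""Sliding-window heart-rate-variability metrics from an RR-interval series.

pNN50 — the proportion of adjacent beat pairs whose RR intervals differ by
more than 50 ms (strictly) — is computed over a trailing window of
``window_beats`` beats (default 100, roughly one minute of recording) and
emitted at every beat, anchored at the window's END.  It is reported as a
proportion in [0, 1].

LF/HF — the ratio of low-frequency (0.04-0.15 Hz) to high-frequency
(0.15-0.40 Hz) spectral power of the RRI tachogram — is computed over a
trailing window of ``window_s`` seconds (default 120).  The tachogram lives
on the uneven beat-time grid, so the default estimator is the Lomb-Scargle
periodogram; cubic-spline resampling to an even grid followed by a Welch
periodogram is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, welch

from .errors import ParameterError
from .io import RRISeries

logger = logging.getLogger("nodeffect")

NN_THRESHOLD_MS = 50.0
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class MetricSeries:
    """A time-aligned sliding-window metric (one sample per anchor time).

    ``t[k]`` is the time of the window END; ``valid[k]`` is False where the
    full lookback window does not fit inside the recording (value is NaN).
    """

    metric: str
    t: np.ndarray
    value: np.ndarray
    valid: np.ndarray
    window_spec: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def t_valid(self) -> np.ndarray:
        return self.t[self.valid]

    @property
    def value_valid(self) -> np.ndarray:
        return self.value[self.valid]


def compute_pnn50(rri: RRISeries, window_beats: int = 100) -> MetricSeries:
    """Sliding pNN50 over the most recent ``window_beats`` beats, per beat.

    Only differences between *adjacent* beats fully inside the window are
    counted (a gap left by artifact rejection breaks adjacency); the
    denominator is the number of such adjacent pairs, which is
    ``window_beats - 1`` on gap-free data.  Strict inequality: a difference
    of exactly 50 ms does not count.
    """
    if window_beats < 2:
        raise ParameterError(f"window_beats must be >= 2, got {window_beats}")
    n = len(rri)
    t = rri.t.copy()
    value = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    spec = {"window_beats": window_beats}
    if n < window_beats:
        if n:
            logger.warning("series of %d beats shorter than window %d: all samples invalid",
                           n, window_beats)
        return MetricSeries("pnn50", t, value, valid, spec)
    adj = rri.pair_adjacent                       # pair j couples beats j, j+1
    exceed = adj & (np.abs(np.diff(rri.rri)) > NN_THRESHOLD_MS)
    c_exc = np.concatenate([[0], np.cumsum(exceed)])
    c_adj = np.concatenate([[0], np.cumsum(adj)])
    w = window_beats
    # window ending at beat k covers beats k-w+1..k -> pairs k-w+1..k-1
    ks = np.arange(w - 1, n)
    num = c_exc[ks] - c_exc[ks - w + 1]
    den = c_adj[ks] - c_adj[ks - w + 1]
    ok = den > 0
    value[ks[ok]] = num[ok] / den[ok]
    valid[ks[ok]] = True
    return MetricSeries("pnn50", t, value, valid, spec)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    m = (freqs >= band[0]) & (freqs <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def compute_lf_hf(rri: RRISeries, window_s: float = 120.0, step_s: float = 1.0,
                  lf_band: tuple[float, float] = LF_BAND,
                  hf_band: tuple[float, float] = HF_BAND,
                  method: str = "lombscargle",
                  min_beats: int = 30) -> MetricSeries:
    """Sliding LF/HF ratio over a trailing ``window_s``-second window.

    Anchors run from the first time the full window fits to the last beat,
    every ``step_s`` seconds.  Windows with fewer than ``min_beats`` beats,
    a degenerate (constant) tachogram, or vanishing HF power are marked
    invalid rather than raising.
    """
    if method not in ("lombscargle", "welch"):
        raise ParameterError(f"method must be 'lombscargle' or 'welch', got {method!r}")
    spec = {"window_s": window_s, "step_s": step_s, "lf_band": lf_band,
            "hf_band": hf_band, "method": method}
    if len(rri) < 2 or rri.t[-1] - rri.t[0] < window_s:
        return MetricSeries("lf_hf", np.zeros(0), np.zeros(0), np.zeros(0, dtype=bool), spec)
    anchors = np.arange(rri.t[0] + window_s, rri.t[-1] + 1e-9, step_s)
    value = np.full(len(anchors), np.nan)
    valid = np.zeros(len(anchors), dtype=bool)
    f_grid = np.arange(lf_band[0], hf_band[1] + 1e-9, 0.002)
    ang = 2.0 * np.pi * f_grid
    for i, a in enumerate(anchors):
        lo_idx = np.searchsorted(rri.t, a - window_s, side="left")
        hi_idx = np.searchsorted(rri.t, a, side="right")
        tw = rri.t[lo_idx:hi_idx]
        yw = rri.rri[lo_idx:hi_idx]
        if len(tw) < min_beats or np.ptp(yw) == 0:
            continue
        y = yw - yw.mean()
        if method == "lombscargle":
            psd = lombscargle(tw, y, ang)
            freqs = f_grid
        else:
            fs = 4.0
            cs = CubicSpline(tw, y)
            tg = np.arange(tw[0], tw[-1], 1.0 / fs)
            yg = cs(tg)
            freqs, psd = welch(yg, fs=fs, nperseg=min(256, len(yg)))
        lf = _band_power(freqs, psd, lf_band)
        hf = _band_power(freqs, psd, hf_band)
        if hf <= max(lf + hf, 1.0) * 1e-12:
            continue
        value[i] = lf / hf
        valid[i] = True
    return MetricSeries("lf_hf", anchors, value, valid, spec)


@dataclass(frozen=True)
class RejectionReport:
    """Indices (into the input series) of removed beats, with reasons."""

    removed: list
    reasons: list

    def __len__(self) -> int:
        return len(self.removed)


def reject_artifacts(rri: RRISeries, max_rel_jump: float = 0.3,
                     bounds_ms: tuple[float, float] = (300.0, 2000.0)
                     ) -> tuple[RRISeries, RejectionReport]:
    """Remove physiologically implausible beats, keeping the time axis.

    A beat is rejected when its RRI lies outside ``bounds_ms`` or differs
    from the previously *accepted* RRI by more than ``max_rel_jump``
    (relative).  Removed beats leave gaps: the retained beats keep their
    original timestamps, so downstream pair statistics skip across gaps.
    """
    removed: list[int] = []
    reasons: list[str] = []
    keep = np.ones(len(rri), dtype=bool)
    prev: float | None = None
    for k in range(len(rri)):
        r = rri.rri[k]
        if not (bounds_ms[0] <= r <= bounds_ms[1]):
            keep[k] = False
            removed.append(k)
            reasons.append(f"out of bounds [{bounds_ms[0]}, {bounds_ms[1]}] ms: {r}")
            continue
        if prev is not None and abs(r - prev) > max_rel_jump * prev:
            keep[k] = False
            removed.append(k)
            reasons.append(f"jump > {max_rel_jump:.0%} vs previous accepted ({prev} -> {r})")
            continue
        prev = r
    if removed:
        logger.warning("%s: rejected %d/%d beats as artifacts",
                       rri.session_id, len(removed), len(rri))
    cleaned = RRISeries(rri.session_id, rri.t[keep], rri.rri[keep])
    return cleaned, RejectionReport(removed, reasons)
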