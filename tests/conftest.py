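import numpy as np
import pytest

from nodeffect import Condition, EventTrack, MetricSeries, RRISeries


def make_rri(rri_ms, session_id="s1", t=None):
    """RRISeries from a list of intervals; times reconstructed by cumsum."""
    rri_ms = np.asarray(rri_ms, dtype=float)
    if t is None:
        t = np.cumsum(rri_ms) / 1000.0
    return RRISeries(session_id, np.asarray(t, dtype=float), rri_ms)


def make_metric(t, value, metric="pnn50"):
    """Fully valid MetricSeries on an explicit time grid."""
    t = np.asarray(t, dtype=float)
    value = np.asarray(value, dtype=float)
    return MetricSeries(metric, t, value, np.ones(len(t), dtype=bool),
                        {"window_beats": 100})


def linear_metric(t0=0.0, t1=600.0, step=1.0, intercept=0.3, slope=1e-4):
    t = np.arange(t0, t1, step)
    return make_metric(t, intercept + slope * t)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def track_factory():
    def make(nods=(), sleep=(), condition=Condition.WITH_VIDEO_NOT_FORCED,
             session_id="s1"):
        return EventTrack(session_id=session_id, condition=condition,
                          nods=np.asarray(nods, dtype=float), sleep=list(sleep))
    return make
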