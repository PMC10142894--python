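"""The event-locked slope statistic: oracles, identities, invariances."""

import numpy as np
import pytest

from nodeffect import (Condition, EffectConfig, EventTrack, MetricSeries,
                       baseline_effects, global_trend, nod_slope, nodding_effects)
from nodeffect.errors import InsufficientDataError, ParameterError

from conftest import linear_metric, make_metric


class TestGlobalTrend:
    def test_constant_series_has_zero_slope(self):
        assert global_trend(make_metric([0, 60, 120], [0.3, 0.3, 0.3])) == pytest.approx(0.0)

    def test_exact_linear_recovery(self):
        ms = linear_metric(slope=-2.5e-4, intercept=0.4)
        assert global_trend(ms) == pytest.approx(-2.5e-4, abs=1e-15)

    def test_five_point_fixture_matches_closed_form_ols(self):
        t = np.array([0.0, 60.0, 120.0, 180.0, 240.0])
        v = np.array([0.30, 0.32, 0.31, 0.35, 0.34])
        # independent closed-form OLS: sum((t-tbar)(v-vbar)) / sum((t-tbar)^2)
        expected = np.sum((t - t.mean()) * (v - v.mean())) / np.sum((t - t.mean()) ** 2)
        assert global_trend(make_metric(t, v)) == pytest.approx(expected, rel=1e-12)

    def test_fewer_than_two_valid_samples_rejected(self):
        ms = MetricSeries("pnn50", np.array([0.0, 1.0]), np.array([0.3, np.nan]),
                          np.array([True, False]), {})
        with pytest.raises(InsufficientDataError):
            global_trend(ms)


class TestNodSlope:
    def test_linear_series_gives_its_slope_everywhere(self):
        ms = linear_metric(slope=3e-4)
        for t in (70.0, 123.4, 400.0, 539.0):
            assert nod_slope(ms, t, 60.0) == pytest.approx(3e-4, abs=1e-15)

    def test_hand_arithmetic_fixture(self):
        # pNN50(t)=0.40, pNN50(t+60)=0.34 -> (0.34-0.40)/60 = -0.001 /s
        ms = make_metric([0.0, 60.0], [0.40, 0.34])
        assert nod_slope(ms, 0.0, 60.0) == pytest.approx(-0.001)

    def test_event_near_recording_end_excluded(self):
        ms = linear_metric(t1=300.0)
        with pytest.raises(InsufficientDataError, match="beyond last"):
            nod_slope(ms, 290.0, 60.0)

    def test_event_before_first_sample_excluded(self):
        ms = linear_metric(t0=100.0, t1=400.0)
        with pytest.raises(InsufficientDataError, match="precedes"):
            nod_slope(ms, 50.0, 60.0)

    def test_non_positive_lag_rejected(self):
        with pytest.raises(ParameterError):
            nod_slope(linear_metric(), 100.0, 0.0)


class TestNoddingEffects:
    def test_linear_series_gives_zero_effect_for_every_nod(self, track_factory):
        ms = linear_metric(slope=5e-4, t1=900.0)
        track = track_factory(nods=[100.0, 333.3, 700.0])
        res = nodding_effects(ms, track)
        assert len(res) == 3
        assert all(abs(s.n) < 1e-12 for s in res)

    def test_subtraction_identity_and_sign_flag(self, track_factory):
        # Ns = -0.001, Nall = -0.0002  ->  n = -0.0008, arousal-increasing.
        # Endpoint values are chosen so the closed-form OLS slope over the
        # four samples is exactly -0.0002 (hand: sum(dev*v)/sum(dev^2)).
        t = np.array([0.0, 40.0, 100.0, 140.0])
        v = np.array([0.40, 0.40, 0.34, 0.40 - 0.52 / 70.0])
        dev = t - t.mean()
        assert np.sum(dev * v) / np.sum(dev**2) == pytest.approx(-0.0002, rel=1e-12)
        res = nodding_effects(make_metric(t, v), track_factory(nods=[40.0]))
        [s] = res.samples
        assert s.ns == pytest.approx(-0.001, rel=1e-12)
        assert s.n_all == pytest.approx(-0.0002, rel=1e-9)
        assert s.n == pytest.approx(-0.0008, rel=1e-9)
        assert s.arousal_increasing

    def test_every_nod_accounted_for(self, track_factory):
        ms = linear_metric(t0=80.0, t1=600.0)
        track = track_factory(nods=[10.0, 100.0, 300.0, 560.0, 590.0])
        res = nodding_effects(ms, track)
        assert len(res) + len(res.exclusions) == 5
        assert len(res.exclusions) == 3   # 10.0 too early; 560, 590 too late
        reasons = [r for _, r in res.exclusions]
        assert any("before first" in r for r in reasons)
        assert any("beyond last" in r for r in reasons)

    def test_ramp_addition_leaves_effects_unchanged(self, track_factory, rng):
        t = np.sort(rng.uniform(0, 600, size=400))
        v = rng.uniform(0, 0.5, size=400)
        track = track_factory(nods=[90.0, 200.0, 455.5])
        base = nodding_effects(make_metric(t, v), track)
        ramped = nodding_effects(make_metric(t, v + 7e-3 * t), track)
        for a, b in zip(base.samples, ramped.samples):
            assert b.n == pytest.approx(a.n, abs=1e-12)

    def test_time_translation_invariance(self, track_factory, rng):
        t = np.sort(rng.uniform(0, 600, size=300))
        v = rng.uniform(0, 0.5, size=300)
        track0 = track_factory(nods=[100.0, 400.0])
        track1 = track_factory(nods=[1100.0, 1400.0])
        r0 = nodding_effects(make_metric(t, v), track0)
        r1 = nodding_effects(make_metric(t + 1000.0, v), track1)
        np.testing.assert_allclose(r1.values(), r0.values(), atol=1e-12)

    def test_no_nods_gives_empty_result(self, track_factory):
        res = nodding_effects(linear_metric(), track_factory(nods=[]))
        assert len(res) == 0 and len(res.exclusions) == 0

    def test_sleep_exclusion_policy(self, track_factory):
        ms = linear_metric(t1=900.0)
        track = track_factory(nods=[100.0, 400.0], sleep=[(430.0, 500.0)])
        keep = nodding_effects(ms, track, EffectConfig(sleep_policy="include"))
        drop = nodding_effects(ms, track, EffectConfig(sleep_policy="exclude"))
        assert len(keep) == 2
        assert len(drop) == 1   # the 400 s nod's [400, 460] span touches sleep
        assert drop.exclusions[0][1] == "span intersects sleep interval"


class TestBaselineEffects:
    def test_no_nods_makes_every_interior_sample_a_probe(self, track_factory):
        ms = linear_metric(t0=0.0, t1=300.0)
        res = baseline_effects(ms, track_factory(nods=[]))
        # all samples with s + t0 inside the recording: t in [0, 239]
        assert len(res) == np.sum(ms.t + 60.0 <= ms.t[-1])

    def test_linear_series_gives_zero_baseline(self, track_factory):
        res = baseline_effects(linear_metric(slope=1e-3), track_factory(nods=[]))
        assert len(res) > 0
        assert np.max(np.abs(res.values())) < 1e-12

    def test_guard_excludes_probes_near_nods(self, track_factory):
        ms = linear_metric(t1=600.0)
        track = track_factory(nods=[300.0])
        res = baseline_effects(ms, track)
        probes = np.array([s.anchor_t for s in res.samples])
        # no probe s may have the nod inside [s - 60, s + 60]
        assert not np.any((probes >= 240.0) & (probes <= 360.0))

    def test_matches_per_probe_nod_slope_oracle(self, track_factory, rng):
        t = np.sort(rng.uniform(0, 500, size=250))
        v = rng.uniform(0, 0.5, size=250)
        ms = make_metric(t, v)
        track = track_factory(nods=[250.0])
        res = baseline_effects(ms, track, EffectConfig(baseline_stride=7))
        n_all = global_trend(ms)
        for s in res.samples:
            assert s.n == pytest.approx(nod_slope(ms, s.anchor_t, 60.0) - n_all,
                                        abs=1e-15)

    def test_stride_thins_probe_grid(self, track_factory):
        ms = linear_metric(t1=400.0)
        full = baseline_effects(ms, track_factory(nods=[]))
        thin = baseline_effects(ms, track_factory(nods=[]),
                                EffectConfig(baseline_stride=10))
        assert len(full) > 5 * len(thin) > 0
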