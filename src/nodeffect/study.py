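"""Simulation studies on synthetic cohorts: effect recovery and null calibration.

A *cohort* is one replicate of the three-condition design: ``n_per_group``
sessions per condition generated from :func:`nodeffect.simulate.study_templates`,
analysed end to end (pNN50 -> event-locked effects + nod-free baseline ->
Kruskal-Wallis + LSD).  With a negative injected effect for spontaneous nods
and a positive one for cued nods, a correct pipeline recovers the sign
ordering  mean(not_forced) < mean(baseline) < mean(forced); with all effects
zero, the omnibus rejection rate calibrates the test's type-I error.

Baseline probes are thinned to one per ~150 s (``baseline_stride`` beats):
the statistic at anchor s depends on beats in [s - window, s + t0]
(~145 s at the default 100-beat window and 60 s lag), so this spacing makes
baseline samples approximately independent, as the rank test assumes, and
keeps the baseline pool comparable in size to the nod pools.
"""

from __future__ import annotations

from typing import Sequence

from .effect import EffectConfig, baseline_effects, nodding_effects
from .hrv import compute_pnn50
from .simulate import SimParams, simulate_cohort, study_templates
from .stats import GroupComparison, compare_conditions

#: default thinning of baseline probes: 175 beats ~ 150 s at 850 ms RRI
BASELINE_STRIDE = 175


def analyze_cohort(sessions, baseline_stride: int = BASELINE_STRIDE,
                   window_beats: int = 100, t0_s: float = 60.0,
                   alpha: float = 0.05) -> GroupComparison:
    """Run the metric -> effect -> comparison chain on simulated sessions."""
    cfg = EffectConfig(t0_s=t0_s, baseline_stride=baseline_stride)
    samples = []
    conditions = {}
    for s in sessions:
        pnn50 = compute_pnn50(s.rri, window_beats=window_beats)
        samples.extend(nodding_effects(pnn50, s.events, cfg).samples)
        samples.extend(baseline_effects(pnn50, s.events, cfg).samples)
        conditions[s.rri.session_id] = s.events.condition
    return compare_conditions(samples, conditions, alpha=alpha)


def cohort_comparison(seed: int, n_per_group: int | Sequence[int] = 10,
                      effect_delta_not_forced: float = -0.3,
                      effect_delta_forced: float = 0.3,
                      baseline_stride: int = BASELINE_STRIDE,
                      templates: Sequence[SimParams] | None = None,
                      **template_kwargs) -> GroupComparison:
    """Simulate one three-condition cohort and compare the conditions."""
    if templates is None:
        templates = study_templates(
            effect_delta_not_forced=effect_delta_not_forced,
            effect_delta_forced=effect_delta_forced, **template_kwargs)
    n = [n_per_group] * len(templates) if isinstance(n_per_group, int) else list(n_per_group)
    sessions = simulate_cohort(n, templates, seed=seed)
    return analyze_cohort(sessions, baseline_stride=baseline_stride)


def sign_ordering_recovered(comparison: GroupComparison) -> bool:
    """True when mean(not_forced) < mean(baseline) < mean(forced)."""
    means = dict(zip(comparison.groups, comparison.mean_i))
    return (means["not_forced_effect"] < means["baseline_no_nod_trend"]
            < means["forced_effect"])


def recovery_rate(n_cohorts: int = 100, seed: int = 0, **kwargs) -> float:
    """Fraction of cohorts recovering the injected sign ordering."""
    hits = sum(sign_ordering_recovered(cohort_comparison(seed + i, **kwargs))
               for i in range(n_cohorts))
    return hits / n_cohorts


def type_i_error_rate(n_cohorts: int = 200, seed: int = 0, alpha: float = 0.05,
                      **kwargs) -> float:
    """Omnibus rejection rate with all injected effects zero."""
    kwargs.setdefault("effect_delta_not_forced", 0.0)
    kwargs.setdefault("effect_delta_forced", 0.0)
    rej = sum(cohort_comparison(seed + i, **kwargs).p < alpha
              for i in range(n_cohorts))
    return rej / n_cohorts
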