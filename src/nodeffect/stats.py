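"""Rank-based comparison of the three effect distributions.

The omnibus test is the Kruskal-Wallis H with the standard tie correction:
mid-ranks R over the pooled sample of size N,

    H = [ 12 / (N (N+1)) * sum_i R_i^2 / n_i  -  3 (N+1) ] / C,
    C = 1 - sum_j (t_j^3 - t_j) / (N^3 - N)

with t_j the sizes of tied groups; under the null H ~ chi-square with k-1
degrees of freedom.  Pairwise follow-up uses the protected least-significant-
difference (LSD) procedure on the pooled mid-ranks (Conover style): for
groups i, j

    T = |Rbar_i - Rbar_j| / sqrt( S^2 (1/n_i + 1/n_j) )

with S^2 the pooled within-group rank variance on N-k degrees of freedom,
referred to a t distribution with N-k df, two-sided, with no further
multiplicity adjustment (the protection step — only testing pairs after a
significant omnibus test — is what keeps the LSD honest).  A raw-scale
Fisher LSD on the observed values is available behind ``on_ranks=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, ParameterError
from .effect import EffectSample
from .io import Condition

#: canonical group order: no-event trend, spontaneous nods, cued nods
GROUP_LABELS = ("baseline_no_nod_trend", "not_forced_effect", "forced_effect")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis test; returns (H, df, p).

    p is the upper chi-square tail with k-1 degrees of freedom — a
    large-sample approximation that is conservative for tiny N.
    """
    if len(groups) < 2:
        raise ParameterError(f"need k >= 2 groups, got {len(groups)}")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([len(a) for a in arrs])
    if np.any(sizes < 1):
        raise ParameterError("every group must have n >= 1")
    pooled = np.concatenate(arrs)
    n_total = len(pooled)
    if n_total < 3:
        raise ParameterError(f"need total N >= 3, got {n_total}")
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical: ranks carry no information")
    ranks = sps.rankdata(pooled)                       # mid-ranks for ties
    h = 12.0 / (n_total * (n_total + 1))
    start = 0
    acc = 0.0
    for n_i in sizes:
        r_i = ranks[start:start + n_i].sum()
        acc += r_i * r_i / n_i
        start += n_i
    h = h * acc - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n_total**3 - n_total)
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return float(h), df, p


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[int, int]
    labels: tuple[str, str]
    t_stat: float
    p: float
    significant: bool


def lsd_pairwise(groups: Sequence[Sequence[float]], alpha: float = 0.05,
                 on_ranks: bool = True, labels: Sequence[str] | None = None,
                 protected: bool = True,
                 omnibus_alpha: float | None = None) -> list[PairwiseResult]:
    """Protected LSD pairwise comparisons after Kruskal-Wallis.

    With ``on_ranks=True`` the comparisons run on the pooled mid-ranks;
    otherwise on the raw values (classic Fisher LSD).  When ``protected``,
    a non-significant omnibus test (at ``omnibus_alpha``, default = alpha)
    short-circuits to an empty list.
    """
    if len(groups) < 2:
        raise ParameterError(f"need k >= 2 groups, got {len(groups)}")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    sizes = np.array([len(a) for a in arrs])
    n_total = int(sizes.sum())
    if n_total <= k:
        raise InsufficientDataError("pooled variance needs N > k")
    if protected:
        _, _, p_omni = kruskal_wallis(groups)
        if p_omni > (alpha if omnibus_alpha is None else omnibus_alpha):
            return []
    if on_ranks:
        pooled = sps.rankdata(np.concatenate(arrs))
        data = []
        start = 0
        for n_i in sizes:
            data.append(pooled[start:start + n_i])
            start += n_i
    else:
        data = arrs
    means = [a.mean() for a in data]
    ss_within = sum(float(((a - a.mean())**2).sum()) for a in data)
    df = n_total - k
    s2 = ss_within / df
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(k)]
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            if sizes[i] < 2 or sizes[j] < 2:
                raise InsufficientDataError(
                    f"pair ({labels[i]}, {labels[j]}): both groups need n >= 2")
            se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                t_stat = 0.0 if means[i] == means[j] else np.inf
            else:
                t_stat = abs(means[i] - means[j]) / se
            p = float(2.0 * sps.t.sf(t_stat, df))
            out.append(PairwiseResult((i, j), (labels[i], labels[j]),
                                      float(t_stat), p, p < alpha))
    return out


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus LSD pairwise results for the three conditions."""

    groups: tuple
    n_i: tuple
    mean_i: tuple
    h: float
    df: int
    p: float
    pairwise: list
    alpha: float
    per_session_counts: dict = field(default_factory=dict)

    def interpretation(self) -> dict:
        """Sign reading per group: negative mean effect = arousal-increasing."""
        return {g: ("arousal-increasing" if m < 0 else "arousal-decreasing")
                for g, m in zip(self.groups, self.mean_i)}

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "n": list(self.n_i),
            "mean_per_s": list(self.mean_i),
            "kruskal_wallis": {"H": self.h, "df": self.df, "p": self.p},
            "pairwise_lsd": [
                {"pair": list(r.labels), "T": r.t_stat, "p": r.p,
                 "significant": r.significant} for r in self.pairwise
            ],
            "alpha": self.alpha,
            "interpretation": self.interpretation(),
            "per_session_counts": self.per_session_counts,
        }


def _condition_group(sample: EffectSample, conditions: dict) -> str | None:
    """Map one effect sample to its comparison group (None = not used)."""
    if sample.kind == "baseline":
        return GROUP_LABELS[0]
    cond = conditions[sample.session_id]
    if cond == Condition.WITH_VIDEO_FORCED:
        return GROUP_LABELS[2]
    return GROUP_LABELS[1]       # spontaneous nods: no-video or not-forced sessions


def compare_conditions(effects: Iterable[EffectSample], conditions: dict,
                       alpha: float = 0.05,
                       omnibus_alpha: float | None = None,
                       on_ranks: bool = True) -> GroupComparison:
    """Assemble the three samples and run Kruskal-Wallis + protected LSD.

    ``conditions`` maps session_id -> Condition.  Baseline samples from all
    sessions form the no-nod trend group; nod samples split into spontaneous
    (no-video and not-forced sessions pooled) vs forced.  Per-session sample
    counts are reported so the within-participant clustering is visible.
    """
    buckets: dict[str, list[float]] = {g: [] for g in GROUP_LABELS}
    per_session: dict[str, dict[str, int]] = {g: {} for g in GROUP_LABELS}
    for s in effects:
        g = _condition_group(s, conditions)
        buckets[g].append(s.n)
        per_session[g][s.session_id] = per_session[g].get(s.session_id, 0) + 1
    for g in GROUP_LABELS:
        if not buckets[g]:
            raise InsufficientDataError(f"group {g!r} is empty")
    groups = [buckets[g] for g in GROUP_LABELS]
    h, df, p = kruskal_wallis(groups)
    pairwise = lsd_pairwise(groups, alpha=alpha, on_ranks=on_ranks,
                            labels=list(GROUP_LABELS), protected=True,
                            omnibus_alpha=omnibus_alpha)
    return GroupComparison(
        groups=GROUP_LABELS,
        n_i=tuple(len(g) for g in groups),
        mean_i=tuple(float(np.mean(g)) for g in groups),
        h=h, df=df, p=p, pairwise=pairwise, alpha=alpha,
        per_session_counts=per_session,
    )
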