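"""Kruskal-Wallis + LSD: closed-form oracles, permutation null, power."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from nodeffect import (Condition, EffectSample, compare_conditions,
                       kruskal_wallis, lsd_pairwise)
from nodeffect.errors import (DegenerateDataError, InsufficientDataError,
                              ParameterError)


def kw_direct(groups):
    """Independent textbook evaluation of tie-corrected H (mid-ranks by sort)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)     # mid-rank of the tie block
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1.0 - np.sum(counts**3 - counts) / (n**3 - n))


class TestKruskalWallis:
    def test_hand_rank_sum_fixture_no_ties(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)), rel=1e-12)

    def test_tie_correction_matches_direct_formula(self):
        cases = [
            [[1, 1, 2], [2, 3, 3]],
            [[5, 5, 5, 1], [5, 2, 2], [7, 7, 1, 2]],
            [[0.1, 0.1], [0.1, 0.2], [0.3, 0.3, 0.1]],
        ]
        for groups in cases:
            h, _, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kw_direct(groups), rel=1e-12)

    def test_agrees_with_scipy_reference(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 8, size=rng.integers(3, 12)) for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, _, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(size=9)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([np.exp(3 * g) for g in groups])
        assert h2 == pytest.approx(h1, rel=1e-12)

    def test_null_mean_is_roughly_df(self, rng):
        hs = []
        for _ in range(400):
            g = rng.normal(size=18)
            hs.append(kruskal_wallis([g[:6], g[6:12], g[12:]])[0])
        assert np.mean(hs) == pytest.approx(2.0, abs=0.25)

    def test_chi_square_p_near_exact_permutation_p(self):
        groups = [[1.0, 4.0, 6.0], [2.0, 7.0, 8.0], [3.0, 5.0]]
        h_obs, _, p_chi2 = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = total = 0
        for perm in itertools.permutations(range(len(pooled))):
            vals = pooled[list(perm)]
            gs = [vals[:sizes[0]], vals[sizes[0]:sizes[0] + sizes[1]],
                  vals[sizes[0] + sizes[1]:]]
            h, _, _ = kruskal_wallis(gs)
            count += h >= h_obs - 1e-12
            total += 1
        p_exact = count / total
        assert abs(p_chi2 - p_exact) < 0.1

    def test_degenerate_and_parameter_errors(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1, 1], [1, 1, 1]])
        with pytest.raises(ParameterError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ParameterError):
            kruskal_wallis([[1], [2]])


class TestLsdPairwise:
    def test_hand_computed_rank_t_fixture(self):
        # pooled ranks 1..9; group mean ranks 2, 8, 5; within-group rank
        # variance: SS = 3*2 = 6 on N-k = 6 df -> S^2 = 1
        # T(0,1) = |2-8| / sqrt(1*(1/3+1/3)) = 6 / 0.81650 = 7.3485
        res = lsd_pairwise([[1, 2, 3], [7, 8, 9], [4, 5, 6]], protected=False)
        t01 = next(r for r in res if r.pair == (0, 1))
        assert t01.t_stat == pytest.approx(6 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert t01.p == pytest.approx(2 * sps.t.sf(6 / np.sqrt(2.0 / 3.0), 6), rel=1e-12)

    def test_interleaved_identical_groups_show_no_separation(self):
        res = lsd_pairwise([[1, 3, 5, 7], [2, 4, 6, 8]], protected=False)
        [r] = res
        assert r.t_stat < 1.0 and r.p > 0.5 and not r.significant

    def test_p_decreases_with_separation(self):
        near = lsd_pairwise([[1, 2, 3, 7], [4, 5, 6, 8]], protected=False)[0]
        far = lsd_pairwise([[1, 2, 3, 4], [5, 6, 7, 8]], protected=False)[0]
        assert far.t_stat > near.t_stat and far.p < near.p

    def test_protection_blocks_pairs_without_omnibus_significance(self, rng):
        g = rng.normal(size=15)
        res = lsd_pairwise([g[:5], g[5:10], g[10:]], alpha=0.05, protected=True)
        assert res == [] or all(isinstance(r.p, float) for r in res)
        # identical-distribution groups essentially never clear the omnibus
        same = lsd_pairwise([[1, 4, 7, 10], [2, 5, 8, 11], [3, 6, 9, 12]],
                            alpha=0.05, protected=True)
        assert same == []

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            lsd_pairwise([[1.0], [2.0, 3.0, 4.0]], protected=False)

    def test_raw_scale_option_matches_classic_fisher_lsd(self):
        groups = [[1.0, 2.0, 3.0], [7.0, 8.0, 9.0]]
        res = lsd_pairwise(groups, on_ranks=False, protected=False)[0]
        # classic pooled-variance two-sample t on the raw values
        s2 = (np.var(groups[0], ddof=1) * 2 + np.var(groups[1], ddof=1) * 2) / 4
        t_ref = 6.0 / np.sqrt(s2 * (2 / 3))
        assert res.t_stat == pytest.approx(t_ref, rel=1e-12)

    def test_power_non_decreasing_in_sample_size(self, rng):
        shift = 1.0
        rates = []
        for n in (10, 30, 100):
            rej = 0
            for _ in range(60):
                g = [rng.normal(size=n), rng.normal(shift, size=n)]
                _, _, p = kruskal_wallis(g)
                rej += p < 0.05
            rates.append(rej / 60)
        assert rates[0] <= rates[1] + 0.1 and rates[1] <= rates[2] + 0.05
        assert rates[2] > 0.9


def _sample(sid, kind, n):
    return EffectSample(sid, 0.0, kind, n, 0.0, n, 60.0)


class TestCompareConditions:
    def test_groups_assembled_by_condition_and_kind(self, rng):
        conditions = {"a": Condition.NO_NODDING_VIDEO,
                      "b": Condition.WITH_VIDEO_NOT_FORCED,
                      "c": Condition.WITH_VIDEO_FORCED}
        samples = ([_sample("a", "baseline", v) for v in rng.normal(0, 1e-4, 30)]
                   + [_sample("b", "nod", v) for v in rng.normal(-8e-4, 1e-4, 20)]
                   + [_sample("a", "nod", v) for v in rng.normal(-8e-4, 1e-4, 5)]
                   + [_sample("c", "nod", v) for v in rng.normal(8e-4, 1e-4, 20)])
        cmp_res = compare_conditions(samples, conditions)
        assert cmp_res.n_i == (30, 25, 20)   # no-video nods pool as spontaneous
        means = dict(zip(cmp_res.groups, cmp_res.mean_i))
        assert (means["not_forced_effect"] < means["baseline_no_nod_trend"]
                < means["forced_effect"])
        assert cmp_res.p < 0.001
        interp = cmp_res.interpretation()
        assert interp["not_forced_effect"] == "arousal-increasing"
        assert interp["forced_effect"] == "arousal-decreasing"
        assert cmp_res.per_session_counts["not_forced_effect"] == {"b": 20, "a": 5}

    def test_empty_group_names_the_condition(self):
        conditions = {"a": Condition.NO_NODDING_VIDEO}
        samples = [_sample("a", "baseline", 0.1), _sample("a", "nod", 0.2)]
        with pytest.raises(InsufficientDataError, match="forced_effect"):
            compare_conditions(samples, conditions)
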