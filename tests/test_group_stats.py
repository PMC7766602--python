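from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from capedema.group_stats import (
    BoxSummary,
    GroupedSamples,
    assign_stars,
    box_summary,
    kruskal_wallis,
    pairwise_bonferroni,
)


def _brute_force_kw_p(groups: dict) -> float:
    """Independent oracle: iterate every permutation of the pooled values
    over the label vector and count arrangements at least as extreme."""
    labels = [g for g, vals in groups.items() for _ in vals]
    pooled = np.array([v for vals in groups.values() for v in vals], float)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tc = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)

    def h_of(assignment):
        by = {}
        for lab, r in zip(assignment, ranks):
            by.setdefault(lab, []).append(r)
        h = 12.0 / (n * (n + 1)) * sum(
            sum(rs) ** 2 / len(rs) for rs in by.values()) - 3 * (n + 1)
        return h / tc

    h_obs = h_of(labels)
    count = total = 0
    for perm in permutations(range(len(pooled))):
        assignment = [labels[i] for i in perm]
        total += 1
        count += h_of(assignment) >= h_obs - 1e-12
    return count / total


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        h, p = kruskal_wallis(GroupedSamples({"A": [1, 2, 3], "B": [1, 2, 3]}))
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_exact_permutation_two_of_six_labelings(self):
        # separated pairs: only the observed split and its mirror reach H_obs
        h, p = kruskal_wallis(GroupedSamples({"A": [1, 2], "B": [10, 11]}))
        assert p == pytest.approx(1 / 3)

    def test_exact_branch_matches_brute_force(self, rng):
        for _ in range(4):
            groups = {"a": rng.normal(size=3).tolist(),
                      "b": rng.normal(size=2).tolist(),
                      "c": rng.normal(size=3).tolist()}
            _, p = kruskal_wallis(GroupedSamples(groups))
            assert p == pytest.approx(_brute_force_kw_p(groups), abs=1e-12)

    def test_all_values_identical_degenerate(self):
        h, p = kruskal_wallis(GroupedSamples({"A": [5.0, 5.0], "B": [5.0, 5.0, 5.0]}))
        assert (h, p) == (0.0, 1.0)

    def test_invariant_under_monotone_transform(self, rng):
        groups = {k: rng.normal(loc=i, size=15).tolist() for i, k in enumerate("abc")}
        h1, p1 = kruskal_wallis(GroupedSamples(groups))
        warped = {k: [np.exp(v) for v in vals] for k, vals in groups.items()}
        h2, p2 = kruskal_wallis(GroupedSamples(warped))
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_two_groups_h_matches_mannwhitney_relation(self, rng):
        # without ties: H = (U - n1 n2 / 2)^2 / (n1 n2 (n+1) / 12)
        a, b = rng.normal(size=18), rng.normal(size=13)
        h, _ = kruskal_wallis(GroupedSamples({"a": a.tolist(), "b": b.tolist()}))
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        n = n1 + n2
        expect = (u - n1 * n2 / 2) ** 2 / (n1 * n2 * (n + 1) / 12)
        assert h == pytest.approx(expect, rel=1e-9)

    def test_group_invariants_enforced(self):
        with pytest.raises(ValueError):
            GroupedSamples({"A": [1.0, 2.0]})
        with pytest.raises(ValueError):
            GroupedSamples({"A": [1.0], "B": [1.0, 2.0]})
        with pytest.raises(ValueError):
            GroupedSamples({"A": [1.0, np.inf], "B": [1.0, 2.0]})


class TestPairwiseBonferroni:
    def test_two_groups_no_correction(self, rng):
        g = GroupedSamples({"a": rng.normal(size=12).tolist(),
                            "b": rng.normal(1.0, size=12).tolist()})
        res = pairwise_bonferroni(g)
        (_, raw, adj, _), = res.pairwise
        assert adj == pytest.approx(raw)

    def test_six_pairs_multiplier_and_cap(self):
        assert assign_stars(min(1.0, 6 * 0.02)) == "ns"  # 0.12
        assert min(1.0, 6 * 0.3) == 1.0

    def test_four_groups_adjustment_factor(self, rng):
        g = GroupedSamples({k: rng.normal(size=10).tolist() for k in "abcd"})
        res = pairwise_bonferroni(g)
        assert len(res.pairwise) == 6
        for (_, raw, adj, stars) in res.pairwise:
            assert adj == pytest.approx(min(1.0, 6 * raw))
            assert stars == assign_stars(adj)

    def test_star_thresholds(self):
        assert assign_stars(0.04) == "*"
        assert assign_stars(0.009) == "**"
        assert assign_stars(0.0009) == "***"
        assert assign_stars(0.00009) == "****"
        assert assign_stars(0.06) == "ns"

    def test_dunn_option_runs_and_orders_like_mw(self, rng):
        g = GroupedSamples({"a": rng.normal(size=15).tolist(),
                            "b": rng.normal(2.0, size=15).tolist(),
                            "c": rng.normal(size=15).tolist()})
        res = pairwise_bonferroni(g, method="dunn")
        pvals = {pair: adj for pair, _, adj, _ in res.pairwise}
        assert pvals[("a", "b")] < pvals[("a", "c")]


class TestBoxSummary:
    def test_one_to_seven(self):
        s = box_summary(range(1, 8))
        assert (s.median, s.q1, s.q3) == (4.0, 2.5, 5.5)
        assert s.outliers == ()
        assert (s.whisker_low, s.whisker_high) == (1.0, 7.0)

    def test_constant_values_degenerate_box(self):
        s = box_summary([1, 1, 1, 1])
        assert (s.median, s.q1, s.q3, s.whisker_low, s.whisker_high) == (1,) * 5

    def test_outlier_flagged(self):
        s = box_summary([1, 2, 3, 100])
        # q3 + 1.5 IQR = 27.75 + ... by direct type-7 computation 100 is out
        q1, q3 = np.percentile([1, 2, 3, 100], [25, 75])
        assert 100 > q3 + 1.5 * (q3 - q1)
        assert s.outliers == (100.0,)
        assert s.whisker_high == 3.0

    def test_whiskers_clip_to_data_within_fences(self, rng):
        v = rng.normal(size=200)
        s = box_summary(v)
        iqr = s.q3 - s.q1
        assert s.whisker_low >= s.q1 - 1.5 * iqr
        assert s.whisker_high <= s.q3 + 1.5 * iqr
        assert s.whisker_low in v and s.whisker_high in v
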