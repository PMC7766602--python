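"""Nonparametric group comparison: Kruskal-Wallis, Bonferroni pairwise tests,
and Tukey-style box summaries.

All metrics in this package (sharpness, vessel size, papilla brightness)
are compared across conditions with rank statistics: a Kruskal-Wallis
omnibus test (tie-corrected, chi-squared reference; exact permutation
enumeration for very small samples), followed by pairwise two-sided
Mann-Whitney U tests with Bonferroni correction.  Significance stars use
the conventional thresholds 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"),
)

EXACT_N_MAX = 10  # total sample size at or below which permutation p is exact


def assign_stars(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass(frozen=True)
class GroupedSamples:
    """Ordered label -> values mapping with basic sanity invariants."""

    groups: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need >= 2 groups")
        clean: dict[str, tuple[float, ...]] = {}
        for label, vals in self.groups.items():
            v = tuple(float(x) for x in vals)
            if len(v) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 values")
            if not all(np.isfinite(v)):
                raise ValueError(f"group {label!r} contains non-finite values")
            clean[label] = v
        object.__setattr__(self, "groups", clean)

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.groups[g] for g in self.groups])


@dataclass(frozen=True)
class ComparisonResult:
    h_statistic: float
    omnibus_p: float
    pairwise: tuple[tuple[tuple[str, str], float, float, str], ...]
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _h_statistic(ranks: np.ndarray, sizes: np.ndarray, tie_correction: float) -> float:
    n = ranks.size
    start = 0
    h = 0.0
    for sz in sizes:
        r = ranks[start:start + sz]
        h += r.sum() ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_correction


def _tie_correction(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(((counts ** 3 - counts).sum()) / (n ** 3 - n))


def _exact_permutation_p(samples: GroupedSamples) -> tuple[float, float]:
    """Enumerate all assignments of pooled ranks to group labels.

    The H statistic depends only on which midranks land in which group,
    so enumeration runs over multiset partitions of the index set into
    groups of the observed sizes (at most multinomial(n; n1..nk) cases;
    for n <= 10 this is a few thousand).
    """
    pooled = samples.pooled()
    sizes = np.array([len(samples.groups[g]) for g in samples.groups])
    ranks = stats.rankdata(pooled)
    tc = _tie_correction(pooled)
    h_obs = _h_statistic(ranks, sizes, tc)

    n = pooled.size
    count = 0
    total = 0

    def recurse(avail: tuple[int, ...], gi: int, acc_ranks: list[np.ndarray]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            arrangement = np.concatenate(acc_ranks + [ranks[list(avail)]])
            h = _h_statistic(arrangement, sizes, tc)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for pick in combinations(avail, sizes[gi]):
            rest = tuple(i for i in avail if i not in set(pick))
            recurse(rest, gi + 1, acc_ranks + [ranks[list(pick)]])

    recurse(tuple(range(n)), 0, [])
    return h_obs, count / total


def kruskal_wallis(samples: GroupedSamples) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its p-value.

    The p-value comes from the chi-squared reference with k-1 degrees of
    freedom; when the total sample size is <= 10 the exact permutation
    distribution is enumerated instead (the chi-squared approximation is
    poor there).  If every pooled value is identical the comparison is
    degenerate and (H=0, p=1) is returned.
    """
    pooled = samples.pooled()
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    if pooled.size <= EXACT_N_MAX:
        return _exact_permutation_p(samples)
    h, p = stats.kruskal(*[samples.groups[g] for g in samples.groups])
    return float(h), float(p)


def pairwise_bonferroni(samples: GroupedSamples,
                        method: str = "mannwhitney") -> ComparisonResult:
    """All pairwise two-sided tests with Bonferroni-adjusted p-values.

    ``method`` is "mannwhitney" (default) or "dunn" (rank-sum z-tests on
    the pooled ranks, the classical Kruskal-Wallis post hoc).  The
    adjusted p is min(1, m * raw_p) for m pairs.
    """
    pooled = samples.pooled()
    degenerate = np.unique(pooled).size == 1
    h, omnibus_p = kruskal_wallis(samples)
    labels = samples.labels
    pairs = list(combinations(labels, 2))
    m = len(pairs)

    if method == "dunn":
        ranks = stats.rankdata(pooled)
        n = pooled.size
        tie = ((lambda c: (c ** 3 - c).sum())(np.unique(pooled, return_counts=True)[1]))
        mean_ranks, sizes, start = {}, {}, 0
        for g in labels:
            sz = len(samples.groups[g])
            mean_ranks[g] = ranks[start:start + sz].mean()
            sizes[g] = sz
            start += sz
        var_base = (n * (n + 1) / 12.0) - tie / (12.0 * (n - 1))

    results = []
    for a, b in pairs:
        if degenerate:
            raw = 1.0
        elif method == "mannwhitney":
            raw = float(stats.mannwhitneyu(samples.groups[a], samples.groups[b],
                                           alternative="two-sided").pvalue)
        elif method == "dunn":
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            raw = float(2 * stats.norm.sf(abs(z)))
        else:
            raise ValueError(f"unknown pairwise method {method!r}")
        adj = min(1.0, m * raw)
        results.append(((a, b), raw, adj, assign_stars(adj)))

    return ComparisonResult(
        h_statistic=h, omnibus_p=omnibus_p, pairwise=tuple(results),
        method=f"kruskal-wallis + {method} (bonferroni m={m})",
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Box-plot summary
# ---------------------------------------------------------------------------

def box_summary(values) -> BoxSummary:
    """Five-number box summary with 1.5 x IQR whiskers.

    Quartiles use linear interpolation (numpy's default, "type 7");
    whiskers sit at the most extreme data points still within
    [q1 - 1.5 IQR, q3 + 1.5 IQR]; points beyond are listed as outliers.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in np.sort(v[(v < lo_fence) | (v > hi_fence)]))
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=outliers,
    )
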