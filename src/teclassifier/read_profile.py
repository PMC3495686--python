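"""Deep-sequencing side analysis: 5'-start predominance ratios and a chi-square
comparison of ratio distributions between candidate categories.

The predominance ratio of a precursor is the count of the most frequent
5'-read start divided by the total read count — an indicator of clean
nuclease processing (one or few dominant mature species), not of expression
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "ReadStartProfile",
    "predominance_ratio",
    "chi2_critical_value",
    "compare_ratio_distributions",
]


@dataclass
class ReadStartProfile:
    """Read counts per 5'-start offset for one candidate."""

    candidate_name: str
    counts: dict[int, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def predominance_ratio(self) -> float:
        return predominance_ratio(self.counts)


def predominance_ratio(counts: dict[int, int]) -> float:
    """max(counts) / sum(counts); in (0, 1] whenever any read exists."""
    if not counts or sum(counts.values()) < 1:
        raise ValueError("no reads")
    values = list(counts.values())
    return max(values) / sum(values)


def chi2_critical_value(n_bins: int = 10, alpha: float = 0.05) -> float:
    """Upper-tail critical value at level alpha with df = n_bins - 1.

    For the default 10 ratio bins this is the familiar 16.919.
    """
    return float(chi2_dist.ppf(1.0 - alpha, n_bins - 1))


def _bin_ratios(ratios: list[float], n_bins: int) -> np.ndarray:
    """Histogram ratios into equal-width bins on (0, 1]; bin i covers
    (i/n, (i+1)/n], so a ratio of exactly 1 lands in the last bin."""
    counts = np.zeros(n_bins, dtype=np.int64)
    for r in ratios:
        if not 0.0 < r <= 1.0:
            raise ValueError(f"predominance ratio {r} outside (0, 1]")
        idx = min(n_bins - 1, int(np.ceil(r * n_bins)) - 1)
        counts[idx] += 1
    return counts


def _pool_sparse_bins(a: np.ndarray, b: np.ndarray, min_expected: float = 5.0):
    """Merge adjacent bins until every pooled expected count reaches
    min_expected in both groups (the standard chi-square validity guard)."""
    na, nb = a.sum(), b.sum()
    total = na + nb
    pooled_a: list[int] = []
    pooled_b: list[int] = []
    acc_a = acc_b = 0
    for ai, bi in zip(a, b):
        acc_a += int(ai)
        acc_b += int(bi)
        p = (acc_a + acc_b) / total
        if min(na * p, nb * p) >= min_expected:
            pooled_a.append(acc_a)
            pooled_b.append(acc_b)
            acc_a = acc_b = 0
    if acc_a or acc_b:
        if pooled_a:
            pooled_a[-1] += acc_a
            pooled_b[-1] += acc_b
        else:
            pooled_a.append(acc_a)
            pooled_b.append(acc_b)
    return np.asarray(pooled_a), np.asarray(pooled_b)


def compare_ratio_distributions(
    profiles_a: list[ReadStartProfile],
    profiles_b: list[ReadStartProfile],
    n_bins: int = 10,
    critical: float | None = None,
) -> tuple[float, bool]:
    """Chi-square comparison of predominance-ratio distributions of two groups.

    Ratios are binned into n_bins equal-width bins on (0, 1]; expected counts
    come from the pooled bin proportions; adjacent bins with expected counts
    below 5 are pooled first. The groups are reported as different when the
    statistic exceeds the critical value (computed at the 5% level with
    df = n_bins - 1 when not given; 16.919 for the default 10 bins).
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both groups must be non-empty")
    ratios_a = [p.predominance_ratio for p in profiles_a if p.total_reads > 0]
    ratios_b = [p.predominance_ratio for p in profiles_b if p.total_reads > 0]
    if not ratios_a or not ratios_b:
        raise ValueError("a group has no profiles with reads")
    if critical is None:
        critical = chi2_critical_value(n_bins)
    a = _bin_ratios(ratios_a, n_bins)
    b = _bin_ratios(ratios_b, n_bins)
    a, b = _pool_sparse_bins(a, b)
    na, nb = a.sum(), b.sum()
    pooled = (a + b) / (na + nb)
    stat = 0.0
    for obs, n in ((a, na), (b, nb)):
        expected = n * pooled
        mask = expected > 0
        stat += float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    return stat, stat > critical
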