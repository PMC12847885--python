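"""Ranking, partitioning and two-group comparison machinery.

Features are ranked by p-value (or |log2 fold change|), split into k
contiguous near-equal aliquots or top/bottom quantile slices, and group
feature distributions are compared with a rank test (Mann–Whitney U,
the default) or Welch's t, with Benjamini–Hochberg control across
families of tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, InputValidationError
from .records import DERecord


@dataclass
class RankedSet:
    """A significance-filtered, deterministically ordered feature list.

    ``ids`` are strictly ordered by ``(key value, feature_id)`` (the id
    tie-break makes the order reproducible across runs); ``values`` holds
    the ranking key aligned with ``ids``.
    """

    ids: list[str]
    values: np.ndarray
    key: str
    ascending: bool
    stratum: str
    alpha: float

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class GroupPartition:
    """Ordered assignment of ranked ids to labelled groups."""

    groups: list[list[str]]
    labels: list[str]

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]


@dataclass
class ComparisonResult:
    """Outcome of one two-group comparison.

    ``direction`` is derived from the group medians ('a>b', 'a<b', or
    'none' on a median tie); ``adjusted_pvalue`` is filled only when the
    comparison belongs to a BH-corrected family.  ``note`` marks
    comparisons that could not be computed (groups too small).
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    median_a: float
    median_b: float
    direction: str
    method: str = "rank"
    adjusted_pvalue: float | None = None
    feature: str = ""
    note: str = ""

    @property
    def computable(self) -> bool:
        return not self.note


def rank_by_pvalue(records: list[DERecord], alpha: float, stratum: str) -> RankedSet:
    """Keep one significance stratum and sort it ascending by p-value.

    The significant stratum holds ``pvalue < alpha`` (strict, mirroring a
    "P < 0.05" cutoff: p == alpha is non-significant); ties are broken
    lexicographically by feature id, and p-values of exactly 0 therefore
    rank ahead of every positive p-value.
    """
    if not records:
        raise InputValidationError("rank_by_pvalue: no records")
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha!r}")
    if stratum == "significant":
        kept = [r for r in records if r.pvalue < alpha]
    elif stratum == "nonsignificant":
        kept = [r for r in records if r.pvalue >= alpha]
    elif stratum == "all":
        kept = list(records)
    else:
        raise ConfigError(f"unknown stratum {stratum!r}")
    if not kept:
        raise InputValidationError(f"rank_by_pvalue: the {stratum!r} stratum is empty at alpha={alpha}")
    kept.sort(key=lambda r: (r.pvalue, r.feature_id))
    return RankedSet(
        ids=[r.feature_id for r in kept],
        values=np.array([r.pvalue for r in kept]),
        key="pvalue",
        ascending=True,
        stratum=stratum,
        alpha=alpha,
    )


def rank_by_abs_lfc(records: list[DERecord]) -> RankedSet:
    """Order records by |log2FC| descending (largest change first)."""
    if not records:
        raise InputValidationError("rank_by_abs_lfc: no records")
    ordered = sorted(records, key=lambda r: (-abs(r.log2fc), r.feature_id))
    return RankedSet(
        ids=[r.feature_id for r in ordered],
        values=np.array([abs(r.log2fc) for r in ordered]),
        key="abs_log2fc",
        ascending=False,
        stratum="all",
        alpha=float("nan"),
    )


def partition_aliquots(r: RankedSet, k: int) -> GroupPartition:
    """Split a ranked set into k contiguous near-equal aliquots.

    With ``N = len(r)``, ``base = N // k`` and ``rem = N % k``: the first
    ``rem`` groups (the smallest-p end) take ``base + 1`` members, the
    rest ``base``, preserving rank order.  Labels run "10%", "20%", ...
    for the default k = 10.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    n = len(r)
    if n < k:
        raise InputValidationError(f"cannot partition {n} features into {k} aliquots")
    base, rem = divmod(n, k)
    groups, labels, pos = [], [], 0
    for i in range(k):
        size = base + 1 if i < rem else base
        groups.append(r.ids[pos : pos + size])
        labels.append(f"{100 * (i + 1) / k:g}%")
        pos += size
    return GroupPartition(groups=groups, labels=labels)


def slice_size(n: int, frac: float) -> int:
    """Quantile slice size: round-half-away-from-zero(frac * n), min 1."""
    if not 0.0 < frac <= 0.5:
        raise ConfigError(f"slice fraction must be in (0, 0.5], got {frac!r}")
    return max(1, math.floor(frac * n + 0.5))


def quantile_slice(r: RankedSet, frac: float, which: str) -> list[str]:
    """Top or bottom quantile slice of an ordered feature list.

    'top' is the first m ids in the set's stated ordering (smallest
    p-values, or largest |log2FC| for fold-change ranking); 'bottom' the
    last m, where m follows :func:`slice_size`.
    """
    if len(r) == 0:
        raise InputValidationError("quantile_slice: empty ranked set")
    m = slice_size(len(r), frac)
    if which == "top":
        return r.ids[:m]
    if which == "bottom":
        return r.ids[len(r) - m :]
    raise ConfigError(f"which must be 'top' or 'bottom', got {which!r}")


def _direction(median_a: float, median_b: float) -> str:
    if median_a > median_b:
        return "a>b"
    if median_a < median_b:
        return "a<b"
    return "none"


def compare_groups(
    values_a,
    values_b,
    method: str = "rank",
    label_a: str = "a",
    label_b: str = "b",
    feature: str = "",
) -> ComparisonResult:
    """Two-sided two-group comparison.

    The default is the Mann–Whitney rank test: exact null distribution
    when ``min(n_a, n_b) <= 8`` and the pooled values carry no ties,
    otherwise the normal approximation with tie correction.  ``welch``
    selects Welch's unequal-variance t test.  Groups where every value is
    identical across both samples yield p = 1 and direction 'none'.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputValidationError(
            f"compare_groups[{label_a} vs {label_b}]: each group needs >= 2 values "
            f"(got {a.size}, {b.size})"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputValidationError(f"compare_groups[{label_a} vs {label_b}]: non-finite values")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    common = dict(label_a=label_a, label_b=label_b, n_a=a.size, n_b=b.size,
                  median_a=med_a, median_b=med_b, feature=feature, method=method)

    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: fully tied
        stat = a.size * b.size / 2 if method == "rank" else 0.0
        return ComparisonResult(statistic=stat, pvalue=1.0, direction="none", **common)

    if method == "rank":
        has_ties = np.unique(pooled).size < pooled.size
        mode = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
    elif method == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
    else:
        raise ConfigError(f"unknown comparison method {method!r}")
    pval = min(1.0, float(res.pvalue))
    return ComparisonResult(statistic=float(res.statistic), pvalue=pval,
                            direction=_direction(med_a, med_b), **common)


def kruskal_groups(groups: list[np.ndarray], feature: str = "") -> ComparisonResult:
    """Global k-sample Kruskal–Wallis rank test across aliquots."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    common = dict(label_a="all-aliquots", label_b="", n_a=int(pooled.size), n_b=0,
                  median_a=float(np.median(pooled)), median_b=float("nan"),
                  feature=feature, method="kruskal")
    if np.all(pooled == pooled[0]):
        return ComparisonResult(statistic=0.0, pvalue=1.0, direction="none", **common)
    stat, p = sps.kruskal(*arrays)
    return ComparisonResult(statistic=float(stat), pvalue=min(1.0, float(p)),
                            direction="none", **common)


def adjust_bh(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = list(pvalues)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise InputValidationError("adjust_bh: p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(arr, method="fdr_bh")[1]]
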