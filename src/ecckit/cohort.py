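"""Group-level statistics: EPM comparison, correlations, length-distribution
comparison and miRNA-circle recurrence across samples.

The two-group EPM test is a two-sided rank-sum (Wilcoxon/Mann-Whitney):
exact by full enumeration over pooled midranks when both groups have <= 10
samples, normal approximation with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SampleCircleSet, epm
from .genome import AnnotationSet

__all__ = [
    "GroupComparison",
    "MirnaCircleHit",
    "rank_sum_test",
    "compare_epm",
    "correlate",
    "mirna_recurrence",
    "compare_length_distributions",
]

EXACT_MAX_N = 10


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    p_value: float
    test: str


@dataclass
class MirnaCircleHit:
    mirna_id: str
    sample_ids: list[str]
    recurrence: int
    total_circles: int
    circle_coords: list[tuple[str, int, int]]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Two-sided rank-sum p-value.

    Exact: enumerate every assignment of pooled midranks to group x
    (handles ties; used when both n <= 10). Otherwise the normal
    approximation with tie correction (scipy Mann-Whitney U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)  # midranks under ties
        w_obs = ranks[:n1].sum()
        e_w = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(w_obs - e_w)
        total = more = 0
        for idx in combinations(range(n1 + n2), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - e_w) >= dev - 1e-12:
                more += 1
        return more / total, "rank-sum (exact enumeration)"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "rank-sum (normal approximation)"


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(values.mean())
    if len(values) < 2:
        return m, (m, m)
    se = float(values.std(ddof=1) / np.sqrt(len(values)))
    return m, (m - 1.96 * se, m + 1.96 * se)


def compare_epm(
    samples_a: Sequence[SampleCircleSet],
    samples_b: Sequence[SampleCircleSet],
) -> GroupComparison:
    """Two-group EPM comparison with normal-theory 95% CIs."""
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("need at least 3 samples per group")
    epm_a = np.array([epm(s) for s in samples_a])
    epm_b = np.array([epm(s) for s in samples_b])
    p, test = rank_sum_test(epm_a, epm_b)
    mean_a, ci_a = _mean_ci(epm_a)
    mean_b, ci_b = _mean_ci(epm_b)
    return GroupComparison(
        group_a=samples_a[0].group,
        group_b=samples_b[0].group,
        mean_a=mean_a,
        mean_b=mean_b,
        ci95_a=ci_a,
        ci95_b=ci_b,
        p_value=p,
        test=test,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    if np.std(y) == 0:
        raise ValueError("zero variance in y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mirna_recurrence(
    samples: Sequence[SampleCircleSet],
    mirna_annotations: AnnotationSet,
    top_n: int = 20,
    mirna_class: str = "miRNA",
) -> list[MirnaCircleHit]:
    """Rank miRNA genes by cross-sample recurrence of fully-containing circles.

    A circle carries a miRNA when circle.start <= mirna.start and
    mirna.end <= circle.end. Recurrence counts distinct samples with >= 1
    carrying circle; ties rank by total carrying-circle count, then id.
    """
    mirnas = mirna_annotations.by_class(mirna_class)
    hits: list[MirnaCircleHit] = []
    for m in mirnas.itertuples(index=False):
        sample_ids: list[str] = []
        coords: list[tuple[str, int, int]] = []
        total = 0
        for s in samples:
            carrying = [
                c
                for c in s.circles
                if c.chrom == m.chrom and c.start <= m.start and m.end <= c.end
            ]
            if carrying:
                sample_ids.append(s.sample_id)
                total += len(carrying)
                coords.extend((c.chrom, c.start, c.end) for c in carrying)
        if sample_ids:
            hits.append(
                MirnaCircleHit(
                    mirna_id=str(m.name),
                    sample_ids=sample_ids,
                    recurrence=len(sample_ids),
                    total_circles=total,
                    circle_coords=coords,
                )
            )
    hits.sort(key=lambda h: (-h.recurrence, -h.total_circles, h.mirna_id))
    return hits[:top_n]


def compare_length_distributions(
    samples_a: Sequence[SampleCircleSet],
    samples_b: Sequence[SampleCircleSet],
    bin_width: int = 10,
) -> dict:
    """Pooled per-group circle-length comparison.

    Shared-bin histograms always; a two-sided rank-sum p on the pooled
    per-circle lengths when both groups have >= 100 circles.
    """
    len_a = np.array([c.length for s in samples_a for c in s.circles], dtype=float)
    len_b = np.array([c.length for s in samples_b for c in s.circles], dtype=float)
    hi = max(len_a.max() if len(len_a) else 0, len_b.max() if len(len_b) else 0)
    edges = np.arange(0, hi + bin_width, bin_width)
    hist_a, _ = np.histogram(len_a, bins=edges)
    hist_b, _ = np.histogram(len_b, bins=edges)
    out = {
        "bin_edges": edges,
        "hist_a": hist_a,
        "hist_b": hist_b,
        "n_a": len(len_a),
        "n_b": len(len_b),
        "p_value": None,
    }
    if len(len_a) >= 100 and len(len_b) >= 100:
        if np.all(len_a == len_a[0]) and np.all(len_b == len_b[0]) and len_a[0] == len_b[0]:
            out["p_value"] = 1.0
        else:
            res = stats.mannwhitneyu(len_a, len_b, alternative="two-sided",
                                     method="asymptotic")
            out["p_value"] = float(res.pvalue)
    return out
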