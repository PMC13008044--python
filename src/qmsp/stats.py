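"""Group-level summaries and comparisons of methylation results.

Methylation percentages are summarized as median and interquartile
range.  Two-group comparisons are gated on normality (Shapiro-Wilk at
alpha = 0.05): normal data use the t-test (paired or unpaired), non-
normal data the Wilcoxon matched-pairs signed-rank test (paired) or
Mann-Whitney U test (unpaired).  For paired designs the gate is applied
to the paired differences.  More than two groups use the Kruskal-Wallis
test; age association uses Spearman's rank correlation.  All p-values
are two-sided and no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .quantify import MethylationResult

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "compare_two_groups",
    "compare_multi",
    "correlate_age",
    "ok_levels",
]

NORMALITY_ALPHA = 0.05


def ok_levels(results: Iterable[MethylationResult]) -> np.ndarray:
    """Usable methylation percentages (OK and ZERO_SIGNAL rows)."""
    return np.array(
        [r.methylation_pct for r in results if r.status in ("OK", "ZERO_SIGNAL")],
        dtype=float,
    )


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    median_pct: float
    q1: float
    q3: float
    mean: float
    sd: float
    n_excluded: int = 0

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)


def _as_values(group: Sequence[float] | Sequence[MethylationResult]) -> tuple[np.ndarray, int]:
    seq = list(group)
    if seq and isinstance(seq[0], MethylationResult):
        vals = ok_levels(seq)
        return vals, len(seq) - len(vals)
    return np.asarray(seq, dtype=float), 0


def summarize_group(group: Sequence[float] | Sequence[MethylationResult], label: str = "") -> GroupSummary:
    """Median, IQR (linear-interpolation quartiles), mean and SD of one group.

    Accepts raw percentages or MethylationResult rows; EXCLUDED rows are
    omitted and counted.
    """
    values, n_excluded = _as_values(group)
    if len(values) == 0:
        raise ValueError("group has no usable results")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return GroupSummary(
        label=label,
        n=len(values),
        median_pct=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, ...]
    paired: bool
    test_name: str
    statistic: float
    p_value: float
    normality_p: tuple[float, ...] = ()


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        # constant data: not Gaussian in any useful sense
        return 0.0
    return float(sps.shapiro(x).pvalue)


def compare_two_groups(
    a: Sequence[float] | Sequence[MethylationResult],
    b: Sequence[float] | Sequence[MethylationResult],
    paired: bool = False,
    labels: tuple[str, str] = ("a", "b"),
    normality_alpha: float = NORMALITY_ALPHA,
) -> ComparisonResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Paired and normal differences -> paired t-test; paired and non-normal
    -> Wilcoxon signed-rank; unpaired and both groups normal -> unpaired
    t-test; otherwise Mann-Whitney U.  Identical paired samples (all
    differences zero) are reported as a degenerate no-signal comparison
    with p = 1.
    """
    xa, _ = _as_values(a)
    xb, _ = _as_values(b)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("each group needs at least 3 usable values")
    if paired:
        if len(xa) != len(xb):
            raise ValueError("paired groups must have equal length and matched order")
        diffs = xa - xb
        if np.all(diffs == 0):
            return ComparisonResult(labels, True, "degenerate (identical pairs)", math.nan, 1.0, (0.0,))
        p_norm = _shapiro_p(diffs)
        if p_norm > normality_alpha:
            stat, p = sps.ttest_rel(xa, xb)
            name = "paired t-test"
        else:
            stat, p = sps.wilcoxon(xa, xb)
            name = "Wilcoxon signed-rank"
        return ComparisonResult(labels, True, name, float(stat), float(p), (p_norm,))
    p_na, p_nb = _shapiro_p(xa), _shapiro_p(xb)
    if p_na > normality_alpha and p_nb > normality_alpha:
        stat, p = sps.ttest_ind(xa, xb)
        name = "unpaired t-test"
    else:
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        name = "Mann-Whitney U"
    return ComparisonResult(labels, False, name, float(stat), float(p), (p_na, p_nb))


def compare_multi(
    groups: Sequence[Sequence[float] | Sequence[MethylationResult]],
    labels: Sequence[str] | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis comparison of three or more groups."""
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis comparison needs >= 3 groups")
    arrays = [_as_values(g)[0] for g in groups]
    if any(len(x) < 3 for x in arrays):
        raise ValueError("each group needs at least 3 usable values")
    stat, p = sps.kruskal(*arrays)
    labs = tuple(labels) if labels is not None else tuple(f"g{i + 1}" for i in range(len(groups)))
    return ComparisonResult(labs, False, "Kruskal-Wallis", float(stat), float(p))


def correlate_age(ages: Sequence[float], levels: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p) of age and methylation."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(levels, dtype=float)
    if len(x) != len(y):
        raise ValueError("ages and levels must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
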