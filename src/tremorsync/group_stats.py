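"""Group-level summaries of percent-change values.

Planned one-sample contrasts of the per-subject percent changes against
zero (two-tailed Student's t with Cohen's d as effect size), an exact
Wilcoxon signed-rank test for ordinal phosphene ratings, and
Benjamini-Hochberg FDR adjustment within a user-declared family of
comparisons. Omnibus repeated-measures machinery (ANOVA, sphericity and
normality checks) is deliberately left to stock statistics routines — this
module only provides the tidy per-condition tables they consume.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import DegenerateInputError, ValidationError

__all__ = [
    "ContrastResult",
    "one_sample_contrast",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "contrast_table",
]


@dataclasses.dataclass
class ContrastResult:
    """Two-tailed one-sample t contrast against zero."""

    condition: str
    mean_pct_change: float
    sem: float
    t_stat: float
    df: int
    p_two_sided: float
    cohens_d: float


def one_sample_contrast(
    values: Sequence[float], condition: str = ""
) -> ContrastResult:
    """t = mean / (sd / sqrt(n)) against zero; d = mean / sd.

    Degrees of freedom are n - 1 and the p-value is two-sided from the t
    distribution.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values for a one-sample contrast")
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero variance: t statistic undefined")
    n = x.size
    mean = float(x.mean())
    sem = sd / np.sqrt(n)
    t = mean / sem
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return ContrastResult(
        condition=condition,
        mean_pct_change=mean,
        sem=float(sem),
        t_stat=float(t),
        df=n - 1,
        p_two_sided=min(p, 1.0),
        cohens_d=mean / sd,
    )


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the positive-rank sum over all 2^n equiprobable sign flips.

    ``ranks2`` are doubled ranks (integers even with midrank ties); entry k
    of the result counts assignments with doubled rank sum k.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(values: Sequence[float]) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank test of ratings against zero.

    Zeros are dropped (standard convention), absolute values are midranked,
    and the statistic is the sum of ranks of the positive values. For
    n <= 25 the two-sided p-value is exact, from the full distribution of
    the rank sum under random sign assignment; larger samples use the
    normal approximation with tie correction.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must be finite")
    x = x[x != 0]
    n = x.size
    if n == 0:
        raise DegenerateInputError("all values are zero")
    ranks = stats.rankdata(np.abs(x))
    w_pos = float(ranks[x > 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w_pos - mean) / np.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return w_pos, float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted adjusted values are ``p_(k) * m / k`` made monotone by a
    cumulative minimum from the largest p downward, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def contrast_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-condition contrasts of subject percent changes, FDR-adjusted.

    ``summary`` is the per-subject condition summary table (columns
    ``subject_id``, ``condition``, ``pct_change``); the conditions present
    form the FDR family.
    """
    rows = []
    for condition, sub in summary.groupby("condition", sort=False):
        res = one_sample_contrast(sub["pct_change"].to_numpy(), str(condition))
        rows.append(dataclasses.asdict(res))
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p_two_sided"].to_numpy())
    return table
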