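"""Group summaries and one-way ANOVA with Fisher's protected LSD.

The inferential recipe of classical hemodynamic studies: per-group
mean +/- SEM, an omnibus one-way ANOVA, and — only when the omnibus F is
significant — pairwise t tests using the pooled within-group mean square
and its degrees of freedom (Fisher's protected least significant
difference).  No further multiplicity correction is applied beyond the
protection step.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    outcome: str
    summaries: tuple[GroupSummary, ...]
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    alpha: float
    pairwise: tuple[PairwiseTest, ...]

    @property
    def significant(self) -> bool:
        return self.anova_p < self.alpha


def summarize(groups: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Per-group n, arithmetic mean and SEM (sample SD / sqrt(n))."""
    out = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        out.append(GroupSummary(group=name, n=int(v.size),
                                mean=float(np.mean(v)),
                                sem=float(np.std(v, ddof=1) / np.sqrt(v.size))))
    return out


def anova_fisher_plsd(groups: Mapping[str, Sequence[float]],
                      alpha: float = 0.05,
                      outcome: str = "") -> GroupComparison:
    """One-way ANOVA followed by Fisher's protected LSD at ``alpha``.

    F = MS_between / MS_within with the textbook sums of squares.  When
    the omnibus p is below ``alpha``, each pair is tested with
    ``t = diff / sqrt(MSW (1/n_i + 1/n_j))`` on the full within-group
    degrees of freedom; otherwise all pairwise flags are false
    (the protection rule).  Zero within-group variance with unequal
    means is reported as p = 0; fully identical data are an error.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if any(v.size < 2 for v in data):
        raise ValueError("every group needs n >= 2")

    k = len(data)
    ns = np.array([v.size for v in data])
    big_n = int(ns.sum())
    grand = float(np.concatenate(data).mean())
    means = np.array([v.mean() for v in data])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - v.mean()) ** 2) for v in data))
    df_b, df_w = k - 1, big_n - k

    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("all observations identical: F undefined (0/0)")
    if ss_within == 0.0:
        f_stat, p = np.inf, 0.0
        msw = 0.0
    else:
        msw = ss_within / df_w
        f_stat = (ss_between / df_b) / msw
        p = float(sps.f.sf(f_stat, df_b, df_w))

    pairwise = []
    protected = p < alpha
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        diff = float(means[i] - means[j])
        if protected and msw > 0:
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
            t = diff / se
            p_ij = float(2.0 * sps.t.sf(abs(t), df_w))
            sig = p_ij < alpha
        elif protected:                      # msw == 0, unequal means
            t, p_ij = np.inf if diff > 0 else -np.inf, 0.0
            sig = diff != 0.0
        else:
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j])) if msw > 0 else np.nan
            t = diff / se if msw > 0 else np.nan
            p_ij = float(2.0 * sps.t.sf(abs(t), df_w)) if msw > 0 else np.nan
            sig = False
        pairwise.append(PairwiseTest(a, b, diff, float(t), p_ij, sig))

    return GroupComparison(
        outcome=outcome,
        summaries=tuple(summarize({g: groups[g] for g in names})),
        anova_f=float(f_stat), anova_p=float(p),
        df_between=df_b, df_within=df_w, alpha=alpha,
        pairwise=tuple(pairwise))
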