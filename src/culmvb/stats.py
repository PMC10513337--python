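"""Group-comparison machinery: ANOVA + Tukey HSD, Kruskal–Wallis + DSCF,
and compact letter displays.

The all-pairs post-hoc tests reference the studentized-range distribution:
Tukey's HSD with N−k error degrees of freedom after a one-way ANOVA, and the
Dwass–Steel–Critchlow–Fligner (DSCF) rank test with infinite degrees of
freedom after a Kruskal–Wallis test. The DSCF statistic for a pair (i, j)
re-ranks only those two groups jointly:

    W     = rank sum of group i
    E[W]  = n_i (n_i + n_j + 1) / 2
    Var   = n_i n_j / 12 · [ (N + 1) − Σ(t³ − t) / (N (N − 1)) ],  N = n_i+n_j
    q     = √2 · |W − E[W]| / √Var

with t the tie-group sizes of the joint sample, and p the upper tail of the
studentized range with k groups. If every value in a pair is tied Var = 0
and p = 1 by convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseResult",
    "anova_tukey",
    "kruskal_dscf",
    "compact_letters",
    "pairwise_to_frame",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class PairwiseResult:
    group_a: int
    group_b: int
    statistic: float
    p_value: float
    significant: bool

    @property
    def pair(self) -> frozenset:
        return frozenset((self.group_a, self.group_b))


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    return gs


def anova_tukey(groups, alpha: float = ALPHA_DEFAULT):
    """One-way ANOVA with Tukey HSD all-pairs comparisons.

    Pairwise q_ij = |ȳ_i − ȳ_j| / sqrt(MSE (1/n_i + 1/n_j) / 2), referred to
    the studentized range with k groups and N − k degrees of freedom
    (Tukey–Kramer for unequal group sizes).
    """
    gs = _check_groups(groups)
    k = len(gs)
    ns = np.array([g.size for g in gs])
    N = int(ns.sum())
    F, p_global = sps.f_oneway(*gs)

    means = np.array([g.mean() for g in gs])
    sse = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_err = N - k
    mse = sse / df_err

    results = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0)
        if se == 0.0:
            q, p = 0.0, 1.0
        else:
            q = abs(means[i] - means[j]) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
        results.append(PairwiseResult(i, j, q, p, p < alpha))
    return float(F), float(p_global), results


def _dscf_pair(x: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    n_i, n_j = x.size, y.size
    N = n_i + n_j
    joint = np.concatenate([x, y])
    ranks = sps.rankdata(joint)
    W = ranks[:n_i].sum()
    expected = n_i * (N + 1) / 2.0
    _, counts = np.unique(joint, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
    var = n_i * n_j / 12.0 * ((N + 1) - tie_term)
    if var <= 0:  # all values tied across the pair
        return 0.0, 1.0
    q = math.sqrt(2.0) * abs(W - expected) / math.sqrt(var)
    p = float(sps.studentized_range.sf(q, k, np.inf))
    return q, p


def kruskal_dscf(groups, alpha: float = ALPHA_DEFAULT):
    """Kruskal–Wallis test with DSCF all-pairs post-hoc comparisons."""
    gs = _check_groups(groups)
    k = len(gs)
    joint = np.concatenate(gs)
    if np.all(joint == joint[0]):  # every value tied: no evidence of shift
        H, p_global = 0.0, 1.0
    else:
        H, p_global = sps.kruskal(*gs)
    results = []
    for i, j in itertools.combinations(range(k), 2):
        q, p = _dscf_pair(gs[i], gs[j], k)
        results.append(PairwiseResult(i, j, q, p, p < alpha))
    return float(H), float(p_global), results


def compact_letters(
    pairwise: list[PairwiseResult], alpha: float = ALPHA_DEFAULT
) -> dict[int, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise comparison is not
    significant at ``alpha``. Letter count is not guaranteed minimal; the
    sharing relation is.
    """
    sig: dict[frozenset, bool] = {}
    groups: set[int] = set()
    for r in pairwise:
        key = r.pair
        flag = r.p_value < alpha
        if key in sig and sig[key] != flag:
            raise ValueError(f"conflicting significance for pair {sorted(key)}")
        sig[key] = flag
        groups.update(key)
    order = sorted(groups)
    for a, b in itertools.combinations(order, 2):
        if frozenset((a, b)) not in sig:
            raise ValueError(f"missing pairwise comparison for ({a}, {b})")

    # insert-and-absorb: start from one letter holding every group; each
    # significant pair splits any letter containing both; subsets are absorbed.
    letters: list[set[int]] = [set(order)]
    for key, flag in sig.items():
        if not flag:
            continue
        i, j = sorted(key)
        nxt: list[set[int]] = []
        for s in letters:
            if i in s and j in s:
                nxt.append(s - {i})
                nxt.append(s - {j})
            else:
                nxt.append(s)
        # absorb sets contained in another
        letters = [
            s for si, s in enumerate(nxt)
            if s and not any(
                (s < t) or (s == t and si > ti) for ti, t in enumerate(nxt)
            )
        ]
    letters.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for li, s in enumerate(letters):
        for g in sorted(s):
            out[g] += alphabet[li % len(alphabet)]
    return out


def pairwise_to_frame(pairwise: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_a": [r.group_a for r in pairwise],
            "group_b": [r.group_b for r in pairwise],
            "statistic": [r.statistic for r in pairwise],
            "p_value": [r.p_value for r in pairwise],
            "significant": [r.significant for r in pairwise],
        }
    )
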