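"""Nonparametric group comparison with stepdown homogeneous subsets.

Groups are compared with the Kruskal-Wallis test (tie-corrected mid-ranks,
chi-square approximation), followed by Campbell-Skillings stepwise stepdown
multiple comparisons: groups are ordered by mean rank, and contiguous
ordered subsets are tested hierarchically — a subset is examined only after
every contiguous superset on some trimming chain proved significant, and is
declared homogeneous when its own within-subset Kruskal-Wallis test (ranks
recomputed within the subset) is non-significant at a size-adjusted level

    alpha_p = 1 - (1 - alpha)^(p/k)   for subset size p <= k - 2,
    alpha_p = alpha                   for p in {k - 1, k},

the standard allocation of mainstream stepwise-stepdown routines. Maximal
homogeneous subsets are reported and rendered as a compact-letter display:
groups that share a letter do not differ significantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_lowercase
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "stepdown_subsets",
    "compare_traits",
    "format_table",
    "table_markdown",
]


@dataclass
class GroupComparison:
    """Kruskal-Wallis result plus stepdown homogeneous subsets for one trait."""

    trait: str
    H: float
    p: float
    subsets: list[list[str]]
    letters: dict[str, str]
    alpha: float
    mean_ranks: dict[str, float] = field(default_factory=dict)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p-value over two or more samples.

    Mid-ranks with tie correction; k - 1 degrees of freedom. If every
    observation is identical the test is degenerate and (0, 1) is returned.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def _alpha_p(p_size: int, k: int, alpha: float) -> float:
    if p_size >= k - 1:
        return alpha
    return 1.0 - (1.0 - alpha) ** (p_size / k)


def stepdown_subsets(
    samples: Mapping[str, Sequence[float]], alpha: float = 0.05, trait: str = ""
) -> GroupComparison:
    """Campbell-Skillings stepdown homogeneous subsets with letter display.

    ``samples`` maps group label to its observations. Groups are ordered by
    mean mid-rank in the pooled ranking; the closed family of contiguous
    ordered subsets is traversed top-down as described in the module
    docstring.
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in labels}

    pooled = np.concatenate([arrays[g] for g in labels])
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for g in labels:
        n = arrays[g].size
        mean_ranks[g] = float(ranks[pos : pos + n].mean())
        pos += n
    order = sorted(labels, key=lambda g: (mean_ranks[g], g))
    k = len(order)

    H_all, p_all = kruskal_wallis([arrays[g] for g in order])

    sig_cache: dict[tuple[int, int], bool] = {}

    def significant(i: int, j: int) -> bool:
        """Is the contiguous subset order[i..j] heterogeneous at its level?"""
        key = (i, j)
        if key not in sig_cache:
            size = j - i + 1
            _, p = kruskal_wallis([arrays[g] for g in order[i : j + 1]])
            sig_cache[key] = p < _alpha_p(size, k, alpha)
        return sig_cache[key]

    # reachability: a subset is tested iff the full set reaches it through a
    # chain of significant (hence further-split) supersets
    reached: dict[tuple[int, int], bool] = {(0, k - 1): True}
    homogeneous: list[tuple[int, int]] = []
    frontier = [(0, k - 1)]
    while frontier:
        i, j = frontier.pop()
        if i == j:
            homogeneous.append((i, j))
            continue
        if not significant(i, j):
            homogeneous.append((i, j))
            continue
        for child in ((i, j - 1), (i + 1, j)):
            if not reached.get(child):
                reached[child] = True
                frontier.append(child)

    # maximal subsets only
    homogeneous = sorted(set(homogeneous))
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in homogeneous)
    ]
    maximal.sort()

    letters = {g: "" for g in order}
    for idx, (i, j) in enumerate(maximal):
        letter = ascii_lowercase[idx] if idx < 26 else f"z{idx}"
        for g in order[i : j + 1]:
            letters[g] += letter
    subsets = [[g for g in order[i : j + 1]] for i, j in maximal]

    return GroupComparison(
        trait=trait, H=H_all, p=p_all, subsets=subsets,
        letters=letters, alpha=alpha, mean_ranks=mean_ranks,
    )


def compare_traits(
    df: pd.DataFrame,
    group_col: str,
    trait_cols: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, GroupComparison]:
    """Run the stepdown comparison for each trait column of a long table."""
    out = {}
    for trait in trait_cols:
        samples = {
            str(g): sub[trait].dropna().to_numpy()
            for g, sub in df.groupby(group_col, sort=True)
        }
        out[trait] = stepdown_subsets(samples, alpha=alpha, trait=trait)
    return out


def format_table(
    df: pd.DataFrame,
    comparisons: Mapping[str, GroupComparison],
    group_col: str,
) -> pd.DataFrame:
    """Render "mean ^letters^ (CV)" cells per group and trait.

    Mirrors the published layout: one row per group, one column per trait,
    plus the group sizes; groups sharing a letter within a column do not
    differ significantly. With a single group no letters are emitted.
    """
    groups = sorted(df[group_col].astype(str).unique())
    trait_cols = list(comparisons)
    for trait, comp in comparisons.items():
        if comp.letters and set(comp.letters) != set(groups):
            raise ValueError(f"group set mismatch for trait {trait!r}")
    rows = []
    for g in groups:
        sub = df[df[group_col].astype(str) == g]
        row = {group_col: g, "N": len(sub)}
        for trait in trait_cols:
            vals = sub[trait].dropna().to_numpy()
            mean = vals.mean()
            cv = vals.std(ddof=1) / mean * 100.0 if mean else np.nan
            letters = comparisons[trait].letters.get(g, "") if len(groups) > 1 else ""
            tag = f" ^{letters}^" if letters else ""
            row[trait] = f"{mean:.2f}{tag} ({cv:.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def table_markdown(table: pd.DataFrame) -> str:
    """Plain GitHub-style markdown rendering of a formatted table."""
    cols = list(table.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"
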