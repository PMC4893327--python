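"""Nonparametric multi-group comparison: Kruskal–Wallis omnibus, Nemenyi
all-pairs post-hoc, and compact letter displays.

The Nemenyi test operates on the mean ranks of the pooled sample.  Two
variants are provided:

* ``"chi2"`` (default) — the chi-square approximation appropriate for tied
  data: for groups i, j with mean ranks R̄_i, R̄_j and sizes n_i, n_j,

      stat_ij = (R̄_i − R̄_j)² / [ (N(N+1)/12 − T) · (1/n_i + 1/n_j) ],
      T = Σ(t³ − t) / (12 (N − 1))  over tie groups of size t,

  referred to a chi-square distribution with k − 1 degrees of freedom;
* ``"tukey"`` — the studentized-range approximation,
  q_ij = |R̄_i − R̄_j| / sqrt( (N(N+1)/24) · (1/n_i + 1/n_j) ),
  referred to the studentized range distribution with k groups and
  infinite degrees of freedom.

The compact letter display assigns shared letters to groups that are not
significantly different (insert-and-absorb algorithm), as used to annotate
multi-group boxplots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MultiGroupReport", "rank_compare", "nemenyi_test", "compact_letter_display"]


@dataclass(frozen=True)
class MultiGroupReport:
    """Omnibus + pairwise outcome of a k-group rank comparison."""

    h: float
    df: int
    p: float
    n: int
    group_sizes: dict
    mean_ranks: dict
    pairwise_p: pd.DataFrame  # symmetric matrix of Nemenyi p-values
    letters: dict  # group -> letter string, shared letter = indistinguishable
    dropped: tuple = ()  # groups excluded for having < 2 records


def _tie_term(ranks: np.ndarray) -> float:
    """Σ(t³ − t) over tie groups of the pooled ranks."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def nemenyi_test(groups: Mapping[str, Sequence[float]], dist: str = "chi2") -> pd.DataFrame:
    """All-pairs Nemenyi p-value matrix on the pooled-rank scale."""
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    sizes = np.array([v.size for v in values])
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(float(np.mean(ranks[start:start + size])))
        start += size
    mean_ranks = np.array(mean_ranks)
    k = len(labels)

    pmat = np.ones((k, k))
    if dist == "chi2":
        tie = _tie_term(ranks) / (12.0 * (n_total - 1))
        scale = n_total * (n_total + 1) / 12.0 - tie
        for i in range(k):
            for j in range(i + 1, k):
                var = scale * (1.0 / sizes[i] + 1.0 / sizes[j])
                stat = (mean_ranks[i] - mean_ranks[j]) ** 2 / var if var > 0 else 0.0
                pmat[i, j] = pmat[j, i] = stats.chi2.sf(stat, k - 1)
    elif dist == "tukey":
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(n_total * (n_total + 1) / 24.0
                             * (1.0 / sizes[i] + 1.0 / sizes[j]))
                q = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
                pmat[i, j] = pmat[j, i] = stats.studentized_range.sf(q, k, np.inf)
    else:
        raise ValueError(f"unknown Nemenyi variant {dist!r}")
    return pd.DataFrame(pmat, index=labels, columns=labels)


def compact_letter_display(pairwise_p: pd.DataFrame, alpha: float = 0.05,
                           order: Optional[Sequence[str]] = None) -> dict:
    """Assign letters so that groups sharing a letter are indistinguishable.

    Insert-and-absorb: start from one letter covering all groups; for every
    significant pair split the letters containing both; drop letters that
    became subsets of others.  ``order`` controls letter naming (default:
    matrix order).
    """
    labels = list(order) if order is not None else list(pairwise_p.index)
    sets = [set(labels)]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if pairwise_p.loc[a, b] < alpha:
                for s in [s for s in sets if a in s and b in s]:
                    sets.remove(s)
                    sets.extend([s - {a}, s - {b}])
                # absorb subsets
                sets = [s for s in sets
                        if s and not any(s < t for t in sets if t is not s)]
                # deduplicate while preserving order
                seen, unique = [], []
                for s in sets:
                    if s not in seen:
                        seen.append(s)
                        unique.append(s)
                sets = unique
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # name letters in the order groups appear
    sets.sort(key=lambda s: min(labels.index(g) for g in s))
    out = {g: "" for g in labels}
    for letter, s in zip(alphabet, sets):
        for g in labels:
            if g in s:
                out[g] += letter
    return out


def rank_compare(groups: Mapping[str, Sequence[float]], *, alpha: float = 0.05,
                 nemenyi: str = "chi2", min_size: int = 2) -> MultiGroupReport:
    """Kruskal–Wallis omnibus (tie-corrected) plus Nemenyi pairwise letters.

    Groups with fewer than ``min_size`` values are excluded with a warning.
    With every pooled value identical the omnibus is reported as H = 0,
    p = 1 (all tied, no evidence of differences).
    """
    kept = {g: np.asarray(v, dtype=float) for g, v in groups.items()
            if len(v) >= min_size}
    dropped = tuple(g for g in groups if g not in kept)
    if dropped:
        warnings.warn(f"excluding group(s) with < {min_size} records: {dropped}",
                      stacklevel=2)
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with enough records")

    values = list(kept.values())
    n = int(sum(v.size for v in values))
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0.0:
        h, p = 0.0, 1.0  # every observation tied: degenerate, defined as no signal
    else:
        h, p = stats.kruskal(*values)
    pmat = nemenyi_test(kept, dist=nemenyi)

    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for g, v in kept.items():
        mean_ranks[g] = float(np.mean(ranks[start:start + v.size]))
        start += v.size

    order = sorted(kept, key=lambda g: -mean_ranks[g])
    letters = compact_letter_display(pmat, alpha=alpha, order=order)
    return MultiGroupReport(
        h=float(h),
        df=len(kept) - 1,
        p=float(p),
        n=n,
        group_sizes={g: int(v.size) for g, v in kept.items()},
        mean_ranks=mean_ranks,
        pairwise_p=pmat,
        letters=letters,
        dropped=dropped,
    )
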