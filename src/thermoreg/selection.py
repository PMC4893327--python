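"""Microhabitat selection versus availability.

Compares what lizards used (capture-point variables, microhabitat
frequencies) against what the habitat offered (availability points placed
1 m from captures in the four cardinal directions):

* continuous variables (air/substrate temperature, refuge distance,
  perch height): Kruskal–Wallis across species A / species B /
  availability with Nemenyi pairwise comparisons;
* microhabitat frequencies: exact contingency test (Fisher for 2×2,
  seeded Monte-Carlo exact test on the conditional hypergeometric
  distribution for wider tables);
* direct species contrasts: Mann–Whitney U, one-way ANOVA, or Levene's
  variance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .posthoc import MultiGroupReport, rank_compare
from .records import AvailabilityPoint, BodyTempRecord

__all__ = [
    "used_vs_available",
    "frequency_selection_test",
    "species_contrast",
    "FrequencyTestResult",
    "ContrastResult",
    "AVAILABILITY_LABEL",
]

log = logging.getLogger("thermoreg.selection")

AVAILABILITY_LABEL = "availability"

#: capture/availability variables that can be compared
SELECTION_VARIABLES = ("ta_c", "ts_c", "refuge_cm", "height_cm")


def _extract(records: Sequence, variable: str) -> np.ndarray:
    vals = []
    missing = 0
    for r in records:
        v = getattr(r, variable)
        if v is None:
            missing += 1
        else:
            vals.append(float(v))
    if missing:
        log.info("%d records missing %s, excluded", missing, variable)
    return np.asarray(vals, dtype=float)


def used_vs_available(
    used: Mapping[str, Sequence[BodyTempRecord]],
    available: Sequence[AvailabilityPoint],
    variable: str,
    *,
    alpha: float = 0.05,
) -> MultiGroupReport:
    """Kruskal–Wallis + Nemenyi on one variable across species and availability.

    ``used`` maps species label → capture records.  Missing values are
    excluded per variable (with logged counts); each group must retain at
    least 2 values.
    """
    if variable not in SELECTION_VARIABLES:
        raise ValueError(
            f"unknown selection variable {variable!r}; expected one of {SELECTION_VARIABLES}"
        )
    groups = {sp: _extract(recs, variable) for sp, recs in used.items()}
    groups[AVAILABILITY_LABEL] = _extract(available, variable)
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 non-missing {variable} values")
    return rank_compare(groups, alpha=alpha)


@dataclass(frozen=True)
class FrequencyTestResult:
    """Outcome of the exact use-vs-availability frequency test."""

    p: float
    table: np.ndarray  # 2 x k: rows (used, available), columns categories
    categories: tuple
    method: str  # "fisher_exact" (2x2) or "monte_carlo" (2xk)
    n_mc: Optional[int] = None
    seed: Optional[int] = None


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of a table under fixed margins (multivariate hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
        - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def frequency_selection_test(
    used_counts: Mapping[str, int],
    available_counts: Mapping[str, int],
    *,
    seed: Optional[int] = None,
    n_mc: int = 20000,
) -> FrequencyTestResult:
    """Exact test of microhabitat-frequency selection versus availability.

    Builds the 2×k table (rows: used, available; columns: the union of
    categories) and tests independence.  For k = 2 this is Fisher's exact
    test.  For k > 2 the exact conditional p-value is estimated by
    Monte-Carlo: tables with the observed margins are sampled (Patefield
    algorithm) and the p-value is the share whose conditional probability
    does not exceed the observed one, with the observed table included
    (add-one rule); the result records the method and seed.
    """
    cats = tuple(sorted(set(used_counts) | set(available_counts)))
    if len(cats) < 2:
        raise ValueError("need at least 2 microhabitat categories")
    table = np.array(
        [[int(used_counts.get(c, 0)) for c in cats],
         [int(available_counts.get(c, 0)) for c in cats]]
    )
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("a margin of the contingency table is all zero")

    if len(cats) == 2:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return FrequencyTestResult(p=float(p), table=table, categories=cats,
                                   method="fisher_exact")

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    samples = sampler.rvs(n_mc, method="patefield", random_state=rng)
    logp_obs = _log_table_prob(table)
    logp_sim = np.array([_log_table_prob(t) for t in np.asarray(samples, dtype=float)])
    # tolerance guards against ties lost to rounding in the log domain
    hits = int(np.sum(logp_sim <= logp_obs + 1e-9))
    p = (hits + 1.0) / (n_mc + 1.0)
    return FrequencyTestResult(p=float(p), table=table, categories=cats,
                               method="monte_carlo", n_mc=n_mc, seed=seed)


@dataclass(frozen=True)
class ContrastResult:
    """A named two-sample contrast."""

    method: str
    statistic_name: str
    statistic: float
    df: Optional[tuple]
    p: float
    n: tuple


def species_contrast(
    a: Sequence[float],
    b: Sequence[float],
    method: str,
    *,
    levene_center: str = "mean",
) -> ContrastResult:
    """Two-sample contrast by the named method.

    ``method`` is one of ``"mann_whitney"`` (location, rank-based),
    ``"anova"`` (location, one-way F) or ``"levene"`` (spread; classic
    mean-centred by default, ``levene_center="median"`` gives the
    Brown–Forsythe-robust variant).  Two identical samples are reported
    with p = 1 by convention.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")

    identical = np.ptp(np.concatenate([a, b])) == 0.0
    if method == "mann_whitney":
        if identical:
            return ContrastResult("mann_whitney", "U", a.size * b.size / 2.0,
                                  None, 1.0, (a.size, b.size))
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ContrastResult("mann_whitney", "U", float(res.statistic), None,
                              float(res.pvalue), (a.size, b.size))
    if method == "anova":
        if identical:
            return ContrastResult("anova", "F", 0.0, (1, a.size + b.size - 2),
                                  1.0, (a.size, b.size))
        f, p = stats.f_oneway(a, b)
        return ContrastResult("anova", "F", float(f), (1, a.size + b.size - 2),
                              float(p), (a.size, b.size))
    if method == "levene":
        if identical:
            return ContrastResult("levene", "W", 0.0, (1, a.size + b.size - 2),
                                  1.0, (a.size, b.size))
        w, p = stats.levene(a, b, center=levene_center)
        return ContrastResult("levene", "W", float(w), (1, a.size + b.size - 2),
                              float(p), (a.size, b.size))
    raise ValueError(f"unknown method {method!r}")


def microhabitat_counts(records: Sequence, *,
                        other: tuple = ("grass", "log")) -> dict:
    """Tally microhabitat labels, folding minor categories into 'other'.

    Mirrors the field convention of reporting grass and logs together.
    Records without a microhabitat label are skipped.
    """
    counts: dict = {}
    for r in records:
        label = getattr(r, "microhabitat", None)
        if label is None:
            continue
        key = "other" if label in other else label
        counts[key] = counts.get(key, 0) + 1
    return counts
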