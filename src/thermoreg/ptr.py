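"""Preferred temperature range (set-point range) estimation.

The preferred temperature range (PTR) of a population is the central 50%
(interquartile range) of body temperatures selected in a laboratory
thermal gradient, free of ecological constraints.  It is the reference
interval against which both field body temperatures and operative
temperatures are judged by the thermoregulation indices.

Two estimation units are supported:

* pooled hourly measures (default) — the quantiles of every individual
  gradient reading;
* per-individual means (``by_individual=True``) — the quantiles of one
  mean temperature per lizard.

The sex-difference check that licenses pooling males and females operates
on per-individual means (one value per lizard), compares them with a
one-way ANOVA, and falls back to a Mann–Whitney rank test when the
normality or variance-homogeneity assumptions fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import PreferredTemperatureRange, TprefMeasurement

__all__ = ["estimate_ptr", "sex_pooling_check", "SexPoolingReport"]

log = logging.getLogger("thermoreg.ptr")


def _tpref_values(measurements, by_individual: bool) -> np.ndarray:
    """Extract the vector the quantiles run over."""
    ms = list(measurements)
    if ms and isinstance(ms[0], TprefMeasurement):
        if by_individual:
            sums: dict = {}
            counts: dict = {}
            for m in ms:
                sums[m.individual_id] = sums.get(m.individual_id, 0.0) + m.tpref_c
                counts[m.individual_id] = counts.get(m.individual_id, 0) + 1
            return np.array([sums[k] / counts[k] for k in sorted(sums)])
        return np.asarray([m.tpref_c for m in ms], dtype=float)
    return np.asarray(ms, dtype=float)


def estimate_ptr(
    measurements: Sequence,
    q_low: float = 0.25,
    q_high: float = 0.75,
    *,
    by_individual: bool = False,
    method: str = "linear",
) -> PreferredTemperatureRange:
    """Estimate the preferred temperature range as central quantiles.

    Parameters
    ----------
    measurements
        :class:`TprefMeasurement` records or bare temperatures (°C).
    q_low, q_high
        Quantile levels bounding the central fraction (default the
        interquartile range, 0.25–0.75).
    by_individual
        Run the quantiles over per-individual mean temperatures instead of
        pooled hourly measures.
    method
        Quantile convention passed to :func:`numpy.quantile` (default
        ``"linear"``, i.e. linear interpolation between order statistics).
    """
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("require 0 <= q_low < q_high <= 1")
    values = _tpref_values(measurements, by_individual)
    if values.size == 0:
        raise ValueError("no measurements")
    if values.size < 4:
        raise ValueError(f"need at least 4 values to estimate a range, got {values.size}")
    lower, upper = np.quantile(values, [q_low, q_high], method=method)
    if lower == upper:
        log.warning("degenerate preferred range: lower == upper == %.3f", lower)
    return PreferredTemperatureRange(
        lower_c=float(lower),
        upper_c=float(upper),
        q_low=q_low,
        q_high=q_high,
        n_values=int(values.size),
    )


@dataclass(frozen=True)
class SexPoolingReport:
    """Outcome of the males-vs-females comparison of mean selected temperatures."""

    method: str  # "anova" or "mann_whitney"
    statistic_name: str  # "F" or "U"
    statistic: float
    df: Optional[tuple]  # (1, n-2) for ANOVA, None for the rank test
    p: float
    pooled: bool
    n_by_sex: dict


def sex_pooling_check(
    measurements: Sequence[TprefMeasurement],
    alpha: float = 0.05,
    *,
    force_method: Optional[str] = None,
    assumption_alpha: float = 0.05,
) -> SexPoolingReport:
    """Test whether male and female mean selected temperatures differ.

    Per-individual mean temperatures are computed first (one value per
    lizard).  A one-way ANOVA compares the sexes when Shapiro normality
    and Levene homogeneity hold at ``assumption_alpha``; otherwise a
    Mann–Whitney U test is used.  ``pooled`` is True when ``p >= alpha``,
    licensing a single pooled preferred range for the species.
    """
    by_sex: dict = {"male": {}, "female": {}}
    for m in measurements:
        d = by_sex[m.sex].setdefault(m.individual_id, [])
        d.append(m.tpref_c)
    groups = {
        sex: np.array([float(np.mean(v)) for _, v in sorted(ind.items())])
        for sex, ind in by_sex.items()
    }
    for sex, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"need >= 2 individuals of sex {sex!r}, got {vals.size}")
    males, females = groups["male"], groups["female"]

    method = force_method
    if method is None:
        method = "anova" if _parametric_ok(males, females, assumption_alpha) else "mann_whitney"

    if np.ptp(np.concatenate([males, females])) == 0.0:
        # all means identical: no evidence of a difference, p = 1 by convention
        stat, p = (0.0, 1.0)
        name = "F" if method == "anova" else "U"
        df = (1, males.size + females.size - 2) if method == "anova" else None
        if name == "U":
            stat = males.size * females.size / 2.0
    elif method == "anova":
        stat, p = stats.f_oneway(males, females)
        name, df = "F", (1, males.size + females.size - 2)
    elif method == "mann_whitney":
        res = stats.mannwhitneyu(males, females, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        name, df = "U", None
    else:
        raise ValueError(f"unknown method {method!r}")

    report = SexPoolingReport(
        method=method,
        statistic_name=name,
        statistic=float(stat),
        df=df,
        p=float(p),
        pooled=bool(p >= alpha),
        n_by_sex={"male": int(males.size), "female": int(females.size)},
    )
    log.info(
        "sex pooling check: %s %s=%.3f p=%.4f -> %s",
        method, name, report.statistic, report.p,
        "pool" if report.pooled else "keep separate",
    )
    return report


def _parametric_ok(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """Shapiro normality per group plus Levene homogeneity, all at alpha."""
    for g in (a, b):
        if np.ptp(g) == 0.0:
            return False  # constant group: Shapiro undefined, variance zero
        if g.size >= 3 and stats.shapiro(g).pvalue < alpha:
            return False
    if stats.levene(a, b, center="mean").pvalue < alpha:
        return False
    return True
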