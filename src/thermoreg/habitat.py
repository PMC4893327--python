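"""Habitat thermal profiling from operative temperatures.

Answers two questions about the mosaic of microhabitats a site offers:

* how suitable is each microhabitat for a species — the share of operative
  temperatures falling below, within and above its preferred temperature
  range (suitability profiles);
* which microhabitats are thermally distinct, and how do they group
  relative to the preferred ranges of a cold specialist and a thermal
  generalist — Kruskal–Wallis with Nemenyi letters, and a four-way
  cold / mild / warm / very-warm classification driven by hourly-block
  statistics of the diel T_e curve.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import to_frame
from .posthoc import MultiGroupReport, rank_compare
from .records import OperativeTempRecord, PreferredTemperatureRange, SuitabilityProfile

__all__ = [
    "suitability_profile",
    "profiles_to_frame",
    "compare_microhabitat_te",
    "classify_thermal_groups",
    "filter_window",
    "ACTIVITY_WINDOW",
]

log = logging.getLogger("thermoreg.habitat")

#: daily activity period of the lizards (hours, GMT): records from 08:00
#: up to but not including 18:00 count as daytime
ACTIVITY_WINDOW = (8, 18)


def _as_frame(te: Union[Sequence[OperativeTempRecord], pd.DataFrame]) -> pd.DataFrame:
    if isinstance(te, pd.DataFrame):
        return te
    return to_frame(list(te))


def filter_window(te: Sequence[OperativeTempRecord],
                  window: tuple = ACTIVITY_WINDOW) -> list:
    """Keep records whose timestamp hour lies in [start, end)."""
    start, end = window
    return [r for r in te if start <= r.timestamp.hour < end]


def _profile(group, temps: np.ndarray, ptr: PreferredTemperatureRange) -> SuitabilityProfile:
    n = temps.size
    below = int(np.sum(temps < ptr.lower_c))
    above = int(np.sum(temps > ptr.upper_c))
    within = n - below - above  # bounds inclusive: on-bound values are within
    return SuitabilityProfile(
        group=group,
        pct_below=100.0 * below / n,
        pct_within=100.0 * within / n,
        pct_above=100.0 * above / n,
        n=n,
        n_below=below,
        n_within=within,
        n_above=above,
    )


def suitability_profile(
    te: Union[Sequence[OperativeTempRecord], pd.DataFrame],
    ptr: PreferredTemperatureRange,
    group_by: Union[str, Sequence[str], None] = "microhabitat",
) -> list:
    """Per-group and total shares of T_e below / within / above the PTR.

    ``group_by`` names one or more categorical record fields; ``None``
    produces only the overall ("total") profile.  Percentages are stored
    unrounded; round to 1 decimal for display via :func:`profiles_to_frame`.
    """
    frame = _as_frame(te)
    if frame.empty:
        raise ValueError("no operative temperature records")
    temps = frame["te_c"].to_numpy(dtype=float)

    profiles = []
    if group_by is not None:
        keys = [group_by] if isinstance(group_by, str) else list(group_by)
        for key in keys:
            if key not in frame.columns:
                raise KeyError(f"unknown group field {key!r}")
        for name, sub in frame.groupby(keys if len(keys) > 1 else keys[0], sort=True):
            profiles.append(_profile(name, sub["te_c"].to_numpy(dtype=float), ptr))
    profiles.append(_profile("total", temps, ptr))
    return profiles


def profiles_to_frame(profiles: Sequence[SuitabilityProfile], decimals: int = 1) -> pd.DataFrame:
    """Tabulate profiles with display rounding of the percentage columns."""
    rows = [
        {
            "group": "/".join(p.group) if isinstance(p.group, tuple) else p.group,
            "pct_below": round(p.pct_below, decimals),
            "pct_within": round(p.pct_within, decimals),
            "pct_above": round(p.pct_above, decimals),
            "n": p.n,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["group", "pct_below", "pct_within", "pct_above", "n"])


def te_category(record: OperativeTempRecord,
                fields: Sequence[str] = ("microhabitat", "sun", "orientation")) -> str:
    """Joined category label, skipping unset parts (e.g. orientation)."""
    parts = [getattr(record, f) for f in fields]
    return "/".join(str(p) for p in parts if p is not None)


def compare_microhabitat_te(
    te: Sequence[OperativeTempRecord],
    category_fields: Sequence[str] = ("microhabitat", "sun", "orientation"),
    *,
    alpha: float = 0.05,
    nemenyi: str = "chi2",
) -> MultiGroupReport:
    """Kruskal–Wallis + Nemenyi letters on T_e across microhabitat categories.

    Categories are the cross of ``category_fields`` combinations actually
    present in the data (not a hard-coded list); categories with fewer than
    2 records are excluded with a warning.
    """
    groups: dict = {}
    for r in te:
        groups.setdefault(te_category(r, category_fields), []).append(r.te_c)
    return rank_compare(groups, alpha=alpha, nemenyi=nemenyi)


THERMAL_GROUPS = ("cold", "mild", "warm", "very_warm")


def classify_thermal_groups(
    te: Sequence[OperativeTempRecord],
    ptr_specialist: PreferredTemperatureRange,
    ptr_generalist: PreferredTemperatureRange,
    *,
    window: tuple = ACTIVITY_WINDOW,
    block_stat: str = "median",
    category_fields: Sequence[str] = ("microhabitat", "sun", "orientation"),
) -> dict:
    """Four-way thermal classification of microhabitat categories.

    For each category the daytime records are split into hourly blocks and
    a per-block statistic (median by default) of T_e is taken.  Rules, in
    precedence order:

    ``very_warm``  every block exceeds both preferred ranges;
    ``mild``       some block falls within the specialist (colder,
                   narrower) range — such microhabitats offer set-point
                   conditions to the cold-adapted species at some hours,
                   and typically to the generalist at warmer hours;
    ``warm``       some block exceeds the specialist range while lying
                   within the generalist range (never reaching the
                   specialist's set-points);
    ``cold``       every block is below both ranges.

    A category matching none of the rules is resolved by where its overall
    daytime statistic falls (below specialist → cold, above generalist →
    very_warm, within generalist → warm, else mild).  Categories with no
    daytime records are mapped to ``"unclassified"`` with a warning.
    """
    statfun = {"median": np.median, "mean": np.mean}[block_stat]
    by_cat: dict = {}
    for r in te:
        by_cat.setdefault(te_category(r, category_fields), []).append(r)

    out = {}
    for cat, records in sorted(by_cat.items()):
        day = [r for r in records if window[0] <= r.timestamp.hour < window[1]]
        if not day:
            warnings.warn(f"microhabitat category {cat!r} has no daytime records",
                          stacklevel=2)
            out[cat] = "unclassified"
            continue
        blocks: dict = {}
        for r in day:
            blocks.setdefault(r.timestamp.hour, []).append(r.te_c)
        stats_ = np.array([statfun(v) for _, v in sorted(blocks.items())])

        in_spec = (stats_ >= ptr_specialist.lower_c) & (stats_ <= ptr_specialist.upper_c)
        in_gen = (stats_ >= ptr_generalist.lower_c) & (stats_ <= ptr_generalist.upper_c)
        above_spec = stats_ > ptr_specialist.upper_c
        above_both = above_spec & (stats_ > ptr_generalist.upper_c)
        below_both = (stats_ < ptr_specialist.lower_c) & (stats_ < ptr_generalist.lower_c)

        if above_both.all():
            out[cat] = "very_warm"
        elif in_spec.any():
            out[cat] = "mild"
        elif (above_spec & in_gen).any():
            out[cat] = "warm"
        elif below_both.all():
            out[cat] = "cold"
        else:
            overall = float(statfun(np.concatenate([np.asarray(v) for v in blocks.values()])))
            if overall < ptr_specialist.lower_c:
                out[cat] = "cold"
            elif overall > ptr_generalist.upper_c:
                out[cat] = "very_warm"
            elif ptr_generalist.contains(overall):
                out[cat] = "warm"
            else:
                out[cat] = "mild"
        log.debug("thermal group %s -> %s", cat, out[cat])
    return out
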