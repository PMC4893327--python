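"""Hertz–Huey–Stevenson thermoregulation indices with a bootstrap engine.

Three indices summarise how well an ectotherm population thermoregulates
relative to its preferred temperature range (PTR):

* accuracy of thermoregulation ``d̄_b`` — mean absolute deviation of field
  body temperatures (T_b) from the PTR; the scale is counterintuitive:
  higher values mean *lower* accuracy;
* thermal quality of habitat ``d̄_e`` — the same statistic applied to
  operative temperatures (T_e) from physical models placed in the habitat;
  higher values mean a thermally *worse* habitat;
* effectiveness of thermoregulation ``E = 1 − d̄_b / d̄_e`` — near 1 for
  effective thermoregulators, near 0 for thermoconformers.  Negative
  values are possible (active avoidance of the preferred range) and are
  not an error.  E is undefined when ``d̄_e = 0`` (a thermally ideal
  habitat).

Uncertainty is quantified by a nonparametric bootstrap: each iteration
resamples the T_b and the T_e samples independently, with replacement, at
their original sizes, and recomputes the three indices, building
pseudo-distributions from which means, standard deviations and confidence
intervals are read.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import BootSummary, PreferredTemperatureRange, ThermoregIndices

__all__ = [
    "deviation_from_range",
    "mean_deviation_index",
    "effectiveness",
    "bootstrap_indices",
    "ThermallyIdealHabitatError",
]

log = logging.getLogger("thermoreg.indices")


class ThermallyIdealHabitatError(ZeroDivisionError):
    """E is undefined: every operative temperature lies inside the PTR."""


def deviation_from_range(t, ptr: PreferredTemperatureRange):
    """Absolute deviation of a temperature from the preferred range, in °C.

    Zero inside the range (bounds inclusive), distance to the nearer bound
    outside.  Accepts a scalar or an array; returns the matching shape.
    """
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("temperatures must be finite")
    dev = np.maximum(ptr.lower_c - arr, 0.0) + np.maximum(arr - ptr.upper_c, 0.0)
    return float(dev) if np.isscalar(t) or arr.ndim == 0 else dev


def mean_deviation_index(temps: Sequence[float], ptr: PreferredTemperatureRange) -> float:
    """Mean absolute deviation from the PTR: d̄_b for T_b, d̄_e for T_e."""
    arr = np.asarray(list(temps) if not isinstance(temps, np.ndarray) else temps,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("empty temperature collection")
    return float(np.mean(deviation_from_range(arr, ptr)))


def effectiveness(db: float, de: float) -> float:
    """Effectiveness of thermoregulation, E = 1 − d̄_b / d̄_e.

    E = 1 iff d̄_b = 0 (perfect accuracy); E may be negative when body
    temperatures deviate more than the habitat itself does.  Raises
    :class:`ThermallyIdealHabitatError` when ``de == 0``.
    """
    if db < 0 or de < 0:
        raise ValueError("deviation indices must be >= 0")
    if de == 0:
        raise ThermallyIdealHabitatError(
            "undefined E: thermally ideal habitat (d̄_e = 0)"
        )
    return 1.0 - db / de


def _bootstrap_means(dev: np.ndarray, n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Means of ``n_iter`` with-replacement resamples of ``dev`` (own size).

    Chunked so the index matrix never exceeds a few tens of MB; the random
    stream, hence the result, is independent of the chunking.
    """
    n = dev.size
    out = np.empty(n_iter)
    chunk = max(1, min(n_iter, 4_000_000 // max(n, 1)))
    start = 0
    while start < n_iter:
        stop = min(start + chunk, n_iter)
        idx = rng.integers(0, n, size=(stop - start, n))
        out[start:stop] = dev[idx].mean(axis=1)
        start = stop
    return out


def _summary(pseudo: np.ndarray, ci_level: float, ci_method: str) -> BootSummary:
    mean = float(np.mean(pseudo))
    sd = float(np.std(pseudo, ddof=1)) if pseudo.size > 1 else 0.0
    if ci_method == "percentile":
        tail = 100.0 * (1.0 - ci_level) / 2.0
        lo, hi = np.percentile(pseudo, [tail, 100.0 - tail])
    elif ci_method == "normal":
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        lo, hi = mean - z * sd, mean + z * sd
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    # a degenerate pseudo-distribution can put the mean on a CI bound
    lo, hi = min(float(lo), mean), max(float(hi), mean)
    return BootSummary(boot_mean=mean, boot_sd=sd, ci_low=lo, ci_high=hi)


def bootstrap_indices(
    tb: Sequence[float],
    te: Sequence[float],
    ptr: PreferredTemperatureRange,
    n_iter: int = 100,
    seed: Optional[int] = None,
    ci_level: float = 0.95,
    *,
    ci_method: str = "percentile",
    return_pseudo: bool = False,
):
    """Point estimates and bootstrap summaries of d̄_b, d̄_e and E.

    Each iteration draws independent with-replacement resamples of ``tb``
    (size ``len(tb)``) and ``te`` (size ``len(te)``), with the PTR held
    fixed, and recomputes the three indices.  Iterations whose resampled
    d̄_e is zero leave E undefined; they are excluded from the E
    pseudo-distribution and counted in ``n_excluded_e``.

    Fully reproducible: the same ``seed`` yields bit-identical results.
    With ``return_pseudo=True`` returns ``(indices, pseudo)`` where
    ``pseudo`` is a dict of the three pseudo-distributions (E with NaN at
    excluded iterations), mirroring the full bootstrap output table.
    """
    tb = np.asarray(list(tb) if not isinstance(tb, np.ndarray) else tb, dtype=float)
    te = np.asarray(list(te) if not isinstance(te, np.ndarray) else te, dtype=float)
    if tb.size == 0 or te.size == 0:
        raise ValueError("tb and te must be non-empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    dev_b = deviation_from_range(tb, ptr)
    dev_e = deviation_from_range(te, ptr)
    db = float(np.mean(dev_b))
    de = float(np.mean(dev_e))
    e_point = 1.0 - db / de if de > 0 else math.nan

    rng = np.random.default_rng(seed)
    db_pseudo = _bootstrap_means(dev_b, n_iter, rng)
    de_pseudo = _bootstrap_means(dev_e, n_iter, rng)
    defined = de_pseudo > 0
    e_pseudo = np.full(n_iter, np.nan)
    e_pseudo[defined] = 1.0 - db_pseudo[defined] / de_pseudo[defined]
    n_excluded = int(n_iter - defined.sum())
    if n_excluded:
        log.warning(
            "E undefined in %d of %d bootstrap iterations (resampled d̄_e = 0)",
            n_excluded, n_iter,
        )

    e_boot = _summary(e_pseudo[defined], ci_level, ci_method) if defined.any() else None
    result = ThermoregIndices(
        db=db,
        de=de,
        e=e_point,
        db_boot=_summary(db_pseudo, ci_level, ci_method),
        de_boot=_summary(de_pseudo, ci_level, ci_method),
        e_boot=e_boot,
        n_boot=n_iter,
        seed=seed,
        n_excluded_e=n_excluded,
    )
    if return_pseudo:
        return result, {"db": db_pseudo, "de": de_pseudo, "e": e_pseudo}
    return result
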