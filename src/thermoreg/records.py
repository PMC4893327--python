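"""Domain record types shared by every analysis stage.

Four kinds of field/lab observations flow through the package:

* :class:`TprefMeasurement` — hourly preferred (selected) body temperatures
  of individual lizards in a laboratory thermal gradient.
* :class:`BodyTempRecord` — cloacal body temperatures taken in the field
  immediately after capture, with the capture microhabitat context.
* :class:`OperativeTempRecord` — operative temperatures (T_e) logged by
  hollow copper lizard models placed in different microhabitats; T_e is the
  equilibrium temperature a non-thermoregulating lizard would reach there.
* :class:`AvailabilityPoint` — habitat-availability sampling points placed
  1 m from a capture in each cardinal direction.

plus :class:`MicrohabitatCount` rows for use-versus-availability frequency
tables, and the derived quantities :class:`PreferredTemperatureRange`,
:class:`ThermoregIndices` and :class:`SuitabilityProfile`.

All temperatures are degrees Celsius, lengths are centimetres unless the
field name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime
from datetime import time as TimeOfDay
from typing import Mapping, Optional

__all__ = [
    "CategoryTable",
    "DEFAULT_CATEGORIES",
    "TprefMeasurement",
    "PreferredTemperatureRange",
    "BodyTempRecord",
    "OperativeTempRecord",
    "AvailabilityPoint",
    "MicrohabitatCount",
    "BootSummary",
    "ThermoregIndices",
    "SuitabilityProfile",
]

SEXES = frozenset({"male", "female"})
DIRECTIONS = frozenset({"N", "S", "E", "W"})


@dataclass(frozen=True)
class CategoryTable:
    """Configurable controlled vocabulary for categorical record fields.

    Readers validate labels against one of these; there is no silent
    coercion of unknown categories.
    """

    microhabitats: frozenset = frozenset(
        {"rock", "soil", "leaf_litter", "log", "grass", "under_rock"}
    )
    orientations: frozenset = frozenset({"N", "S", "E", "W", "flat"})
    sun: frozenset = frozenset({"full_sun", "filtered_sun", "shade"})

    def check_microhabitat(self, label: str) -> None:
        if label not in self.microhabitats:
            raise ValueError(f"unknown microhabitat label {label!r}")

    def check_operative(self, microhabitat: str, orientation, sun: str) -> None:
        self.check_microhabitat(microhabitat)
        if orientation is not None and orientation not in self.orientations:
            raise ValueError(f"unknown orientation label {orientation!r}")
        if sun not in self.sun:
            raise ValueError(f"unknown sun-exposure label {sun!r}")


DEFAULT_CATEGORIES = CategoryTable()


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def _require_nonneg(name: str, value: Optional[float]) -> None:
    if value is not None and value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class TprefMeasurement:
    """One hourly selected temperature of one lizard in the thermal gradient."""

    individual_id: str
    species: str
    sex: str
    hour: int  # hour of day, GMT; trials run 08-18 h
    tpref_c: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if not 0 <= self.hour <= 23:
            raise ValueError(f"hour must be in 0..23, got {self.hour}")
        _require_finite("tpref_c", self.tpref_c)


@dataclass(frozen=True)
class PreferredTemperatureRange:
    """The set-point (preferred temperature) range of a population.

    By convention this is the central 50% of gradient-selected body
    temperatures, i.e. the interquartile range, but the quantile levels are
    carried along so other central fractions can be used.
    """

    lower_c: float
    upper_c: float
    q_low: float = 0.25
    q_high: float = 0.75
    n_values: int = 0

    def __post_init__(self) -> None:
        _require_finite("lower_c", self.lower_c)
        _require_finite("upper_c", self.upper_c)
        if self.lower_c > self.upper_c:
            raise ValueError("lower_c must be <= upper_c")
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValueError("require 0 <= q_low < q_high <= 1")

    @property
    def width(self) -> float:
        return self.upper_c - self.lower_c

    def contains(self, t: float) -> bool:
        """Boundary-inclusive membership: a value on a bound is within."""
        return self.lower_c <= t <= self.upper_c


@dataclass(frozen=True)
class BodyTempRecord:
    """A field body temperature with its capture context."""

    species: str
    tb_c: float
    time: Optional[TimeOfDay] = None
    date: Optional[Date] = None
    microhabitat: Optional[str] = None
    ta_c: Optional[float] = None  # air temperature at the capture point
    ts_c: Optional[float] = None  # substrate temperature at the capture point
    height_cm: Optional[float] = None
    refuge_cm: Optional[float] = None  # distance to nearest potential refuge
    svl_mm: Optional[float] = None  # stored for completeness, not analysed
    mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite("tb_c", self.tb_c)
        _require_nonneg("height_cm", self.height_cm)
        _require_nonneg("refuge_cm", self.refuge_cm)


@dataclass(frozen=True)
class OperativeTempRecord:
    """One copper-model operative temperature reading."""

    te_c: float
    timestamp: datetime
    microhabitat: str
    sun: str
    orientation: Optional[str] = None
    model_id: str = ""

    def __post_init__(self) -> None:
        _require_finite("te_c", self.te_c)


@dataclass(frozen=True)
class AvailabilityPoint:
    """One habitat-availability point (1 m from a capture, cardinal direction)."""

    capture_ref: str
    direction: str
    microhabitat: Optional[str] = None
    ta_c: Optional[float] = None
    ts_c: Optional[float] = None
    height_cm: Optional[float] = None
    refuge_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
        _require_nonneg("height_cm", self.height_cm)
        _require_nonneg("refuge_cm", self.refuge_cm)


@dataclass(frozen=True)
class MicrohabitatCount:
    """One cell of a use/availability frequency table."""

    group: str  # a species label, or "availability"
    microhabitat: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class BootSummary:
    """Summary of one bootstrap pseudo-distribution."""

    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ThermoregIndices:
    """Point estimates and bootstrap summaries of the three indices.

    ``db`` is the accuracy of thermoregulation (mean absolute deviation of
    field body temperatures from the preferred range; lower = more accurate),
    ``de`` the thermal quality of habitat (same statistic on operative
    temperatures; lower = thermally better habitat) and ``e = 1 - db/de``
    the effectiveness of thermoregulation.  ``e`` and ``e_boot`` may be NaN /
    ``None`` when the habitat is thermally ideal (``de == 0``), in which case
    ``n_excluded_e`` counts the undefined bootstrap iterations.
    """

    db: float
    de: float
    e: float
    db_boot: BootSummary
    de_boot: BootSummary
    e_boot: Optional[BootSummary]
    n_boot: int
    seed: Optional[int]
    n_excluded_e: int = 0

    def __post_init__(self) -> None:
        if self.db < 0 or self.de < 0:
            raise ValueError("deviation indices must be >= 0")
        if self.de > 0 and not math.isclose(self.e, 1.0 - self.db / self.de):
            raise ValueError("e must equal 1 - db/de when de > 0")


@dataclass(frozen=True)
class SuitabilityProfile:
    """Share of operative temperatures below / within / above a PTR.

    Percentages are stored unrounded; display rounding (1 decimal) happens
    when profiles are tabulated.  ``group`` is a microhabitat label (or a
    tuple of category labels) or ``"total"``.
    """

    group: object
    pct_below: float
    pct_within: float
    pct_above: float
    n: int
    n_below: int = 0
    n_within: int = 0
    n_above: int = 0

    def __post_init__(self) -> None:
        for name in ("pct_below", "pct_within", "pct_above"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n > 0 and abs(self.pct_below + self.pct_within + self.pct_above - 100.0) > 0.2:
            raise ValueError("percentages must sum to 100 within tolerance")
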