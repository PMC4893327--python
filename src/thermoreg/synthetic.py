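"""Synthetic field-study generator.

Emulates the statistical structure of a two-species lizard
thermoregulation study so the whole pipeline runs, and can be validated,
without any external data:

* diel operative-temperature curves per microhabitat category, logged at
  a 5-minute cadence with Gaussian sensor/weather noise;
* species-specific Normal distributions of gradient-selected temperatures
  (balanced across sexes, several hourly measures per individual);
* field body temperatures produced by a tunable thermoregulator: a lizard
  picks a microhabitat by preference weights, meets an operative
  temperature there, and pulls its body temperature a fraction
  ``regulation_k`` of the way toward the preferred range
  (``k = 0`` perfect thermoconformer, ``k = 1`` perfect regulator) —
  a deliberately minimal behavioural model that makes the effectiveness
  index identifiable, not a biophysical claim;
* availability points and use/availability frequency tables.

Every generator is a pure function of its parameters and the seed.
Temperatures that a field instrument would record (T_e, T_pref) are
rounded to 0.1 °C to match thermometer precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import (
    AvailabilityPoint,
    BodyTempRecord,
    MicrohabitatCount,
    OperativeTempRecord,
    PreferredTemperatureRange,
    TprefMeasurement,
)

__all__ = [
    "MicrohabitatSpec",
    "SpeciesSpec",
    "generate_operative",
    "generate_tpref",
    "generate_body_temps",
    "generate_availability",
    "default_landscape",
    "default_species",
    "generate_study",
    "StudyData",
    "diel_curve",
]

START_DATE = Date(2012, 8, 1)
ACTIVITY_WINDOW = (8, 18)


@dataclass(frozen=True)
class MicrohabitatSpec:
    """Diel T_e model for one microhabitat × sun × orientation category.

    The noiseless curve is ``T_e(t) = diel_mean_c + diel_amplitude_c *
    (cos(2π (t − 12 − phase_h) / 24) − 1)``: it attains ``diel_mean_c`` at
    solar noon shifted by ``phase_h`` hours and falls off sinusoidally by
    up to ``2 * diel_amplitude_c`` overnight.  Gaussian noise with sd
    ``noise_sd_c`` is added to every reading.
    """

    label: str
    sun: str
    diel_mean_c: float
    diel_amplitude_c: float
    orientation: Optional[str] = None
    phase_h: float = 0.0
    noise_sd_c: float = 0.0
    sampling_interval_min: int = 5

    def __post_init__(self) -> None:
        if self.diel_amplitude_c < 0:
            raise ValueError("diel_amplitude_c must be >= 0")
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be > 0")

    @property
    def model_id(self) -> str:
        parts = [self.label, self.sun] + ([self.orientation] if self.orientation else [])
        return "-".join(parts)


@dataclass(frozen=True)
class SpeciesSpec:
    """Population parameters of one synthetic species."""

    label: str
    tpref_mean_c: float
    tpref_sd_c: float
    regulation_k: float  # 0 = thermoconformer, 1 = perfect regulator
    n_individuals: int = 24
    n_captures: int = 75
    microhabitat_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tpref_sd_c < 0:
            raise ValueError("tpref_sd_c must be >= 0")
        if not 0.0 <= self.regulation_k <= 1.0:
            raise ValueError("regulation_k must be in [0, 1]")
        if self.microhabitat_weights:
            total = sum(self.microhabitat_weights.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6):
                raise ValueError(f"microhabitat_weights must sum to 1, got {total}")


def diel_curve(spec: MicrohabitatSpec, hour: float) -> float:
    """Noiseless operative temperature at a (fractional) hour of day."""
    return spec.diel_mean_c + spec.diel_amplitude_c * (
        math.cos(2.0 * math.pi * (hour - 12.0 - spec.phase_h) / 24.0) - 1.0
    )


def _round_temp(x) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float), 1)


def generate_operative(
    specs: Sequence[MicrohabitatSpec],
    days: int = 1,
    seed: Optional[int] = None,
    *,
    window: tuple = ACTIVITY_WINDOW,
    full_day: bool = False,
    start_date: Date = START_DATE,
) -> list:
    """Copper-model style T_e streams for every microhabitat spec.

    Records are produced at each spec's cadence over the activity window
    (or the full 24 h with ``full_day=True``) for ``days`` consecutive
    days, rounded to 0.1 °C.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = (0, 24) if full_day else window
    out = []
    for spec in specs:
        step = spec.sampling_interval_min
        minutes = np.arange(lo * 60, hi * 60, step)
        for day in range(days):
            date = start_date + timedelta(days=day)
            base = np.array([diel_curve(spec, m / 60.0) for m in minutes])
            noise = rng.normal(0.0, spec.noise_sd_c, size=base.size) if spec.noise_sd_c else 0.0
            temps = _round_temp(base + noise)
            for m, t in zip(minutes, temps):
                ts = datetime.combine(date, datetime.min.time()) + timedelta(minutes=int(m))
                out.append(
                    OperativeTempRecord(
                        te_c=float(t),
                        timestamp=ts,
                        microhabitat=spec.label,
                        sun=spec.sun,
                        orientation=spec.orientation,
                        model_id=spec.model_id,
                    )
                )
    return out


def generate_tpref(
    spec: SpeciesSpec,
    hours_per_individual: int = 6,
    seed: Optional[int] = None,
) -> list:
    """Gradient-trial selected temperatures, balanced across sexes.

    Each individual contributes ``hours_per_individual`` measures at
    distinct hours of the trial window, drawn iid from
    Normal(tpref_mean_c, tpref_sd_c) and rounded to 0.1 °C.
    """
    if spec.n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    hours_avail = np.arange(ACTIVITY_WINDOW[0], ACTIVITY_WINDOW[1])
    if hours_per_individual > hours_avail.size:
        raise ValueError("hours_per_individual exceeds the trial window")
    out = []
    for i in range(spec.n_individuals):
        sex = "male" if i % 2 == 0 else "female"
        ind = f"{spec.label}-{i + 1:02d}"
        hours = np.sort(rng.choice(hours_avail, size=hours_per_individual, replace=False))
        temps = _round_temp(rng.normal(spec.tpref_mean_c, spec.tpref_sd_c,
                                       size=hours_per_individual))
        for h, t in zip(hours, temps):
            out.append(
                TprefMeasurement(
                    individual_id=ind, species=spec.label, sex=sex,
                    hour=int(h), tpref_c=float(t),
                )
            )
    return out


def generate_body_temps(
    species: SpeciesSpec,
    te_pool: Sequence[OperativeTempRecord],
    ptr: PreferredTemperatureRange,
    n_captures: Optional[int] = None,
    seed: Optional[int] = None,
) -> list:
    """Field body temperatures from the tunable thermoregulator model.

    For each capture a microhabitat is chosen by ``microhabitat_weights``
    and an operative temperature drawn from that microhabitat's records;
    with empty weights the draw is uniform over the whole pool (random use
    of the habitat — the thermoconformer null).  The body temperature is
    ``T_b = T_e + k · (clamp(T_e, PTR) − T_e)`` with ``k`` the species'
    ``regulation_k``.  The T_e record's time and microhabitat label are
    attached; air and substrate temperatures echo the operative reading.
    """
    pool = list(te_pool)
    if not pool:
        raise ValueError("te_pool is empty")
    n = species.n_captures if n_captures is None else n_captures
    rng = np.random.default_rng(seed)

    by_label: dict = {}
    for r in pool:
        by_label.setdefault(r.microhabitat, []).append(r)
    weighted = bool(species.microhabitat_weights)
    if weighted:
        missing = set(species.microhabitat_weights) - set(by_label)
        if missing:
            raise ValueError(f"weights name microhabitats absent from te_pool: {missing}")
        labels = sorted(species.microhabitat_weights)
        probs = np.array([species.microhabitat_weights[l] for l in labels])

    k = species.regulation_k
    out = []
    for _ in range(n):
        if weighted:
            label = labels[rng.choice(len(labels), p=probs)]
            rec = by_label[label][rng.integers(0, len(by_label[label]))]
        else:
            rec = pool[rng.integers(0, len(pool))]
        label = rec.microhabitat
        te = rec.te_c
        target = min(max(te, ptr.lower_c), ptr.upper_c)
        tb = te + k * (target - te)
        out.append(
            BodyTempRecord(
                species=species.label,
                tb_c=float(tb),
                time=rec.timestamp.time(),
                date=rec.timestamp.date(),
                microhabitat=label,
                ta_c=float(te),
                ts_c=float(te),
                height_cm=float(np.round(abs(rng.normal(10.0, 15.0)), 1)),
                refuge_cm=float(np.round(abs(rng.normal(15.0, 12.0)), 1)),
            )
        )
    return out


def generate_availability(
    n_captures: int,
    te_pool: Sequence[OperativeTempRecord],
    seed: Optional[int] = None,
    *,
    weights: Optional[Mapping[str, float]] = None,
) -> list:
    """Availability points: 4 cardinal points per sampled capture place.

    Microhabitats are drawn by ``weights`` (uniform over the pool's labels
    by default); temperatures echo a random operative reading of the
    chosen microhabitat; heights and refuge distances are folded-normal
    with a longer tail than at capture points (the habitat at large is
    less sheltered than where lizards sit).
    """
    pool = list(te_pool)
    if not pool:
        raise ValueError("te_pool is empty")
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for r in pool:
        by_label.setdefault(r.microhabitat, []).append(r)
    if weights:
        labels = sorted(weights)
        probs = np.array([weights[l] for l in labels])
        probs = probs / probs.sum()
    else:
        labels = sorted(by_label)
        probs = np.full(len(labels), 1.0 / len(labels))

    out = []
    for c in range(n_captures):
        for direction in ("N", "S", "E", "W"):
            label = labels[rng.choice(len(labels), p=probs)]
            rec = by_label[label][rng.integers(0, len(by_label[label]))]
            out.append(
                AvailabilityPoint(
                    capture_ref=f"cap-{c + 1:03d}",
                    direction=direction,
                    microhabitat=label,
                    ta_c=float(_round_temp(rec.te_c)),
                    ts_c=float(_round_temp(rec.te_c + rng.normal(0.0, 1.0))),
                    height_cm=float(np.round(abs(rng.normal(10.0, 22.0)), 1)),
                    refuge_cm=float(np.round(abs(rng.normal(40.0, 31.0)), 1)),
                )
            )
    return out


# --------------------------------------------------------------------------
# default study-shaped scenario

def default_landscape() -> list:
    """Sixteen microhabitat × sun × orientation categories spanning the
    cold → very-warm spectrum of a rocky montane site at midsummer."""
    mk = MicrohabitatSpec
    return [
        # cold: shaded or poorly exposed surfaces
        mk("rock", "full_sun", 25.0, 3.0, orientation="S", noise_sd_c=1.5),
        mk("rock", "shade", 22.0, 2.5, orientation="flat", noise_sd_c=1.0),
        mk("soil", "shade", 23.0, 2.5, noise_sd_c=1.0),
        mk("leaf_litter", "shade", 23.5, 2.5, noise_sd_c=1.0),
        # mild: within reach of one or both preferred ranges at some hours
        mk("under_rock", "shade", 28.5, 1.5, noise_sd_c=0.8),
        mk("rock", "full_sun", 29.5, 3.5, orientation="N", noise_sd_c=1.5),
        mk("rock", "full_sun", 31.0, 4.0, orientation="E", phase_h=-2.0, noise_sd_c=1.5),
        mk("rock", "filtered_sun", 29.5, 3.5, orientation="flat", noise_sd_c=1.5),
        mk("soil", "filtered_sun", 30.5, 4.0, noise_sd_c=1.5),
        mk("leaf_litter", "filtered_sun", 30.5, 4.0, noise_sd_c=1.5),
        # warm: beyond the specialist range, within the generalist one
        mk("rock", "full_sun", 35.0, 5.0, orientation="flat", noise_sd_c=2.0),
        mk("rock", "full_sun", 34.0, 5.0, orientation="W", phase_h=2.0, noise_sd_c=2.0),
        mk("log", "full_sun", 36.0, 5.0, noise_sd_c=2.0),
        # very warm: beyond both ranges all day
        mk("grass", "full_sun", 46.0, 6.0, noise_sd_c=2.5),
        mk("leaf_litter", "full_sun", 44.0, 6.0, noise_sd_c=2.5),
        mk("soil", "full_sun", 43.0, 6.0, noise_sd_c=2.5),
    ]


def default_species() -> list:
    """Two species mirroring the study's scale: a cold-adapted specialist
    with a low, narrow selected-temperature distribution and a rock-biased
    microhabitat preference, and a thermal generalist with a higher,
    broader distribution preferring soil and leaf litter."""
    return [
        SpeciesSpec(
            label="specialist",
            tpref_mean_c=28.8,
            tpref_sd_c=0.47,
            regulation_k=0.9,
            n_individuals=24,
            n_captures=79,
            microhabitat_weights={
                "rock": 0.55, "under_rock": 0.15, "soil": 0.10,
                "leaf_litter": 0.10, "grass": 0.05, "log": 0.05,
            },
        ),
        SpeciesSpec(
            label="generalist",
            tpref_mean_c=32.3,
            tpref_sd_c=2.11,
            regulation_k=0.9,
            n_individuals=24,
            n_captures=72,
            microhabitat_weights={
                "rock": 0.20, "under_rock": 0.05, "soil": 0.35,
                "leaf_litter": 0.25, "grass": 0.10, "log": 0.05,
            },
        ),
    ]


@dataclass
class StudyData:
    """One synthetic study: every dataset kind the pipeline consumes."""

    tpref: dict  # species label -> [TprefMeasurement]
    body: dict  # species label -> [BodyTempRecord]
    operative: list
    availability: list
    counts: list  # [MicrohabitatCount] for used (per species) and availability
    ptr: dict  # species label -> PreferredTemperatureRange used by the generator


def generate_study(
    seed: int = 0,
    *,
    landscape: Optional[Sequence[MicrohabitatSpec]] = None,
    species: Optional[Sequence[SpeciesSpec]] = None,
    days: int = 2,
    hours_per_individual: int = 6,
    n_availability_captures: int = 30,
) -> StudyData:
    """Generate a complete synthetic study (pure function of arguments + seed)."""
    from .ptr import estimate_ptr  # local import to avoid a cycle
    from .selection import microhabitat_counts

    landscape = list(landscape) if landscape is not None else default_landscape()
    species = list(species) if species is not None else default_species()
    streams = np.random.SeedSequence(seed).spawn(2 + 3 * len(species))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in streams]

    operative = generate_operative(landscape, days=days, seed=seeds[0])
    tpref: dict = {}
    body: dict = {}
    ptrs: dict = {}
    for i, sp in enumerate(species):
        tpref[sp.label] = generate_tpref(sp, hours_per_individual, seed=seeds[2 + 3 * i])
        ptrs[sp.label] = estimate_ptr(tpref[sp.label])
        body[sp.label] = generate_body_temps(
            sp, operative, ptrs[sp.label], seed=seeds[3 + 3 * i]
        )
    availability = generate_availability(n_availability_captures, operative, seed=seeds[1])

    counts = [
        MicrohabitatCount(group=g, microhabitat=m, count=c)
        for g, records in (
            [(sp.label, body[sp.label]) for sp in species]
            + [("availability", availability)]
        )
        for m, c in sorted(microhabitat_counts(records).items())
    ]
    return StudyData(
        tpref=tpref, body=body, operative=operative,
        availability=availability, counts=counts, ptr=ptrs,
    )
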