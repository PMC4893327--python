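"""Published summary values for the La Baña two-species lizard study.

These constants are the printed field-study results for the cold-adapted
mountain specialist *Iberolacerta galani* and the widespread thermal
generalist *Podarcis bocagei* living in syntopy at 1,400 m asl.  They
serve two purposes: as reference inputs for desk-scale recomputations
(e.g. checking that the effectiveness formula reproduces the published
index from the published accuracy and habitat-quality values) and as the
scale the synthetic generator's defaults are matched to.

They are **inputs**, never substitutes for computation: nothing in the
analysis pipeline reads them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import PreferredTemperatureRange

__all__ = ["StudySummary", "GALANI", "BOCAGEI", "SPECIES"]


@dataclass(frozen=True)
class StudySummary:
    """Printed population-level results for one species."""

    species: str
    ptr: PreferredTemperatureRange
    tpref_mean_c: float
    tpref_sd_c: float
    n_tpref_individuals: int
    tb_mean_c: float
    tb_sd_c: float
    n_tb: int
    db: float  # accuracy of thermoregulation (°C), bootstrap mean
    db_sd: float
    db_ci: tuple
    de: float  # thermal quality of habitat (°C), bootstrap mean
    de_sd: float
    de_ci: tuple
    e: float  # effectiveness of thermoregulation, bootstrap mean
    e_sd: float
    e_ci: tuple
    pct_below: float  # habitat-wide share of T_e below/within/above the PTR
    pct_within: float
    pct_above: float


GALANI = StudySummary(
    species="Iberolacerta galani",
    ptr=PreferredTemperatureRange(27.9, 29.7, n_values=144),
    tpref_mean_c=28.8,
    tpref_sd_c=0.47,
    n_tpref_individuals=24,
    tb_mean_c=30.9,
    tb_sd_c=2.39,
    n_tb=79,
    db=1.88, db_sd=0.02, db_ci=(1.848, 1.912),
    de=9.36, de_sd=0.03, de_ci=(9.294, 9.419),
    e=0.80, e_sd=0.002, e_ci=(0.795, 0.802),
    pct_below=46.9, pct_within=5.1, pct_above=48.0,
)

BOCAGEI = StudySummary(
    species="Podarcis bocagei",
    ptr=PreferredTemperatureRange(30.1, 34.5, n_values=144),
    tpref_mean_c=32.3,
    tpref_sd_c=2.11,
    n_tpref_individuals=24,
    tb_mean_c=33.9,
    tb_sd_c=3.03,
    n_tb=72,
    db=1.05, db_sd=0.02, db_ci=(1.012, 1.089),
    de=8.30, de_sd=0.02, de_ci=(8.249, 8.347),
    e=0.87, e_sd=0.002, e_ci=(0.869, 0.878),
    pct_below=52.9, pct_within=8.5, pct_above=38.6,
)

SPECIES = {s.species: s for s in (GALANI, BOCAGEI)}
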