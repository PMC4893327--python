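"""Suitability profiles, multi-group T_e comparison, thermal grouping."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from thermoreg.habitat import (
    classify_thermal_groups,
    compare_microhabitat_te,
    filter_window,
    profiles_to_frame,
    suitability_profile,
)
from thermoreg.posthoc import rank_compare
from thermoreg.records import OperativeTempRecord, PreferredTemperatureRange as PTR


def _ops(temps, microhabitat="rock", sun="shade", hour=12):
    base = datetime(2012, 8, 1, hour, 0)
    return [
        OperativeTempRecord(te_c=float(t), timestamp=base + timedelta(minutes=5 * i),
                            microhabitat=microhabitat, sun=sun)
        for i, t in enumerate(temps)
    ]


def _diel_ops(curve, microhabitat="rock", sun="full_sun", per_hour=4):
    """One record stream over 08-18 h following ``curve(hour_float)``."""
    out = []
    for h in range(8, 18):
        for j in range(per_hour):
            t = h + j / per_hour
            out.append(
                OperativeTempRecord(
                    te_c=float(curve(t)),
                    timestamp=datetime(2012, 8, 1, h, int(60 * j / per_hour)),
                    microhabitat=microhabitat, sun=sun,
                )
            )
    return out


# ------------------------------------------------------------- suitability

def test_all_below_gives_100_0_0(ptr_specialist):
    (total,) = suitability_profile(_ops([20, 21, 22]), ptr_specialist, group_by=None)
    assert (total.pct_below, total.pct_within, total.pct_above) == (100.0, 0.0, 0.0)
    assert total.n == 3


def test_thirds_round_to_one_decimal(ptr_specialist):
    profiles = suitability_profile(_ops([27.0, 28.0, 31.0]), ptr_specialist,
                                   group_by=None)
    frame = profiles_to_frame(profiles)
    row = frame.iloc[0]
    assert (row.pct_below, row.pct_within, row.pct_above) == (33.3, 33.3, 33.3)
    # rounding tolerance: displayed percentages sum to 100 +- 0.2
    assert abs(row.pct_below + row.pct_within + row.pct_above - 100.0) <= 0.2


def test_profiles_counts_sum_and_grouping(study, ptr_specialist):
    day = filter_window(study.operative)
    profiles = suitability_profile(day, ptr_specialist, group_by="microhabitat")
    total = profiles[-1]
    assert total.group == "total" and total.n == len(day)
    groups = profiles[:-1]
    assert sum(p.n for p in groups) == total.n
    for p in profiles:
        assert p.n_below + p.n_within + p.n_above == p.n
        assert p.pct_below + p.pct_within + p.pct_above == pytest.approx(100.0)


def test_raising_upper_bound_moves_mass_downward(study):
    day = filter_window(study.operative)
    low = suitability_profile(day, PTR(27.9, 29.7), group_by=None)[0]
    high = suitability_profile(day, PTR(27.9, 33.0), group_by=None)[0]
    assert high.pct_above <= low.pct_above
    assert high.pct_within + high.pct_below >= low.pct_within + low.pct_below
    assert high.pct_below == low.pct_below  # lower bound untouched


def test_unknown_group_field_raises(study, ptr_specialist):
    with pytest.raises(KeyError):
        suitability_profile(study.operative, ptr_specialist, group_by="altitude")


# ---------------------------------------------------- Kruskal-Wallis/Nemenyi

def kruskal_oracle(groups):
    """Tie-corrected H from first principles (mid-ranks, correction factor)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kruskal_matches_brute_force_with_ties(seed):
    rng = np.random.default_rng(seed)
    groups = {
        "a": rng.integers(0, 8, size=10).astype(float),
        "b": rng.integers(2, 10, size=9).astype(float),
        "c": rng.integers(0, 6, size=11).astype(float),
    }
    report = rank_compare(groups)
    assert report.h == pytest.approx(kruskal_oracle(list(groups.values())), rel=1e-12)
    assert report.df == 2 and report.n == 30


def test_identical_distributions_rarely_differ():
    """Two categories from one distribution: p >= 0.05 in >= 90% of 100 runs."""
    keep = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        te = _ops(rng.normal(25, 3, 30), microhabitat="rock") + _ops(
            rng.normal(25, 3, 30), microhabitat="soil"
        )
        keep += compare_microhabitat_te(te, ("microhabitat",)).p >= 0.05
    assert keep >= 90


def test_well_separated_categories_get_distinct_letters(rng):
    te = (
        _ops(rng.normal(10, 0.1, 20), "rock", "shade")
        + _ops(rng.normal(30, 0.1, 20), "soil", "shade")
        + _ops(rng.normal(50, 0.1, 20), "grass", "full_sun")
    )
    report = compare_microhabitat_te(te)
    letters = set(report.letters.values())
    assert len(letters) == 3 and all(len(l) == 1 for l in letters)
    assert report.p < 1e-6


def test_all_tied_constant_groups_define_h_zero():
    te = _ops([25.0] * 5, "rock") + _ops([25.0] * 5, "soil")
    report = compare_microhabitat_te(te, ("microhabitat",))
    assert report.h == 0.0 and report.p == 1.0
    assert set(report.letters.values()) == {"a"}


def test_small_categories_are_excluded_with_warning(rng):
    te = (_ops(rng.normal(20, 1, 10), "rock") + _ops(rng.normal(25, 1, 10), "grass")
          + _ops([30.0], "soil"))
    with pytest.warns(UserWarning, match="soil"):
        report = compare_microhabitat_te(te, ("microhabitat",),
                                         nemenyi="tukey")
    assert report.dropped == ("soil",)


def test_nemenyi_chi2_matches_hand_formula():
    """Pairwise p equals chi2.sf of the tied-data rank statistic."""
    from scipy import stats as ss

    from thermoreg.posthoc import nemenyi_test

    groups = {"a": [1.0, 2.0, 2.0, 4.0], "b": [3.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0, 10.0]}
    pooled = np.concatenate(list(groups.values()))
    ranks = ss.rankdata(pooled)
    r_a, r_b = ranks[:4].mean(), ranks[4:7].mean()
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    var = (n * (n + 1) / 12.0 - tie) * (1 / 4 + 1 / 3)
    expected = ss.chi2.sf((r_a - r_b) ** 2 / var, 2)
    assert nemenyi_test(groups).loc["a", "b"] == pytest.approx(expected, rel=1e-12)


# -------------------------------------------------------- thermal grouping

def classify_oracle(block_stats, spec, gen):
    """Hour-by-hour re-evaluation of the grouping rules."""
    s = np.asarray(block_stats)
    if np.all(s > gen.upper_c) and np.all(s > spec.upper_c):
        return "very_warm"
    if np.any((s >= spec.lower_c) & (s <= spec.upper_c)):
        return "mild"
    if np.any((s > spec.upper_c) & (s >= gen.lower_c) & (s <= gen.upper_c)):
        return "warm"
    if np.all(s < spec.lower_c) and np.all(s < gen.lower_c):
        return "cold"
    return None  # fallback territory


def test_constant_cold_and_warm_microhabitats(ptr_specialist, ptr_generalist):
    te = _diel_ops(lambda t: 25.0, "soil", "shade") + _diel_ops(
        lambda t: 32.0, "rock", "full_sun"
    )
    groups = classify_thermal_groups(te, ptr_specialist, ptr_generalist)
    assert groups["soil/shade"] == "cold"
    assert groups["rock/full_sun"] == "warm"


def test_diel_sinusoid_matches_hourly_rule_oracle(ptr_specialist, ptr_generalist):
    """A 20-40 °C sinusoid crosses both ranges; the classifier agrees with a
    brute-force hour-by-hour application of the rules."""
    curve = lambda t: 30.0 + 10.0 * np.sin(np.pi * (t - 8) / 10.0)  # noqa: E731
    te = _diel_ops(curve, "rock", "full_sun")
    groups = classify_thermal_groups(te, ptr_specialist, ptr_generalist)

    blocks = {}
    for r in te:
        blocks.setdefault(r.timestamp.hour, []).append(r.te_c)
    stats_ = [np.median(v) for _, v in sorted(blocks.items())]
    expected = classify_oracle(stats_, ptr_specialist, ptr_generalist)
    assert expected is not None
    assert groups["rock/full_sun"] == expected
    assert expected in ("mild", "warm")


def test_very_warm_and_no_daytime_records(ptr_specialist, ptr_generalist):
    te = _diel_ops(lambda t: 45.0, "grass", "full_sun")
    night = [
        OperativeTempRecord(te_c=12.0, timestamp=datetime(2012, 8, 1, 3, 0),
                            microhabitat="log", sun="shade")
    ]
    with pytest.warns(UserWarning, match="log"):
        groups = classify_thermal_groups(te + night, ptr_specialist, ptr_generalist)
    assert groups["grass/full_sun"] == "very_warm"
    assert groups["log/shade"] == "unclassified"


def test_classification_is_deterministic(study, ptr_specialist, ptr_generalist):
    a = classify_thermal_groups(study.operative, ptr_specialist, ptr_generalist)
    b = classify_thermal_groups(study.operative, ptr_specialist, ptr_generalist)
    assert a == b
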