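"""Use-versus-availability comparisons and exact frequency tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as ss
from scipy.special import gammaln

from thermoreg.records import AvailabilityPoint, BodyTempRecord
from thermoreg.selection import (
    frequency_selection_test,
    species_contrast,
    used_vs_available,
)


# ---------------------------------------------------------------- fisher

def fisher_2x2_oracle(table):
    """Two-sided Fisher p by enumerating every table with the observed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    pmf = ss.hypergeom(n, r1, c1).pmf
    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


@pytest.mark.parametrize("seed", range(25))
def test_fisher_2x2_equals_hypergeometric_enumeration(seed):
    """Exact agreement (12 decimals) on random 2x2 tables with n <= 40."""
    rng = np.random.default_rng(seed)
    while True:
        table = rng.integers(0, 11, size=(2, 2))
        if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
            break
    used = {"rock": int(table[0, 0]), "soil": int(table[0, 1])}
    avail = {"rock": int(table[1, 0]), "soil": int(table[1, 1])}
    res = frequency_selection_test(used, avail)
    assert res.method == "fisher_exact"
    assert res.p == pytest.approx(fisher_2x2_oracle(table), abs=1e-12)


def test_identical_proportions_give_p_one():
    res = frequency_selection_test({"rock": 10, "soil": 20}, {"rock": 5, "soil": 10})
    assert res.p == 1.0


def test_complete_separation_2x2_matches_closed_form():
    """[[10,0],[0,10]]: p = 2 / C(20,10) by direct enumeration."""
    res = frequency_selection_test({"rock": 10, "soil": 0}, {"rock": 0, "soil": 10})
    from math import comb

    assert res.p == pytest.approx(2.0 / comb(20, 10), rel=1e-9)


def enumerate_2xk_exact(table):
    """Full conditional enumeration of 2xk tables with fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)

    def logp(cells):
        t = np.array([cells, cols - np.array(cells)])
        return float(
            gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(table.sum() + 1) - gammaln(t + 1).sum()
        )

    lp_obs = logp(table[0])
    total = 0.0
    k = len(cols)

    def rec(i, remaining, cells):
        nonlocal total
        if i == k - 1:
            if 0 <= remaining <= cols[i]:
                lp = logp(cells + [remaining])
                if lp <= lp_obs + 1e-9:
                    total += np.exp(lp)
            return
        for x in range(0, min(int(cols[i]), remaining) + 1):
            rec(i + 1, remaining - x, cells + [x])

    rec(0, int(rows[0]), [])
    return min(total, 1.0)


def test_monte_carlo_exact_agrees_with_full_enumeration():
    """On a small 2x3 table the seeded Monte-Carlo p sits on the enumerated p."""
    used = {"rock": 8, "soil": 2, "grass": 1}
    avail = {"rock": 3, "soil": 6, "grass": 5}
    table = np.array([[8, 2, 1], [3, 6, 5]])
    exact = enumerate_2xk_exact(table)
    res = frequency_selection_test(used, avail, seed=0, n_mc=40_000)
    assert res.method == "monte_carlo"
    assert res.p == pytest.approx(exact, abs=0.01)


def test_k4_overused_category_is_detected():
    """One category used at 3x its availability share, study-sized samples."""
    used = {"rock": 90, "soil": 30, "leaf_litter": 20, "grass": 10}  # n = 150
    avail = {"rock": 37, "soil": 37, "leaf_litter": 25, "grass": 24}  # n = 123
    res = frequency_selection_test(used, avail, seed=42)
    assert res.p < 0.05


def test_frequency_test_input_validation():
    with pytest.raises(ValueError):
        frequency_selection_test({"rock": 1}, {"rock": 2})
    with pytest.raises(ValueError):
        frequency_selection_test({"rock": 0, "soil": 0}, {"rock": 2, "soil": 1})


# ----------------------------------------------------- used vs available

def _body(vals, species="sp_a", variable="ta_c"):
    return [BodyTempRecord(species=species, tb_c=30.0, **{variable: float(v)})
            for v in vals]


def _avail(vals, variable="ta_c"):
    return [
        AvailabilityPoint(capture_ref=f"c{i}", direction="NSEW"[i % 4],
                          **{variable: float(v)})
        for i, v in enumerate(vals)
    ]


def test_three_identical_samples_show_no_signal():
    vals = [1.0, 2.0, 3.0, 4.0]
    rep = used_vs_available(
        {"sp_a": _body(vals, "sp_a"), "sp_b": _body(vals, "sp_b")},
        _avail(vals), "ta_c",
    )
    assert rep.h == pytest.approx(0.0, abs=1e-12)
    assert rep.p > 0.99
    assert (rep.pairwise_p.values >= 0.99).all()


def test_shifted_availability_is_detected_but_species_pair_is_not(rng):
    a = rng.normal(25, 2, 60)
    b = rng.normal(25, 2, 60)
    av = rng.normal(15, 2, 120)  # availability 10 units colder
    rep = used_vs_available(
        {"sp_a": _body(a, "sp_a"), "sp_b": _body(b, "sp_b")},
        _avail(av), "ta_c",
    )
    assert rep.p < 1e-6
    assert rep.pairwise_p.loc["sp_a", "availability"] < 0.001
    assert rep.pairwise_p.loc["sp_b", "availability"] < 0.001
    assert rep.pairwise_p.loc["sp_a", "sp_b"] > 0.05
    assert rep.letters["sp_a"] == rep.letters["sp_b"] != rep.letters["availability"]


def test_missing_values_are_excluded_per_variable():
    records = _body([20, 21, 22], "sp_a") + [BodyTempRecord(species="sp_a", tb_c=30.0)]
    rep = used_vs_available(
        {"sp_a": records, "sp_b": _body([20, 21, 23], "sp_b")},
        _avail([19, 20, 21, 22]), "ta_c",
    )
    assert rep.group_sizes["sp_a"] == 3  # the None row dropped


def test_unknown_variable_is_an_error():
    with pytest.raises(ValueError, match="unknown selection variable"):
        used_vs_available({"sp_a": _body([1, 2])}, _avail([1, 2]), "tb_c")


# ---------------------------------------------------------------- contrasts

def test_identical_samples_contrast_p_one():
    res = species_contrast([5.0] * 4, [5.0] * 6, "mann_whitney")
    assert res.statistic == 12.0 and res.p == 1.0  # U = n*m/2


def test_complete_separation_gives_u_zero():
    res = species_contrast([1, 2, 3], [4, 5, 6], "mann_whitney")
    assert min(res.statistic, 9 - res.statistic) == 0.0


@pytest.mark.parametrize("method,name", [("anova", "F"), ("levene", "W")])
def test_parametric_contrasts_match_scipy(rng, method, name):
    a, b = rng.normal(30, 2, 40), rng.normal(32, 3, 35)
    res = species_contrast(a, b, method)
    if method == "anova":
        stat, p = ss.f_oneway(a, b)
    else:
        stat, p = ss.levene(a, b, center="mean")
    assert res.statistic == pytest.approx(float(stat))
    assert res.p == pytest.approx(float(p))
    assert res.statistic_name == name and res.df == (1, 73)


def test_levene_median_variant_selected_by_flag(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0, 3, 30)
    res = species_contrast(a, b, "levene", levene_center="median")
    stat, _ = ss.levene(a, b, center="median")
    assert res.statistic == pytest.approx(float(stat))


def test_unknown_method_rejected():
    with pytest.raises(ValueError):
        species_contrast([1, 2], [3, 4], "t_test")


def test_kruskal_two_groups_equals_squared_rank_z(rng):
    """For 2 untied groups, H equals the squared Mann-Whitney normal score."""
    a = rng.permutation(np.arange(0, 30, dtype=float))[:12]
    b = rng.permutation(np.arange(100, 130, dtype=float))[:15] + 0.5
    h, _ = ss.kruskal(a, b)
    u = ss.mannwhitneyu(a, b, alternative="two-sided").statistic
    n, m = len(a), len(b)
    z = (u - n * m / 2) / np.sqrt(n * m * (n + m + 1) / 12.0)
    assert h == pytest.approx(z**2, rel=1e-10)
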