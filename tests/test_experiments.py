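"""Outcome classification and the statistics / experiment harness."""

import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from humoralsim import ContingencyTable, ParameterSet
from humoralsim.config_io import ConfigError
from humoralsim.experiments import (classify_outcome, classify_series,
                                    fisher_one_sided, run_comparison_grid,
                                    run_memory_experiment, run_sensitivity,
                                    welch_t_test)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_win_with_elimination_time():
    series = [(3000.0, 350), (3001.0, 420), (3002.0, 60), (3003.0, 49)]
    rec = classify_series(series, [3000.0], t_max=3500.0)
    assert rec.win
    assert rec.elimination_time_1 == pytest.approx(3.0)
    assert rec.death_time is None


def test_classify_death_at_lethal_threshold():
    series = [(3000.0, 350), (3100.0, 4000)]
    rec = classify_series(series, [3000.0], t_max=3500.0)
    assert not rec.win
    assert rec.death_time == 3100.0


def test_classify_boundary_is_strictly_under_fifty():
    series = [(3000.0, 350), (3400.0, 50)]
    rec = classify_series(series, [3000.0], t_max=3500.0)
    assert not rec.win
    assert rec.elimination_time_1 is None


def test_classify_merged_second_injection():
    """A re-injection into a cleared population arms a fresh elimination
    clock; the pre-injection zero must not count as an elimination."""
    series = [(3000.0, 350), (3050.0, 49), (3060.0, 0),
              (3150.0, 0), (3150.0, 350), (3175.0, 40)]
    rec = classify_series(series, [3000.0, 3150.0], t_max=3400.0)
    assert rec.win
    assert rec.elimination_time_1 == pytest.approx(50.0)
    assert rec.elimination_time_2 == pytest.approx(25.0)


def test_classify_is_stride_invariant_when_crossings_present():
    dense = [(3000.0 + k, 350 - 10 * k) for k in range(32)]
    sparse = [p for p in dense if p[1] >= 50] + [next(p for p in dense
                                                      if p[1] < 50)]
    r1 = classify_series(dense, [3000.0], t_max=3500.0)
    r2 = classify_series(sparse, [3000.0], t_max=3500.0)
    assert (r1.win, r1.elimination_time_1) == (r2.win, r2.elimination_time_1)


def test_classify_requires_an_infection():
    with pytest.raises(ValueError):
        classify_series([(0.0, 10)], [], t_max=100.0)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def test_fisher_single_term_table():
    # (5,0;0,5): a single hypergeometric term C(5,5)C(5,0)/C(10,5) = 1/252
    assert fisher_one_sided(((5, 0), (0, 5))) == pytest.approx(1 / 252)


@pytest.mark.parametrize("a, b", [(3, 3), (7, 7), (12, 12)])
def test_fisher_balanced_tables_are_not_significant(a, b):
    assert fisher_one_sided(((a, a), (b, b))) >= 0.5


def test_fisher_zero_margin_convention():
    assert fisher_one_sided(((0, 0), (5, 7))) == 1.0
    assert fisher_one_sided(((3, 4), (0, 0))) == 1.0


def test_fisher_agrees_with_scipy_on_random_tables():
    """Independent cross-check against scipy's implementation."""
    rng = random.Random(0)
    for _ in range(60):
        a, b, c, d = (rng.randint(0, 60) for _ in range(4))
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        ours = fisher_one_sided(((a, b), (c, d)))
        ref = stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
        assert ours == pytest.approx(float(ref), rel=1e-9, abs=1e-300)


def test_fisher_contingency_table_input_and_validation():
    tbl = ContingencyTable(5, 1, 2, 6)
    assert fisher_one_sided(tbl) == pytest.approx(
        fisher_one_sided(((5, 1), (2, 6))))
    assert tbl.total == 14
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 0)


def test_fisher_small_tables_match_rational_arithmetic():
    """Exhaustive integer-arithmetic oracle on all tables with n <= 12."""
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    row1, row2, col1 = a + b, c + d, a + c
                    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
                        continue
                    num = sum(math.comb(row1, i) * math.comb(row2, col1 - i)
                              for i in range(a, min(row1, col1) + 1))
                    exact = Fraction(num, math.comb(n, col1))
                    assert fisher_one_sided(((a, b), (c, d))) == pytest.approx(
                        float(exact), rel=1e-12)


# ---------------------------------------------------------------------------
# Welch t-test
# ---------------------------------------------------------------------------

def test_welch_identical_samples():
    assert welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
    assert welch_t_test([2.0, 2.0], [2.0, 2.0]) == 1.0  # degenerate variance


def test_welch_requires_two_observations():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [1.0, 2.0])


def test_welch_null_calibration():
    """Under the null the p-values are uniform (KS test at alpha = 0.01)."""
    rng = np.random.default_rng(7)
    pvals = [welch_t_test(rng.normal(size=50), rng.normal(size=50))
             for _ in range(1000)]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_welch_separated_means_are_astronomically_significant():
    """Samples mimicking elimination-time statistics (means 62 vs 20.5,
    sd ~13/15, n=451) give p far below 1e-100."""
    rng = np.random.default_rng(1)
    z1, z2 = rng.normal(size=451), rng.normal(size=451)
    x = 62.02 + 13.26 * (z1 - z1.mean()) / z1.std(ddof=1)
    y = 20.51 + 14.94 * (z2 - z2.mean()) / z2.std(ddof=1)
    assert welch_t_test(x, y) < 1e-100


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

def test_comparison_grid_smoke_and_columns():
    df = run_comparison_grid([(350, 50)], reps=2, seed=1)
    row = df.iloc[0]
    assert set(df.columns) == {"f_cells", "div_time", "ers_wins", "crs_wins",
                               "reps", "ratio", "p_value"}
    assert 0 <= row.ers_wins <= 2 and 0 <= row.crs_wins <= 2
    assert 0.0 <= row.p_value <= 1.0


def test_comparison_grid_rejects_bad_reps():
    with pytest.raises(ValueError):
        run_comparison_grid([(350, 50)], reps=0)


def test_memory_experiment_structure_and_bounds():
    res = run_memory_experiment(3, seed=2)
    assert res["reps"] == 3
    assert 0 <= res["cleared_both"] <= 3
    assert len(res["outcomes"]) == 3
    for rec in res["outcomes"]:
        assert rec.model == "ers"
        assert not (rec.win and rec.death_time is not None)
    if res["cleared_both"] >= 2:
        assert res["mean2"] < res["mean1"]


def test_memory_experiment_rejects_zero_reps():
    with pytest.raises(ValueError):
        run_memory_experiment(0)


def test_sensitivity_rejects_inverted_range():
    bad = {"r0": (150, 250, 50, int)}
    with pytest.raises(ConfigError):
        run_sensitivity(5, ranges=bad)


def test_sensitivity_samples_respect_ranges():
    ranges = {"r0": (150, 140, 160, int), "pmem": (0.3, 0.25, 0.35, float)}
    raw, corr = run_sensitivity(3, seed=3, ranges=ranges, t_end=400.0,
                                infection_step=300.0)
    assert len(raw) == 3
    assert raw["r0"].between(140, 160).all()
    assert raw["pmem"].between(0.25, 0.35).all()
    assert corr.shape == (2, 7)
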