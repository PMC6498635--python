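"""Batch experiments and their statistics.

Win/loss classification of infection runs, the one-sided Fisher exact test
used to compare the ERS and CRS models, Welch's t-test for elimination
times, the repeated-infection memory experiment, the ERS-vs-CRS survival
grids, and the uniform-sampling sensitivity analysis with Pearson
correlations.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .agents import CENSUS_FIELDS, census
from .config_io import ConfigError, ParameterSet
from .immune_rules import DEATH_THRESHOLD, ELIMINATION_THRESHOLD
from .shape_space import ShapePoint
from .simulation import Simulation


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

@dataclass
class OutcomeRecord:
    """Per-run win/loss classification with elimination times (in steps)."""

    run_id: int = 0
    seed: int = 0
    model: str = "ers"
    win: bool = False
    elimination_times: list = field(default_factory=list)
    death_time: float | None = None
    final_census: tuple = ()

    @property
    def elimination_time_1(self):
        return self.elimination_times[0] if len(self.elimination_times) >= 1 else None

    @property
    def elimination_time_2(self):
        return self.elimination_times[1] if len(self.elimination_times) >= 2 else None


def classify_series(series, infection_times, t_max: float) -> OutcomeRecord:
    """Classify one pathogen population's count series.

    ``series`` is an iterable of ``(t, count)`` points that contains every
    crossing of the outcome thresholds (event-granular change points are
    ideal; a dense sampling works as long as crossings appear in it).  A run
    is a *win* iff each injection's population dropped under
    ``ELIMINATION_THRESHOLD`` before ``t_max`` and the count never reached
    ``DEATH_THRESHOLD``; elimination times are measured from the matching
    injection.
    """
    if not infection_times:
        raise ValueError("classification requires at least one infection")
    pts = sorted(series, key=lambda p: p[0])
    death_time = None
    for t, c in pts:
        if c >= DEATH_THRESHOLD:
            death_time = t
            break
    elim: list[float | None] = []
    for inj in sorted(infection_times):
        e = None
        armed = False  # the injected population must first stand at/above
        # the threshold before a crossing below it counts as elimination
        for t, c in pts:
            if t < inj:
                continue
            if not armed:
                if c >= ELIMINATION_THRESHOLD:
                    armed = True
                continue
            if c < ELIMINATION_THRESHOLD:
                e = t - inj
                break
        elim.append(e)
    win = death_time is None and all(e is not None for e in elim)
    return OutcomeRecord(win=win, elimination_times=elim, death_time=death_time)


def classify_outcome(source, infection_times=None, t_max: float | None = None) -> OutcomeRecord:
    """Classify a completed run (a :class:`Simulation` or a raw series)."""
    if isinstance(source, Simulation):
        if not source.foreign_pops:
            raise ValueError("classification requires at least one infection")
        t_end = source.clock.t
        records = []
        for pop in source.foreign_pops:
            trace = list(pop.trace)
            trace.append((t_end, pop.count))
            records.append(classify_series(trace, pop.injections, t_end))
        death_times = [r.death_time for r in records if r.death_time is not None]
        elim = [e for r in records for e in r.elimination_times]
        rec = OutcomeRecord(
            seed=source.seed,
            model="crs" if source.cfg.comptype == 1 else "ers",
            win=all(r.win for r in records) and not death_times,
            elimination_times=elim,
            death_time=min(death_times) if death_times else None,
            final_census=census(source))
        return rec
    if t_max is None:
        t_max = max(t for t, _ in source)
    return classify_series(source, infection_times, t_max)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Win/loss counts of the two models (rows: win/loss, columns: ERS/CRS)."""

    ers_wins: int
    crs_wins: int
    ers_losses: int
    crs_losses: int

    def __post_init__(self) -> None:
        for v in (self.ers_wins, self.crs_wins, self.ers_losses, self.crs_losses):
            if v < 0 or int(v) != v:
                raise ValueError("contingency cells must be nonnegative integers")

    @property
    def total(self) -> int:
        return self.ers_wins + self.crs_wins + self.ers_losses + self.crs_losses


def fisher_one_sided(table) -> float:
    """One-sided (upper tail) Fisher exact test for an ERS-vs-CRS table.

    For the table ``[[a, b], [c, d]]`` (wins in the first row, ERS in the
    first column) the p-value is the upper hypergeometric tail at the
    observed ERS-win cell::

        p = sum_{i=a}^{min(a+b, a+c)} C(a+b, i) C(c+d, a+c-i) / C(n, a+c)

    computed in log space so that tables of hundreds of runs do not
    underflow.  A table with a zero margin carries no information and
    returns 1 by convention.
    """
    if isinstance(table, ContingencyTable):
        a, b, c, d = table.ers_wins, table.crs_wins, table.ers_losses, table.crs_losses
    else:
        (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("contingency cells must be nonnegative")
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or col1 == n:
        return 1.0
    lg = math.lgamma

    def log_choose(m: int, k: int) -> float:
        return lg(m + 1) - lg(k + 1) - lg(m - k + 1)

    denom = log_choose(n, col1)
    hi = min(row1, col1)
    logs = [log_choose(row1, i) + log_choose(row2, col1 - i) - denom
            for i in range(a, hi + 1)]
    peak = max(logs)
    p = math.exp(peak) * math.fsum(math.exp(x - peak) for x in logs)
    return min(p, 1.0)


def welch_t_test(sample1, sample2) -> float:
    """Two-tailed Welch t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(_stats.ttest_ind(x, y, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------

#: Uniform sampling ranges of the sensitivity study: name -> (default, min,
#: max, type).  The default sits at the centre of each range.
TABLE5_RANGES: dict[str, tuple] = {
    "r0": (150, 50, 250, int),
    "pmem": (0.3, 0.1, 0.5, float),
    "crnew": (0.9, 0.1, 1.7, float),
    "rminnew": (5, 1, 9, int),
    "crspread": (0.9, 0.1, 1.7, float),
    "rminsprd": (5, 1, 10, int),
    "thrad": (80, 50, 250, int),
    "pmut": (0.4, 0.1, 0.7, float),
    "taub0": (5.0, 1.0, 9.0, float),
    "tauth0": (2.0, 1.0, 9.0, float),
    "tcrit_stress": (2.0, 1.0, 3.0, float),
    "nr": (350, 200, 500, int),
    "tr": (60.0, 40.0, 80.0, float),
}

#: desk-scale horizons (steps); infections land at day 300 = step 3000
INFECTION_STEP = 3000.0
COMPARISON_T_MAX = 3500.0
MEMORY_T_MAX = 3400.0


def _run_seeds(master_seed: int, n: int) -> list[int]:
    rng = random.Random(master_seed)
    return [rng.getrandbits(31) for _ in range(n)]


def _infection_resolved(sim: Simulation) -> bool:
    if sim.host_dead:
        return True
    if sim.pending_infections:
        return False
    pops = sim.foreign_pops
    return bool(pops) and all(p.count == 0 for p in pops)


def run_infection_once(params: ParameterSet, seed: int,
                       infections: list[tuple[float, int, float, int, int]],
                       t_max: float, stop_resolved: bool = True) -> OutcomeRecord:
    """One seeded run with the given infection schedule, classified."""
    p = params.with_updates({"seed": seed, "record_every": 10.0},
                            infections=infections)
    sim = Simulation(p)
    sim.run(t_max=t_max,
            stop_when=_infection_resolved if stop_resolved else None)
    rec = classify_outcome(sim)
    rec.seed = seed
    return rec


def run_comparison_grid(arms, reps: int, base_params: ParameterSet | None = None,
                        seed: int = 0, t_max: float = COMPARISON_T_MAX,
                        infection_step: float = INFECTION_STEP) -> pd.DataFrame:
    """ERS-vs-CRS survival grid.

    ``arms`` is a sequence of ``(f_cells, div_time)`` pairs; for each arm
    both models are run ``reps`` times against an infection injected at
    ``infection_step`` and the wins are tabulated with the win ratio and the
    one-sided Fisher exact p-value.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = base_params if base_params is not None else ParameterSet()
    rows = []
    for arm_idx, (f_cells, div_time) in enumerate(arms):
        wins = {}
        for model in ("ers", "crs"):
            params = base.with_updates(model=model)
            shape = (params.foreign_x, params.foreign_y)
            seeds = _run_seeds(seed + 7919 * arm_idx + (0 if model == "ers" else 1), reps)
            w = 0
            for s in seeds:
                rec = run_infection_once(
                    params, s,
                    [(infection_step, int(f_cells), float(div_time), *shape)],
                    t_max)
                w += int(rec.win)
            wins[model] = w
        tbl = ContingencyTable(wins["ers"], wins["crs"],
                               reps - wins["ers"], reps - wins["crs"])
        ratio = (round(wins["ers"] / wins["crs"], 3)
                 if wins["crs"] > 0 else float("inf"))
        rows.append({"f_cells": f_cells, "div_time": div_time,
                     "ers_wins": wins["ers"], "crs_wins": wins["crs"],
                     "reps": reps, "ratio": ratio,
                     "p_value": fisher_one_sided(tbl)})
    return pd.DataFrame(rows)


def run_memory_experiment(reps: int, params: ParameterSet | None = None,
                          seed: int = 0, days: tuple[float, float] = (300.0, 315.0),
                          t_max: float = MEMORY_T_MAX) -> dict:
    """Repeated-infection immune-memory experiment (ERS model).

    The same pathogen (``nr`` cells, division wait ``tr``) is injected at
    the two given days; among runs clearing both infections the mean and
    standard deviation of the two elimination times are reported together
    with the two-tailed Welch p-value for equality of the means.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = (params if params is not None else ParameterSet()).with_updates(model="ers")
    shape = (base.foreign_x, base.foreign_y)
    steps = tuple(10.0 * d for d in days)
    elim1, elim2 = [], []
    outcomes = []
    for s in _run_seeds(seed, reps):
        rec = run_infection_once(
            base, s,
            [(steps[0], base.nr, base.tr, *shape),
             (steps[1], base.nr, base.tr, *shape)],
            t_max)
        outcomes.append(rec)
        if rec.win and rec.elimination_time_1 is not None \
                and rec.elimination_time_2 is not None:
            elim1.append(rec.elimination_time_1)
            elim2.append(rec.elimination_time_2)
    cleared = len(elim1)
    result = {"reps": reps, "cleared_both": cleared,
              "injection_steps": steps, "outcomes": outcomes,
              "elim1": elim1, "elim2": elim2}
    if cleared >= 2:
        a1, a2 = np.asarray(elim1), np.asarray(elim2)
        result.update(mean1=float(a1.mean()), sd1=float(a1.std(ddof=1)),
                      mean2=float(a2.mean()), sd2=float(a2.std(ddof=1)),
                      p_value=welch_t_test(a1, a2))
    else:
        result.update(mean1=None, sd1=None, mean2=None, sd2=None, p_value=None)
    return result


def run_sensitivity(n_samples: int, seed: int = 0,
                    ranges: dict | None = None,
                    base_params: ParameterSet | None = None,
                    infection_step: float = INFECTION_STEP,
                    t_end: float = 3050.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform-sampling sensitivity analysis.

    Samples the core parameters uniformly in their ranges, runs each sample
    to ``t_end`` (day 305: five days after an infection of random type at
    day 300) and returns the per-run raw data and the input-by-output
    Pearson correlation matrix rounded to one decimal.  The "random type" of
    infection is realised by the sampled ``nr`` and ``tr`` and a uniformly
    random antigen-lattice shape.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    ranges = dict(TABLE5_RANGES if ranges is None else ranges)
    for name, (default, lo, hi, typ) in ranges.items():
        if lo > hi:
            raise ConfigError(f"inverted range for {name!r}: [{lo}, {hi}]")
    base = base_params if base_params is not None else ParameterSet()
    master = random.Random(seed)
    rows = []
    for k in range(n_samples):
        sample = {}
        for name, (default, lo, hi, typ) in ranges.items():
            sample[name] = master.randint(lo, hi) if typ is int \
                else master.uniform(lo, hi)
        run_seed = master.getrandbits(31)
        half = 500
        shape = ShapePoint(master.randint(0, 1000), master.randint(-half, half))
        p = base.with_updates({**sample, "seed": run_seed, "record_every": 10.0})
        sim = Simulation(p)
        sim.inject(infection_step, nr=p.nr, tr=p.tr, shape=shape)
        sim.run(t_max=t_end)
        out = dict(zip(CENSUS_FIELDS, census(sim)))
        rows.append({**sample, **out, "run_seed": run_seed})
    raw = pd.DataFrame(rows)
    inputs = list(ranges)
    corr = pd.DataFrame(index=inputs, columns=list(CENSUS_FIELDS), dtype=float)
    for name in inputs:
        x = raw[name].to_numpy(dtype=float)
        for out_name in CENSUS_FIELDS:
            y = raw[out_name].to_numpy(dtype=float)
            if x.std() == 0.0 or y.std() == 0.0:
                # a constant output (e.g. a saturated marrow pool) carries no
                # correlation information
                corr.loc[name, out_name] = 0.0
            else:
                corr.loc[name, out_name] = round(
                    float(np.corrcoef(x, y)[0, 1]), 1)
    return raw, corr
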