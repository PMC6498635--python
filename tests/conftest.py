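"""Shared fixtures.

The heavy batch experiments (memory, survival grid, homeostasis/knockout,
sensitivity) are computed once per session and shared between the tests
that assert different properties of the same experiment.
"""

import pytest
from hypothesis import HealthCheck, settings

from humoralsim import ParameterSet, Simulation
from humoralsim.experiments import (run_comparison_grid,
                                    run_memory_experiment, run_sensitivity)

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ers_infection_run():
    """One full ERS run with the standard infection, kept for bookkeeping
    checks (conservation, monotone counters, outcome classification)."""
    params = ParameterSet(values={"seed": 42, "record_every": 1.0})
    sim = Simulation(params)
    sim.inject(3000.0)
    sim.run(t_max=3300.0)
    return sim


@pytest.fixture(scope="session")
def memory_experiment():
    """The repeated-infection memory experiment at 100 replicates."""
    return run_memory_experiment(100, seed=0)


@pytest.fixture(scope="session")
def comparison_grid():
    """ERS-vs-CRS survival grid: 100+100 replicates on the two test arms."""
    return run_comparison_grid([(350, 50), (350, 40)], reps=100, seed=0)


@pytest.fixture(scope="session")
def homeostasis_and_knockout():
    """Matched default / negative-selection-knockout runs, 50 seeds each.

    Returns (default_final_nW, knockout_final_nW, one default Simulation)
    with matched seeds so each knockout run has its control.
    """
    default_nw, knockout_nw = [], []
    kept = None
    for seed in range(1, 51):
        sim = Simulation(ParameterSet(values={"seed": seed, "record_every": 50.0}))
        sim.run()
        default_nw.append(sum(p.count for p in sim.self_pops))
        if kept is None:
            kept = sim
        ko = Simulation(ParameterSet(values={"seed": seed, "record_every": 50.0,
                                             "negsel_on": 0}))
        ko.run()
        knockout_nw.append(sum(p.count for p in ko.self_pops))
    return default_nw, knockout_nw, kept


@pytest.fixture(scope="session")
def sensitivity_result():
    """Uniform-sampling sensitivity analysis, 200 samples."""
    return run_sensitivity(200, seed=0)
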