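"""Event-handler rules: selection, interactions, divisions, soluble pools."""

import random

import pytest

from humoralsim import ParameterSet, RuleViolation, Simulation
from humoralsim.agents import ACTIVATED, NAIVE, PLASMA, STRONG, BCell, ThCell
from humoralsim.immune_rules import (DELETE, INTERMEDIATE, KEEP, STRONG_KIND,
                                     WEAK, b_action, b_activation_control,
                                     b_negative_selection, danger_action,
                                     division, infection_inject,
                                     interleukin_action, th_thymic_selection)
from humoralsim.shape_space import (Lattice, ShapePoint, ball_points,
                                    linf_distance, mirror)

SELF_MIRRORS = [ShapePoint(550, -300), ShapePoint(700, 200),
                ShapePoint(850, -150)]


def quiet_sim(**overrides):
    """A simulation with no marrow output: agents are placed by hand."""
    values = {"seed": 5, "marrow_init": 0}
    self_pops = overrides.pop("self_pops", None)
    values.update(overrides)
    params = ParameterSet(values=values,
                          self_pops=self_pops if self_pops is not None
                          else list(ParameterSet().self_pops))
    return Simulation(params)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_b_negative_selection_examples():
    assert b_negative_selection(ShapePoint(550, -300), SELF_MIRRORS, 50) == DELETE
    assert b_negative_selection(ShapePoint(0, 0), SELF_MIRRORS, 50) == KEEP
    # distance exactly equal to the radius survives (strict inequality)
    assert b_negative_selection(ShapePoint(500, -300), SELF_MIRRORS, 50) == KEEP


def test_b_negative_selection_fraction_matches_ball_union():
    """Deleted fraction under uniform births equals the exact area of the
    union of deletion balls, enumerated on a 100x100 lattice."""
    lat = Lattice(100)
    mirrors = [ShapePoint(30, -20), ShapePoint(45, -25), ShapePoint(90, 40)]
    radius = 12
    union = set()
    for m in mirrors:
        union |= ball_points(m, radius - 1, lat)  # strict: d < radius
    deleted = [ShapePoint(x, y)
               for x in range(101) for y in range(-50, 51)
               if b_negative_selection(ShapePoint(x, y), mirrors, radius) == DELETE]
    assert len(deleted) == len(union)
    assert set(deleted) == union


@pytest.mark.parametrize("comptype, d_probe, expected", [
    (0, 0, (DELETE, False)),       # at the mirror: deleted in both models
    (1, 0, (DELETE, False)),
    (0, 50, (KEEP, True)),         # inner ring edge: regulatory in ERS
    (1, 50, (DELETE, False)),      # ... deleted in CRS
    (0, 80, (KEEP, True)),         # outer edge still regulatory
    (1, 80, (DELETE, False)),
    (0, 81, (KEEP, False)),        # beyond the ring: conventional cell
    (1, 81, (KEEP, False)),
])
def test_th_thymic_selection_boundaries(comptype, d_probe, expected):
    tcr = ShapePoint(550 + d_probe, -300)
    decision, regulatory, ring = th_thymic_selection(
        tcr, SELF_MIRRORS, comptype=comptype, ring_inner=50, ring_outer=80)
    assert (decision, regulatory) == expected
    if regulatory:
        assert ring == 0


def test_th_selection_fractions_match_exact_areas():
    """Survivor and regulatory fractions equal exact ball/annulus areas on a
    100x100 lattice (overlapping domains included via set union)."""
    lat = Lattice(100)
    mirrors = [ShapePoint(30, 0), ShapePoint(40, 5)]  # overlapping rings
    inner, outer = 6, 10
    inner_union, outer_union = set(), set()
    for m in mirrors:
        inner_union |= ball_points(m, inner - 1, lat)
        outer_union |= ball_points(m, outer, lat)
    every = [ShapePoint(x, y) for x in range(101) for y in range(-50, 51)]
    for comptype in (0, 1):
        outcome = [th_thymic_selection(z, mirrors, comptype=comptype,
                                       ring_inner=inner, ring_outer=outer)
                   for z in every]
        kept = sum(d == KEEP for d, _r, _i in outcome)
        regulatory = sum(r for _d, r, _i in outcome)
        if comptype == 0:
            assert kept == len(every) - len(inner_union)
            assert regulatory == len(outer_union) - len(inner_union)
        else:
            assert kept == len(every) - len(outer_union)
            assert regulatory == 0


# ---------------------------------------------------------------------------
# B action, divisions
# ---------------------------------------------------------------------------

def test_b_action_engulfs_perfect_complement_with_certainty():
    sim = quiet_sim(self_pops=[])
    shape = ShapePoint(300, 350)
    sim.add_foreign(shape, 100, 1e9, 0.0)
    cell = BCell(mirror(shape))
    sim.add_b(cell)
    b_action(sim, cell)
    assert sim.foreign_pops[0].count == 99
    assert cell.presented == shape and cell.presented_self == -1


def test_b_action_noop_without_antigen():
    sim = quiet_sim(self_pops=[])
    cell = BCell(ShapePoint(10, 10))
    sim.add_b(cell)
    b_action(sim, cell)  # no antigen populations anywhere
    assert cell.presented is None


def test_division_without_mutation_copies_the_receptor():
    sim = quiet_sim(pmut=0.0)
    parent = BCell(ShapePoint(200, 100), state=STRONG)
    sim.add_b(parent)
    child = division(sim, parent, STRONG_KIND)
    assert child.bcr == parent.bcr


def test_division_offspring_can_improve_affinity():
    """With mutation radius ~5-6 a parent 20 away from the target mirror
    produces offspring strictly closer in a clearly positive fraction."""
    sim = quiet_sim(pmut=1.0, pmem=0.0, memory_recall_p=0.0)
    target = ShapePoint(500, 0)
    parent = BCell(ShapePoint(520, 0), state=STRONG)
    sim.add_b(parent)
    closer = 0
    n = 4000
    for _ in range(n):
        child = division(sim, parent, STRONG_KIND)
        if linf_distance(child.bcr, target) < 20:
            closer += 1
        sim.remove_b(child)
        parent.strong_streak = 0  # keep the parent from plasma conversion
    assert 0.05 < closer / n < 0.5


def test_disabled_division_kinds_raise():
    sim = quiet_sim(medrepr=0, weakrepr=0)
    cell = BCell(ShapePoint(1, 1))
    sim.add_b(cell)
    with pytest.raises(RuleViolation):
        division(sim, cell, WEAK)
    with pytest.raises(RuleViolation):
        division(sim, cell, INTERMEDIATE)


def test_division_updates_the_matching_counter():
    sim = quiet_sim()
    b = BCell(ShapePoint(5, 5))
    sim.add_b(b)
    th = ThCell(ShapePoint(5, 5))
    sim.add_th(th)
    division(sim, b, WEAK)
    division(sim, th, INTERMEDIATE)
    division(sim, th, STRONG_KIND)
    c = sim.counters
    assert (c.weak_B, c.intermediate_T, c.strong_T) == (1, 1, 1)
    assert c.weak_T == c.intermediate_B == c.strong_B == 0


def test_strong_division_streak_makes_plasma():
    sim = quiet_sim(pmut=0.0, pmem=0.0)
    cell = BCell(ShapePoint(100, 0), state=STRONG)
    sim.add_b(cell)
    for _ in range(sim.cfg.plasma_after):
        division(sim, cell, STRONG_KIND)
    assert cell.state == PLASMA
    assert cell in sim.plasma_cells and cell not in sim.b_cells


# ---------------------------------------------------------------------------
# activation control
# ---------------------------------------------------------------------------

def _presenting_self(sim, pop_idx=0):
    pop = sim.self_pops[pop_idx]
    cell = BCell(mirror(pop.shape))
    sim.add_b(cell)
    cell.presented = pop.shape
    cell.presented_self = pop_idx
    cell.presented_at = sim.clock.t
    cell.last_contact = sim.clock.t
    sim.pres_add(cell)
    return cell


def test_threg_guarded_self_presenter_never_activates():
    sim = quiet_sim()
    threg = ThCell(sim.self_mirrors[0], regulatory=True, ring=0)
    sim.add_th(threg)
    cell = _presenting_self(sim)
    for step in range(1, 101):
        sim.clock.t = float(step)
        cell.presented_at = sim.clock.t  # keep the presentation loaded
        b_activation_control(sim, cell)
    assert cell.state == NAIVE
    assert sim.danger.count == 0


def test_foreign_presenter_activates_after_critical_period():
    sim = quiet_sim(tcrit_stress=2.0)
    cell = BCell(ShapePoint(100, 100))
    sim.add_b(cell)
    cell.presented = ShapePoint(300, 350)
    cell.presented_self = -1
    cell.presented_at = 0.0
    cell.last_contact = 0.0
    sim.pres_add(cell)
    sim.clock.t = 1.5
    b_activation_control(sim, cell)
    assert cell.state == NAIVE  # within the critical period
    sim.clock.t = 2.5
    b_activation_control(sim, cell)
    assert cell.state == ACTIVATED
    assert sim.danger.count == sim.cfg.danger_burst


def test_without_any_thregs_self_presenters_eventually_activate():
    """Pathological scenario: the regulatory compartment is absent, so
    every presenting B cell ends up activated."""
    sim = quiet_sim(tcrit_stress=2.0)
    cells = [_presenting_self(sim, i) for i in range(3)]
    assert not any(sim.ring_members)
    sim.clock.t = 5.0
    for cell in cells:
        b_activation_control(sim, cell)
    assert all(cell.state == ACTIVATED for cell in cells)


# ---------------------------------------------------------------------------
# danger signals and interleukins
# ---------------------------------------------------------------------------

def test_danger_action_dissipates_without_th_cells():
    sim = quiet_sim()
    sim.pool_delta(sim.danger, 3)
    danger_action(sim, None)
    assert sim.danger.count == 2
    assert sim.interleukin.count == 0


def test_danger_action_single_th_always_chosen():
    sim = quiet_sim(medrepr=0)
    th = ThCell(ShapePoint(1, 1))
    sim.add_th(th)
    sim.pool_delta(sim.danger, 1)
    danger_action(sim, None)
    assert th.state == ACTIVATED
    assert sim.interleukin.count == sim.cfg.il_burst


def test_danger_action_targets_th_cells_uniformly():
    sim = quiet_sim(medrepr=0, il_burst=0)
    cells = [ThCell(ShapePoint(i, 0)) for i in range(4)]
    for cell in cells:
        sim.add_th(cell)
    n = 4000
    counts = [0, 0, 0, 0]
    for _ in range(n):
        sim.pool_delta(sim.danger, 1)
        danger_action(sim, None)
        for i, cell in enumerate(cells):
            if cell.state == ACTIVATED:
                counts[i] += 1
                cell.state = NAIVE
    se = (0.25 * 0.75 / n) ** 0.5
    for c in counts:
        assert abs(c / n - 0.25) < 3 * se


def test_interleukin_only_divides_uncontrolled_cells():
    sim = quiet_sim()
    guarded = BCell(ShapePoint(1, 1))          # naive: under control
    sim.add_b(guarded)
    sim.pool_delta(sim.interleukin, 1)
    interleukin_action(sim, None)
    assert sim.n_b == 1                        # no division scheduled

    lost = BCell(ShapePoint(2, 2), state=ACTIVATED)
    sim.remove_b(guarded)
    sim.add_b(lost)
    sim.pool_delta(sim.interleukin, 1)
    interleukin_action(sim, None)
    assert sim.n_b == 2                        # intermediate division fired
    assert sim.counters.intermediate_B == 1


def test_crs_run_never_emits_danger_or_interleukin():
    params = ParameterSet(values={"seed": 8, "record_every": 50.0}).with_updates(
        model="crs")
    sim = Simulation(params)
    sim.inject(300.0)
    sim.run(t_max=600.0)
    assert sim.danger.births == 0
    assert sim.interleukin.births == 0


# ---------------------------------------------------------------------------
# antibodies and infections
# ---------------------------------------------------------------------------

def test_antibodies_share_the_plasma_receptor_and_clear_a_static_target():
    sim = quiet_sim(self_pops=[], seed=12)
    shape = ShapePoint(300, 350)
    sim.add_foreign(shape, 100, 1e9, 0.0)
    cell = BCell(mirror(shape), state=STRONG)
    sim.add_b(cell)
    sim.to_plasma(cell)
    sim.run(t_max=2000.0)
    pop = sim.foreign_pops[0]
    assert pop.count == 0
    counts = [c for _t, c in pop.trace]
    assert counts == sorted(counts, reverse=True)  # monotone absorption
    assert set(sim.antibody_pops) == {cell.bcr}


def test_no_plasma_means_no_antibodies():
    sim = Simulation(ParameterSet(values={"seed": 2, "record_every": 100.0}))
    sim.run(t_max=600.0)  # homeostasis only: nothing strongly activated
    assert not sim.antibody_pops


def test_infection_inject_merges_same_shape():
    sim = quiet_sim()
    shape = ShapePoint(300, 350)
    infection_inject(sim, 10.0, 350, 60.0, shape)
    infection_inject(sim, 20.0, 350, 60.0, shape)
    assert len(sim.foreign_pops) == 1
    pop = sim.foreign_pops[0]
    assert pop.count == 700
    assert pop.injections == [10.0, 20.0]
    infection_inject(sim, 30.0, 0, 60.0, shape)   # nr=0: no-op
    assert pop.count == 700
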