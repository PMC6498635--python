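"""Behavioural rules of the agents: the event handlers.

Births, deaths, repertoire selection, the three interaction-and-division
regimes (weak / intermediate / strong), danger-signal and interleukin
mechanics, antibody production and killing, and infection injection.

Model switches
--------------
The self-centered **ERS** model and the conventional **CRS** model differ by
exactly four parameters: ``medrepr`` and ``weakrepr`` enable intermediate and
weak divisions, ``comptype`` selects the thymic selection regime (0: positive
selection of regulatory clones into characteristic rings around self-peptide
mirrors plus negative selection of the strongly self-reactive; 1: negative
selection of everything up to the ring's outer edge, no regulatory cells),
and ``tauthm`` compensates the resulting thymic output difference (5 vs 30).

Interaction success is affinity weighted: a receptor within the hard action
radius of a ligand's mirror image succeeds with probability
``(1 - d/(r+1))**alpha`` so that proximity in shape space acts as affinity —
perfectly complementary pairs always interact, marginal ones rarely do.
This graded weight is what lets affinity maturation select improved mutants
and what makes B cells born at a self mirror (possible only when negative
selection is off) pathologically efficient at destroying self.
"""

from __future__ import annotations

from .agents import ACTIVATED, MEMORY, NAIVE, PLASMA, STRONG, BCell, ThCell
from .shape_space import ShapePoint, affinity_weight, random_offset, random_shape

# outcome thresholds: a pathogen population counts as eliminated when its
# size drops under ELIMINATION_THRESHOLD; the host dies when it reaches
# DEATH_THRESHOLD.
ELIMINATION_THRESHOLD = 50
DEATH_THRESHOLD = 4000

KEEP = "keep"
DELETE = "delete"

WEAK = "weak"
INTERMEDIATE = "intermediate"
STRONG_KIND = "strong"


class RuleViolation(RuntimeError):
    """A division kind was requested that the model configuration disables."""


# ---------------------------------------------------------------------------
# repertoire selection
# ---------------------------------------------------------------------------

def b_negative_selection(bcr: ShapePoint, self_mirrors, radius: int) -> str:
    """Central tolerance of B cells in the bone marrow.

    A candidate whose BCR falls strictly inside the l-infinity ball of
    ``radius`` around the mirror image of any self antigen is deleted; the
    surviving repertoire therefore shows empty domains around self mirrors.
    """
    bx, by = bcr
    for mx, my in self_mirrors:
        dx = bx - mx
        if dx < 0:
            dx = -dx
        dy = by - my
        if dy < 0:
            dy = -dy
        if (dx if dx > dy else dy) < radius:
            return DELETE
    return KEEP


def th_thymic_selection(tcr: ShapePoint, self_peptide_mirrors, *, comptype: int,
                        ring_inner: int, ring_outer: int) -> tuple[str, bool, int]:
    """Thymic positive and negative selection of a candidate Th cell.

    Let ``d*`` be the distance of the TCR to the nearest self-peptide mirror.
    ERS (``comptype=0``): ``d* < ring_inner`` deletes; ``ring_inner <= d* <=
    ring_outer`` keeps the cell as a *regulatory* clone of that self peptide's
    characteristic ring; ``d* > ring_outer`` keeps a conventional
    (potentially infection-specific) cell.  CRS (``comptype=1``): everything
    with ``d* <= ring_outer`` is deleted — moderately self-reactive cells are
    purged, no regulatory compartment exists.

    Returns ``(decision, regulatory, ring_index)``.
    """
    tx, ty = tcr
    best = None
    ring = -1
    for i, (mx, my) in enumerate(self_peptide_mirrors):
        dx = tx - mx
        if dx < 0:
            dx = -dx
        dy = ty - my
        if dy < 0:
            dy = -dy
        d = dx if dx > dy else dy
        if best is None or d < best:
            best = d
            ring = i
    if best is None:  # no self peptides: everything survives, never regulatory
        return KEEP, False, -1
    if comptype == 1:
        if best <= ring_outer:
            return DELETE, False, -1
        return KEEP, False, -1
    if best < ring_inner:
        return DELETE, False, -1
    if best <= ring_outer:
        return KEEP, True, ring
    return KEEP, False, -1


# ---------------------------------------------------------------------------
# births
# ---------------------------------------------------------------------------

def marrow_birth_b(sim, _agent) -> None:
    """The bone marrow creates a naive B cell with a uniformly random BCR,
    which then faces negative selection against the self mirrors."""
    if sim.marrow.count <= 0:
        return
    bcr = random_shape(sim.rng, sim.antigen_lattice)
    if sim.c.negsel_on and b_negative_selection(
            bcr, sim.self_mirrors, sim.c.b_negsel_radius) == DELETE:
        sim.negsel_deleted_b += 1
        return
    cell = BCell(bcr)
    cell.last_contact = sim.clock.t
    sim.add_b(cell)


def marrow_birth_th(sim, _agent) -> None:
    """The bone marrow creates a Th cell with a uniformly random TCR, which
    then faces thymic selection."""
    if sim.marrow.count <= 0:
        return
    tcr = random_shape(sim.rng, sim.peptide_lattice)
    decision, regulatory, ring = th_thymic_selection(
        tcr, sim.self_mirrors, comptype=sim.c.comptype,
        ring_inner=sim.c.ring_inner, ring_outer=sim.c.thrad)
    if decision == DELETE:
        sim.thymus_deleted_th += 1
        return
    sim.add_th(ThCell(tcr, regulatory, ring))


# ---------------------------------------------------------------------------
# divisions
# ---------------------------------------------------------------------------

def division(sim, cell, kind: str):
    """Create one offspring of ``cell`` by a division of the given kind.

    Weak divisions (ERS homeostasis) and intermediate divisions (ERS
    polyclonal first line) must be enabled by ``weakrepr``/``medrepr``.
    B offspring mutate their BCR with probability ``pmut`` by a uniform
    l-infinity offset of magnitude in ``[rmin, round(rmin/cr)]`` (weak
    divisions use the spread parameters, maturation divisions the ``new``
    ones); strong B offspring become memory cells with probability ``pmem``.
    A parent B cell completing ``plasma_after`` strong divisions
    differentiates into an antibody-producing plasma cell.
    """
    cfg = sim.c
    if kind == WEAK and not cfg.weakrepr:
        raise RuleViolation("weak divisions are disabled (weakrepr=0)")
    if kind == INTERMEDIATE and not cfg.medrepr:
        raise RuleViolation("intermediate divisions are disabled (medrepr=0)")
    if isinstance(cell, ThCell):
        return _th_division(sim, cell, kind)
    return _b_division(sim, cell, kind)


def _b_division(sim, cell: BCell, kind: str) -> BCell:
    cfg = sim.c
    rng = sim.rng
    counters = sim.counters
    bcr = cell.bcr
    if cfg.pmut > 0.0 and rng.random() < cfg.pmut:
        if kind == WEAK:
            rmin, cr = cfg.rminsprd, cfg.crspread
        else:
            rmin, cr = cfg.rminnew, cfg.crnew
        hi = round(rmin / cr)
        mag = rng.randint(rmin, hi) if hi > rmin else rmin
        ox, oy = random_offset(rng, mag)
        bcr = sim.antigen_lattice.clamp(bcr[0] + ox, bcr[1] + oy)
    child = BCell(bcr)
    child.last_contact = sim.clock.t
    if kind == WEAK:
        counters.weak_B += 1
        child.state = NAIVE
    elif kind == INTERMEDIATE:
        counters.intermediate_B += 1
        child.state = ACTIVATED
    else:
        counters.strong_B += 1
        child.state = (MEMORY if rng.random() < cfg.pmem * sim.throttle_memory()
                       else STRONG)
    sim.add_b(child)
    if kind == STRONG_KIND and cell.state == STRONG:
        cell.strong_streak += 1
        if cell.strong_streak >= cfg.plasma_after:
            sim.to_plasma(cell)
    return child


def _th_division(sim, cell: ThCell, kind: str) -> ThCell:
    counters = sim.counters
    child = ThCell(cell.tcr, cell.regulatory, cell.ring)
    if kind == WEAK:
        counters.weak_T += 1
        child.state = NAIVE
    elif kind == INTERMEDIATE:
        counters.intermediate_T += 1
        child.state = ACTIVATED
    else:
        counters.strong_T += 1
        child.state = STRONG
    sim.add_th(child)
    return child


# ---------------------------------------------------------------------------
# B cell action and activation control
# ---------------------------------------------------------------------------

def _b_housekeeping(sim, cell: BCell, now: float) -> bool:
    """Presentation decay and blast contraction (both models).

    Returns False if the cell died (an unstimulated blast contracted).
    """
    cfg = sim.c
    if cell.presented is not None and now - cell.presented_at > cfg.pres_life:
        sim.pres_remove(cell)
        cell.presented = None
        cell.presented_self = -1
    if cell.presented is None:
        if cell.state == ACTIVATED:
            cell.state = NAIVE  # the alarm settles once nothing is presented
        elif cell.state == STRONG and now - cell.presented_at > cfg.pres_life:
            # blast contraction: a strongly activated cell that finds no
            # antigen within the presentation lifetime dies; the clone
            # persists only through its memory offspring (and plasma cells)
            sim.remove_b(cell)
            return False
    return True


def b_action(sim, cell: BCell) -> None:
    """Detection / killing / antigen presentation, and the division dispatch.

    The cell picks an antigen-bearing population with probability
    proportional to its size.  If the BCR lies within the action radius of
    the antigen's mirror, the interaction succeeds with the graded affinity
    weight: one antigen is engulfed (killed) and its peptide is presented in
    MHCII.  A successful engulfment then dispatches a division according to
    the cell's state: weak (naive, presenting self), intermediate
    (activated), or strong (strongly activated / memory recall).
    """
    if not _b_housekeeping(sim, cell, sim.clock.t):
        return
    if cell.state == STRONG:
        # an activated blast homes to the infection site: it samples foreign
        # antigen only (and stands down once the pathogen is gone)
        pop = sim.pick_foreign_pop()
    else:
        pop = sim.pick_antigen_pop()
    if pop is None:
        return
    cfg = sim.c
    rng = sim.rng
    bx, by = cell.bcr
    sx, sy = pop.shape
    # distance to the mirror image (sx, -sy) of the antigen
    dx = bx - sx
    if dx < 0:
        dx = -dx
    dy = by + sy
    if dy < 0:
        dy = -dy
    d = dx if dx > dy else dy
    r0 = cfg.r0
    if d > r0 or pop.count <= 0:
        return
    if rng.random() >= affinity_weight(d, r0, cfg.alpha_affinity):
        return
    # engulf one antigen: this is the B-cell side kill
    sim.pop_delta(pop, -1)
    is_self = pop.kind == "self"
    sim.pres_remove(cell)
    cell.presented = pop.shape
    cell.presented_self = sim.self_index[id(pop)] if is_self else -1
    cell.presented_at = sim.clock.t
    sim.pres_add(cell)
    if not is_self and cell.state == MEMORY:
        # memory recall: re-activation without the critical waiting period
        # (each antigen contact re-activates with probability memory_recall_p)
        if rng.random() < cfg.memory_recall_p:
            sim.set_b_strong(cell)
    if cell.state == NAIVE and d < cfg.auto_activation_radius:
        # BCR engagement above the central-tolerance affinity threshold is
        # activating on its own — such clones exist only when negative
        # selection is off (or, for foreign antigen, after maturation)
        cell.state = ACTIVATED
    st = cell.state
    if st == NAIVE:
        if is_self and cfg.weakrepr and rng.random() < cfg.pweak * sim.throttle_b():
            division(sim, cell, WEAK)
    elif st == ACTIVATED:
        if cfg.medrepr and rng.random() < sim.throttle_b():
            division(sim, cell, INTERMEDIATE)
    elif st == STRONG:
        if rng.random() < sim.throttle_b_strong():
            division(sim, cell, STRONG_KIND)


def b_activation_control(sim, cell: BCell) -> None:
    """The homeostatic control loop of a presenting B cell (ERS only).

    A B cell presenting a self peptide is visited by a complementary
    regulatory Th cell of that peptide's characteristic ring: the contact
    refreshes the survival clock of both (and occasionally triggers a weak
    homeostatic division of the regulatory clone).  A foreign peptide blocks
    regulatory docking; once the cell has gone unattended longer than the
    critical period ``tcrit_stress`` it becomes activated and secretes
    danger signals.  Presentation itself decays after ``pres_life`` steps.
    """
    now = sim.clock.t
    cfg = sim.c
    if not _b_housekeeping(sim, cell, now):
        return
    if cell.presented is None or cell.state == MEMORY:
        return
    if cell.presented_self >= 0:
        # self peptide: a regulatory clone of its characteristic ring docks
        ring = sim.ring_members[cell.presented_self]
        if ring:
            rng = sim.rng
            threg = ring[rng.randrange(len(ring))] if len(ring) > 1 else ring[0]
            cell.last_contact = now
            sim.refresh_threg(threg)
            if cfg.weakrepr and rng.random() < cfg.pweak_t * sim.throttle_th():
                division(sim, threg, WEAK)
            return
        if any(sim.ring_members):
            # a transient local miss while other rings stand is tolerated;
            # only total collapse of the regulatory compartment (a
            # pathological state) lets self presenters run the stress clock
            return
    # foreign peptide (or an unguarded self peptide): no regulatory contact;
    # the cell is in emergency once unattended longer than the critical
    # period.  Only foreign presentation triggers danger-signal secretion —
    # an orphaned self presenter activates but raises no systemic alarm.
    if now - cell.last_contact > cfg.tcrit_stress:
        if cell.state == NAIVE:
            cell.state = ACTIVATED
        if cfg.danger_burst and cell.presented_self < 0:
            sim.pool_delta(sim.danger, cfg.danger_burst)


# ---------------------------------------------------------------------------
# Th cell action
# ---------------------------------------------------------------------------

def th_action(sim, cell: ThCell) -> None:
    """Detection by a Th cell: inspect the MHCII of a random presenting B cell.

    Danger-signal chemotaxis concentrates Th surveillance on cells that are
    actually presenting, so the inspected cell is drawn uniformly from the
    presenting registry.  A regulatory cell recognising a presented *self*
    peptide refreshes the homeostatic contact.  Any Th cell recognising a
    presented *foreign* peptide within ``thrad`` delivers the second signal:
    both partners become strongly activated and the Th clone expands.
    """
    nf = len(sim.pres_foreign)
    ns = len(sim.pres_self)
    if nf == 0 and ns == 0:
        return
    rng = sim.rng
    # while danger signals are in the air they attract Th cells to the
    # foreign presenters (chemotaxis weight 4); without them — in the CRS
    # model always — surveillance is unbiased
    wf = (4 if sim.danger.count else 1) * nf
    if rng.random() * (wf + ns) < wf:
        bl = sim.pres_foreign
        b = bl[rng.randrange(nf)] if nf > 1 else bl[0]
    else:
        bl = sim.pres_self
        b = bl[rng.randrange(ns)] if ns > 1 else bl[0]
    p = b.presented
    cfg = sim.c
    tx, ty = cell.tcr
    dx = tx - p[0]
    if dx < 0:
        dx = -dx
    dy = ty + p[1]
    if dy < 0:
        dy = -dy
    d = dx if dx > dy else dy
    if d > cfg.thrad:
        return
    if b.presented_self >= 0:
        if cell.regulatory:
            b.last_contact = sim.clock.t
            sim.refresh_threg(cell)
        return
    # foreign peptide: the two-signal contact strongly activates both partners
    was_strong = b.state == STRONG
    sim.set_b_strong(b)
    sim.set_th_strong(cell)
    # T-cell help drives B blast proliferation directly (with mutation, so
    # affinity maturation can bootstrap from a low-affinity founder); repeat
    # help to an already committed blast is much less proliferative
    help_p = 0.1 if was_strong else 1.0
    if rng.random() < help_p * sim.throttle_b_strong():
        division(sim, b, STRONG_KIND)
    # ... and expands the helping Th clone
    if rng.random() < 0.5 * sim.throttle_th_strong():
        division(sim, cell, STRONG_KIND)


# ---------------------------------------------------------------------------
# danger signals and interleukins (ERS only)
# ---------------------------------------------------------------------------

def danger_action(sim, _agent) -> None:
    """One danger molecule acts: a uniformly random Th cell is alerted.

    The target starts intermediate-kind division and secretes interleukins;
    with no Th cells around the signal simply dissipates.
    """
    sim.pool_delta(sim.danger, -1)
    tl = sim.th_cells
    if not tl:
        return
    rng = sim.rng
    th = tl[rng.randrange(len(tl))] if len(tl) > 1 else tl[0]
    if th.state == NAIVE:
        th.state = ACTIVATED
    cfg = sim.c
    if cfg.il_burst:
        sim.pool_delta(sim.interleukin, cfg.il_burst)
    if cfg.medrepr and rng.random() < sim.throttle_th():
        division(sim, th, INTERMEDIATE)


def danger_death(sim, _agent) -> None:
    sim.pool_delta(sim.danger, -1)


def interleukin_action(sim, _agent) -> None:
    """One interleukin acts: a uniformly random B cell is signalled.

    Only a cell that has lost complementary regulatory control (activated
    state) responds, with an intermediate-kind division.
    """
    sim.pool_delta(sim.interleukin, -1)
    bl = sim.b_cells
    if not bl:
        return
    rng = sim.rng
    b = bl[rng.randrange(len(bl))] if len(bl) > 1 else bl[0]
    if b.state == ACTIVATED and sim.c.medrepr and rng.random() < sim.throttle_b():
        division(sim, b, INTERMEDIATE)


def interleukin_death(sim, _agent) -> None:
    sim.pool_delta(sim.interleukin, -1)


# ---------------------------------------------------------------------------
# antibodies
# ---------------------------------------------------------------------------

def plasma_production(sim, cell: BCell) -> None:
    """A plasma cell creates a batch of antibodies of its own BCR shape."""
    pool = sim.antibody_pool(cell.bcr)
    sim.pool_delta(pool, sim.c.ab_burst)


def antibody_action(sim, pool) -> None:
    """An amount of antibodies acts: binds a random antigen population and
    kills up to ``ab_kill`` of it (affinity weighted within ``ab_radius``);
    the acting amount is consumed."""
    sim.pool_delta(pool, -1)
    target = sim.pick_antigen_pop()
    if target is None or target.count <= 0:
        return
    cfg = sim.c
    px, py = pool.shape
    sx, sy = target.shape
    dx = px - sx
    if dx < 0:
        dx = -dx
    dy = py + sy
    if dy < 0:
        dy = -dy
    d = dx if dx > dy else dy
    if d > cfg.ab_radius:
        return
    if sim.rng.random() >= affinity_weight(d, cfg.ab_radius, cfg.alpha_affinity):
        return
    kill = cfg.ab_kill
    if kill > target.count:
        kill = target.count
    sim.pop_delta(target, -kill)


def antibody_death(sim, pool) -> None:
    sim.pool_delta(pool, -1)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def self_division(sim, pop) -> None:
    sim.pop_delta(pop, +1)


def foreign_division(sim, pop) -> None:
    sim.pop_delta(pop, +1)


def marrow_division(sim, pop) -> None:
    sim.pop_delta(pop, +1)


def infection_inject(sim, t: float, nr: int, tr: float,
                     shape: ShapePoint) -> None:
    """Inject a pathogen population: ``nr`` cells of the given shape with
    mean division wait ``tr``.  Re-injecting an existing shape merges counts
    (and records a fresh injection time for outcome classification)."""
    if nr <= 0:
        return
    for pop in sim.foreign_pops:
        if pop.shape == shape:
            pop.injections.append(t)
            pop.trace.append((t, pop.count))
            sim.pop_delta(pop, nr, birth=True)
            return
    sim.add_foreign(shape, nr, tr, t)


def b_death(sim, cell: BCell) -> None:
    sim.remove_b(cell)


def th_death(sim, cell: ThCell) -> None:
    sim.remove_th(cell)


def plasma_death(sim, cell: BCell) -> None:
    sim.remove_plasma(cell)


#: event-type -> handler dispatch used by the simulation loop
HANDLERS = {
    "b_action": b_action,
    "b_control": b_activation_control,
    "b_death": b_death,
    "th_action": th_action,
    "th_death": th_death,
    "plasma_prod": plasma_production,
    "plasma_death": plasma_death,
    "self_div": self_division,
    "foreign_div": foreign_division,
    "marrow_div": marrow_division,
    "b_birth": marrow_birth_b,
    "th_birth": marrow_birth_th,
    "danger_action": danger_action,
    "danger_death": danger_death,
    "il_action": interleukin_action,
    "il_death": interleukin_death,
    "ab_action": antibody_action,
    "ab_death": antibody_death,
}
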