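"""The simulation state and run loop.

A :class:`Simulation` wires the stochastic event engine to the immune rule
handlers: it builds the initial world from a :class:`~.config_io.ParameterSet`
(three non-immune self populations, a bone marrow population, empty immune
compartments), schedules the recurring events, and then advances the
exponential waiting-time race until the horizon, an injected infection is
resolved, or the host dies.

Time is measured in steps of one tenth of a day.  B and Th cells first
enter circulation at ``start_step`` (day 10 by default).  The census and the
cumulative division counters are recorded every ``record_every`` steps.
"""

from __future__ import annotations

import random
from types import SimpleNamespace
from typing import Callable

from .agents import (CENSUS_FIELDS, MEMORY, PLASMA, STRONG, BCell,
                     DivisionCounters, Population, ThCell, census)
from .config_io import ParameterSet, parse_params
from .engine import EventQueue, QueueEmpty, SimClock, logistic_throttle
from .immune_rules import (DEATH_THRESHOLD, ELIMINATION_THRESHOLD, HANDLERS,
                           infection_inject)
from .shape_space import Lattice, ShapePoint, mirror


class Simulation:
    """One stochastic run of the humoral immune model."""

    def __init__(self, params: ParameterSet | str | None = None,
                 seed: int | None = None) -> None:
        if params is None:
            params = ParameterSet()
        elif isinstance(params, str):
            params = parse_params(params)
        self.cfg = params
        # flat attribute cache of the scalar parameters (hot-path access)
        self.c = SimpleNamespace(**params.values)
        self.seed = params.seed if seed is None else seed
        self.rng = random.Random(self.seed)
        self.clock = SimClock(0.0, params.t_max)
        self.queue = EventQueue()
        self.peptide_lattice = Lattice(1000, "peptide")
        self.antigen_lattice = Lattice(1000, "antigen")
        self.counters = DivisionCounters()

        # individually tracked cells
        self.b_cells: list[BCell] = []
        self.plasma_cells: list[BCell] = []
        self.th_cells: list[ThCell] = []
        # B cells with a loaded MHCII, split by the origin of the peptide;
        # Th surveillance preferentially inspects foreign presenters
        # (stressed cells attract Th cells via danger-signal chemotaxis)
        self.pres_self: list[BCell] = []
        self.pres_foreign: list[BCell] = []
        self.n_b = 0   # every B cell state, plasma and memory included
        self.n_th = 0
        self.n_memory = 0

        # counted populations
        self.self_pops: list[Population] = []
        self.self_index: dict[int, int] = {}
        self.self_mirrors: list[ShapePoint] = []
        for x, y, count in params.self_pops:
            pop = Population("self", ShapePoint(x, y), count,
                             params.self_tau, params.self_capacity)
            pop.eids.append(self.queue.schedule_rate(
                "self_div", pop, self._self_rate(pop)))
            self.self_index[id(pop)] = len(self.self_pops)
            self.self_pops.append(pop)
            self.self_mirrors.append(mirror(pop.shape))
        self.ring_members: list[list[ThCell]] = [[] for _ in self.self_pops]

        self.foreign_pops: list[Population] = []
        self.marrow = Population("marrow", None, params.marrow_init,
                                 params.marrow_tau, params.marrow_capacity)
        self.marrow.eids.append(self.queue.schedule_rate(
            "marrow_div", self.marrow, self._marrow_rate()))
        self.danger = Population("danger", None, 0)
        self.danger.eids.append(self.queue.schedule_rate("danger_action", self.danger, 0.0))
        self.danger.eids.append(self.queue.schedule_rate("danger_death", self.danger, 0.0))
        self.interleukin = Population("interleukin", None, 0)
        self.interleukin.eids.append(self.queue.schedule_rate("il_action", self.interleukin, 0.0))
        self.interleukin.eids.append(self.queue.schedule_rate("il_death", self.interleukin, 0.0))
        self.antibody_pops: dict[ShapePoint, Population] = {}

        # marrow output of B and Th cells (gated until start_step)
        self._eid_b_birth = self.queue.schedule_rate("b_birth", None, 0.0)
        self._eid_th_birth = self.queue.schedule_rate("th_birth", None, 0.0)

        # bookkeeping
        self.negsel_deleted_b = 0
        self.thymus_deleted_th = 0
        self.host_dead = False
        self.death_time: float | None = None
        self.n_events = 0
        self.records: list[tuple] = []
        self._next_record = 0.0

        # deterministic milestones: circulation start and scheduled infections
        self._milestones: list[tuple[float, str, tuple]] = [
            (params.start_step, "start", ())]
        for t, nr, tr, x, y in params.infections:
            self._milestones.append((t, "infect", (nr, tr, ShapePoint(x, y))))
        self._milestones.sort(key=lambda m: m[0])

    # ------------------------------------------------------------------ rates

    def _self_rate(self, pop: Population) -> float:
        return logistic_throttle(pop.count, pop.capacity,
                                 pop.count / pop.division_mean_wait)

    def _foreign_rate(self, pop: Population) -> float:
        return logistic_throttle(pop.count, pop.capacity,
                                 pop.count / pop.division_mean_wait)

    def _marrow_rate(self) -> float:
        return logistic_throttle(self.marrow.count, self.marrow.capacity,
                                 self.marrow.count / self.marrow.division_mean_wait)

    def throttle_b(self) -> float:
        frac = 1.0 - self.n_b / self.c.b_capacity
        return frac if frac > 0.0 else 0.0

    def throttle_th(self) -> float:
        frac = 1.0 - self.n_th / self.c.th_capacity
        return frac if frac > 0.0 else 0.0

    def throttle_memory(self) -> float:
        """Memory-niche competition: formation throttles at the niche size."""
        frac = 1.0 - self.n_memory / self.c.memory_capacity
        return frac if frac > 0.0 else 0.0

    def throttle_b_strong(self) -> float:
        """Strong clonal expansion has its own (higher) carrying capacity."""
        frac = 1.0 - self.n_b / self.c.b_strong_capacity
        return frac if frac > 0.0 else 0.0

    def throttle_th_strong(self) -> float:
        frac = 1.0 - self.n_th / self.c.th_strong_capacity
        return frac if frac > 0.0 else 0.0

    def _refresh_birth_rates(self) -> None:
        cfg = self.c
        if self.clock.t < cfg.start_step or self.marrow.count <= 0:
            self.queue.set_rate(self._eid_b_birth, 0.0)
            self.queue.set_rate(self._eid_th_birth, 0.0)
            return
        self.queue.set_rate(self._eid_b_birth,
                            logistic_throttle(self.n_b, cfg.b_capacity, 1.0 / cfg.taubm))
        self.queue.set_rate(self._eid_th_birth,
                            logistic_throttle(self.n_th, cfg.th_capacity, 1.0 / cfg.tauthm))

    # --------------------------------------------------------- agent registry

    def add_b(self, cell: BCell) -> None:
        cfg = self.c
        if cell.presented is None:
            cell.presented_at = self.clock.t  # grace period for fresh blasts
        cell.idx = len(self.b_cells)
        self.b_cells.append(cell)
        self.n_b += 1
        q = self.queue
        taub = cfg.taub_strong if cell.state == STRONG else cfg.taub0
        cell.eids.append(q.schedule("b_action", cell, taub))
        if cfg.comptype == 0:
            cell.eids.append(q.schedule("b_control", cell, cfg.tauctrl))
        if cell.state == MEMORY:
            self.n_memory += 1
            life = cfg.memory_life
        else:
            life = cfg.b_life
        cell.eids.append(q.schedule("b_death", cell, life))
        self._refresh_birth_rates()

    def set_b_strong(self, cell: BCell) -> None:
        """Strong activation of a B cell: the blast cycles its actions much
        faster (``taub_strong``) until terminal differentiation or death."""
        if cell.state in (STRONG, PLASMA):
            return
        if cell.state == MEMORY:
            self.n_memory -= 1
        cell.state = STRONG
        q = self.queue
        q.cancel(cell.eids[0])
        cell.eids[0] = q.schedule("b_action", cell, self.c.taub_strong)

    def pres_add(self, cell: BCell) -> None:
        """(Re)register a presenting cell under the right peptide origin."""
        if cell.pres_idx >= 0:
            self.pres_remove(cell)
        lst = self.pres_self if cell.presented_self >= 0 else self.pres_foreign
        cell.pres_idx = len(lst)
        lst.append(cell)

    def pres_remove(self, cell: BCell) -> None:
        if cell.pres_idx >= 0:
            lst = self.pres_self if cell.presented_self >= 0 else self.pres_foreign
            last = lst[-1]
            lst[cell.pres_idx] = last
            last.pres_idx = cell.pres_idx
            lst.pop()
            cell.pres_idx = -1

    def remove_b(self, cell: BCell) -> None:
        if cell.state == MEMORY:
            self.n_memory -= 1
        self.pres_remove(cell)
        self.queue.cancel_agent(cell)
        cell.eids.clear()
        lst = self.b_cells
        last = lst[-1]
        lst[cell.idx] = last
        last.idx = cell.idx
        lst.pop()
        cell.idx = -1
        self.n_b -= 1
        self._refresh_birth_rates()

    def to_plasma(self, cell: BCell) -> None:
        """Terminal differentiation: the cell stops acting and being
        controlled, and starts producing antibodies of its BCR shape."""
        self.pres_remove(cell)
        q = self.queue
        q.cancel_agent(cell)
        cell.eids.clear()
        lst = self.b_cells
        last = lst[-1]
        lst[cell.idx] = last
        last.idx = cell.idx
        lst.pop()
        cell.state = PLASMA
        cell.presented = None
        cell.idx = len(self.plasma_cells)
        self.plasma_cells.append(cell)
        cfg = self.c
        cell.eids.append(q.schedule("plasma_prod", cell, cfg.ab_prod_tau))
        cell.eids.append(q.schedule("plasma_death", cell, cfg.plasma_life))

    def remove_plasma(self, cell: BCell) -> None:
        self.queue.cancel_agent(cell)
        cell.eids.clear()
        lst = self.plasma_cells
        last = lst[-1]
        lst[cell.idx] = last
        last.idx = cell.idx
        lst.pop()
        cell.idx = -1
        self.n_b -= 1
        self._refresh_birth_rates()

    def add_th(self, cell: ThCell) -> None:
        cfg = self.c
        cell.idx = len(self.th_cells)
        self.th_cells.append(cell)
        self.n_th += 1
        q = self.queue
        cell.eids.append(q.schedule("th_action", cell, cfg.tauth0))
        life = cfg.th_strong_life if cell.state == STRONG else cfg.th_life
        cell.eids.append(q.schedule("th_death", cell, life))
        if cell.regulatory and cell.ring >= 0:
            ring = self.ring_members[cell.ring]
            cell.ring_idx = len(ring)
            ring.append(cell)
        self._refresh_birth_rates()

    def remove_th(self, cell: ThCell) -> None:
        self.queue.cancel_agent(cell)
        cell.eids.clear()
        lst = self.th_cells
        last = lst[-1]
        lst[cell.idx] = last
        last.idx = cell.idx
        lst.pop()
        cell.idx = -1
        if cell.regulatory and cell.ring >= 0 and cell.ring_idx >= 0:
            ring = self.ring_members[cell.ring]
            last_r = ring[-1]
            ring[cell.ring_idx] = last_r
            last_r.ring_idx = cell.ring_idx
            ring.pop()
            cell.ring_idx = -1
        self.n_th -= 1
        self._refresh_birth_rates()

    def set_th_strong(self, cell: ThCell) -> None:
        """Strong activation of a Th cell: the effector is shorter-lived
        than a naive cell (clonal contraction after the response)."""
        if cell.state == STRONG:
            return
        cell.state = STRONG
        q = self.queue
        q.cancel(cell.eids[1])
        cell.eids[1] = q.schedule("th_death", cell, self.c.th_strong_life)

    def refresh_threg(self, threg: ThCell) -> None:
        """Hook for the mutual-survival contact; clone persistence is carried
        by the weak homeostatic divisions, so this only marks activity."""
        return None

    # ----------------------------------------------------------- populations

    def pick_antigen_pop(self) -> Population | None:
        """A random antigen-bearing population, weighted by its size."""
        total = 0
        for p in self.self_pops:
            total += p.count
        for p in self.foreign_pops:
            total += p.count
        if total <= 0:
            return None
        u = self.rng.random() * total
        for p in self.self_pops:
            if u < p.count:
                return p
            u -= p.count
        for p in self.foreign_pops:
            if u < p.count:
                return p
            u -= p.count
        return self.foreign_pops[-1] if self.foreign_pops else self.self_pops[-1]

    def pick_foreign_pop(self) -> Population | None:
        """A random foreign population, weighted by its size."""
        pops = self.foreign_pops
        if not pops:
            return None
        if len(pops) == 1:
            return pops[0] if pops[0].count > 0 else None
        total = 0
        for p in pops:
            total += p.count
        if total <= 0:
            return None
        u = self.rng.random() * total
        for p in pops:
            if u < p.count:
                return p
            u -= p.count
        return pops[-1]

    def pop_delta(self, pop: Population, delta: int, birth: bool | None = None) -> None:
        """Apply a count change to a self/foreign population, updating its
        division rate, birth/death tallies, outcome trace and thresholds."""
        old = pop.count
        new = old + delta
        if new < 0:
            raise RuntimeError(f"population {pop.kind} went negative")
        pop.count = new
        if delta > 0 if birth is None else birth:
            pop.births += delta
        else:
            pop.deaths -= delta
        self.queue.set_rate(pop.eids[0], self._foreign_rate(pop)
                            if pop.kind == "foreign" else self._self_rate(pop))
        if pop.kind == "foreign":
            t = self.clock.t
            if (old < ELIMINATION_THRESHOLD) != (new < ELIMINATION_THRESHOLD) or new == 0:
                pop.trace.append((t, new))
            if new >= DEATH_THRESHOLD and old < DEATH_THRESHOLD:
                pop.trace.append((t, new))
                if not self.host_dead:
                    self.host_dead = True
                    self.death_time = t

    def pool_delta(self, pool: Population, delta: int) -> None:
        """Apply a count change to a shapeless pool or antibody population."""
        new = pool.count + delta
        if new < 0:
            raise RuntimeError(f"pool {pool.kind} went negative")
        pool.count = new
        if delta > 0:
            pool.births += delta
        else:
            pool.deaths -= delta
        q = self.queue
        kind = pool.kind
        if kind == "danger":
            cfg = self.c
            q.set_rate(pool.eids[0], new / cfg.danger_action_tau)
            q.set_rate(pool.eids[1], new / cfg.danger_decay_tau)
        elif kind == "interleukin":
            cfg = self.c
            q.set_rate(pool.eids[0], new / cfg.il_action_tau)
            q.set_rate(pool.eids[1], new / cfg.il_decay_tau)
        else:  # antibody
            cfg = self.c
            q.set_rate(pool.eids[0], new / cfg.ab_action_tau)
            q.set_rate(pool.eids[1], new / cfg.ab_decay_tau)

    def antibody_pool(self, shape: ShapePoint) -> Population:
        pool = self.antibody_pops.get(shape)
        if pool is None:
            pool = Population("antibody", shape, 0)
            pool.eids.append(self.queue.schedule_rate("ab_action", pool, 0.0))
            pool.eids.append(self.queue.schedule_rate("ab_death", pool, 0.0))
            self.antibody_pops[shape] = pool
        return pool

    def add_foreign(self, shape: ShapePoint, nr: int, tr: float, t: float) -> Population:
        pop = Population("foreign", shape, nr, tr, self.cfg.foreign_capacity)
        pop.injections.append(t)
        pop.trace.append((t, nr))
        pop.eids.append(self.queue.schedule_rate(
            "foreign_div", pop, self._foreign_rate(pop)))
        self.foreign_pops.append(pop)
        return pop

    @property
    def pending_infections(self) -> int:
        """Scheduled infections that have not been injected yet."""
        return sum(1 for m in self._milestones if m[1] == "infect")

    def inject(self, t: float, nr: int | None = None, tr: float | None = None,
               shape: ShapePoint | None = None) -> None:
        """Schedule an infection at time ``t`` (defaults from the parameter
        set: ``nr`` cells, division wait ``tr``, the default foreign shape)."""
        cfg = self.cfg
        entry = (t, "infect", (cfg.nr if nr is None else nr,
                               cfg.tr if tr is None else tr,
                               shape if shape is not None
                               else ShapePoint(cfg.foreign_x, cfg.foreign_y)))
        self._milestones.append(entry)
        self._milestones.sort(key=lambda m: m[0])

    # ------------------------------------------------------------------- run

    def run(self, t_max: float | None = None,
            stop_when: Callable[["Simulation"], bool] | None = None) -> "Simulation":
        """Advance the race until ``t_max`` (default: the configured horizon).

        ``stop_when`` is polled at recording boundaries; the run also stops
        as soon as the host dies (a pathogen reached the lethal threshold).
        Returns ``self`` for chaining.
        """
        cfg = self.cfg
        if t_max is None:
            t_max = cfg.t_max
        self.clock.t_max = t_max
        queue = self.queue
        clock = self.clock
        rng = self.rng
        handlers = HANDLERS
        stride = cfg.record_every
        milestones = self._milestones

        if not self.records and self._next_record == 0.0:
            self._record_row()
            self._next_record = stride

        while True:
            try:
                etype, agent, eid, dt = queue.draw(rng)
            except QueueEmpty:
                if milestones and milestones[0][0] <= t_max:
                    clock.t = milestones[0][0]
                    self._process_milestone(*milestones.pop(0))
                    continue
                while self._next_record <= t_max:
                    clock.t = self._next_record
                    self._record_row()
                    self._next_record += stride
                clock.t = t_max
                break
            t_new = clock.t + dt
            finished = t_new >= t_max
            if finished:
                t_new = t_max
            # interleave deterministic boundaries (milestones, recordings)
            stop = False
            while True:
                next_m = milestones[0][0] if milestones else float("inf")
                boundary = next_m if next_m < self._next_record else self._next_record
                if boundary > t_new:
                    break
                if boundary == next_m:
                    clock.t = next_m
                    self._process_milestone(*milestones.pop(0))
                else:
                    clock.t = self._next_record
                    self._record_row()
                    self._next_record += stride
                    if self.host_dead or (stop_when is not None and stop_when(self)):
                        stop = True
                        break
            if stop:
                break
            if finished:
                clock.t = t_max
                break
            clock.t = t_new
            handlers[etype](self, agent)
            self.n_events += 1
            if self.host_dead:
                break
        return self

    def _process_milestone(self, t: float, kind: str, payload: tuple) -> None:
        if kind == "start":
            self._refresh_birth_rates()
        elif kind == "infect":
            nr, tr, shape = payload
            infection_inject(self, t, nr, tr, shape)

    def _record_row(self) -> None:
        self.records.append((self.clock.t,) + census(self) + self.counters.as_tuple())

    # --------------------------------------------------------------- outputs

    def summary(self) -> dict:
        """Final census, outcome classification and run bookkeeping."""
        from .experiments import classify_outcome  # local import: no cycle at load
        out: dict = {"t_end": self.clock.t, "seed": self.seed,
                     "events": self.n_events,
                     "model": "crs" if self.cfg.comptype == 1 else "ers"}
        cen = census(self)
        out.update(dict(zip(CENSUS_FIELDS, cen)))
        for name, value in zip(("weak_T", "weak_B", "intermediate_T",
                                "intermediate_B", "strong_T", "strong_B"),
                               self.counters.as_tuple()):
            out[name] = value
        if self.foreign_pops:
            rec = self.outcome()
            out["win"] = int(rec.win)
            out["death_time"] = "" if rec.death_time is None else rec.death_time
            for i, e in enumerate(rec.elimination_times, start=1):
                out[f"elimination_time_{i}"] = "" if e is None else e
        return out

    def outcome(self):
        """Win/loss classification of this run (requires >= 1 infection)."""
        from .experiments import classify_outcome
        return classify_outcome(self)

    def snapshot_rows(self) -> list[tuple[str, int, int, int]]:
        """Shape-space snapshot: receptor and antigen positions with counts."""
        from collections import Counter
        rows: list[tuple[str, int, int, int]] = []
        tcr = Counter(c.tcr for c in self.th_cells)
        for (x, y), n in sorted(tcr.items()):
            rows.append(("TCR", x, y, n))
        bcr = Counter(c.bcr for c in self.b_cells)
        bcr.update(c.bcr for c in self.plasma_cells)
        for (x, y), n in sorted(bcr.items()):
            rows.append(("BCR", x, y, n))
        for p in self.self_pops:
            rows.append(("self", p.shape[0], p.shape[1], p.count))
        for p in self.foreign_pops:
            rows.append(("foreign", p.shape[0], p.shape[1], p.count))
        return rows
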