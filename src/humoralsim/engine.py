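"""Stochastic scheduled-event engine.

The simulation advances by an exponential waiting-time race over the dynamic
list of scheduled events: every pending event with expected waiting time
``tau`` competes with rate ``1/tau``; the next event to fire is chosen with
probability proportional to its rate and the clock advances by an exponential
draw with mean ``1/sum(rates)`` (the classic Gillespie construction, which is
the memoryless model consistent with parameterising events by their expected
waiting times).

For efficiency, events sharing an (event type, mean wait) pair are held in
*groups*: a group of k members contributes ``k/tau`` to the total rate and a
uniformly random member fires when the group wins the race.  Population-level
events (births, pool decays) whose rate depends on a count are singleton
groups with an explicitly managed rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log as _log
from typing import Any, NamedTuple


class QueueEmpty(Exception):
    """Raised when the race is drawn on a queue with no positive rate."""


class ScheduledEvent(NamedTuple):
    event_id: int
    event_type: str
    agent_ref: Any
    mean_wait: float


@dataclass
class SimClock:
    """Simulation clock; the unit of time is one step = a tenth of a day."""

    t: float = 0.0
    t_max: float = 5000.0

    def advance(self, dt: float) -> float:
        if dt < 0:
            raise ValueError("time cannot run backwards")
        self.t += dt
        return self.t


class _Group:
    __slots__ = ("etype", "rate", "members", "eids", "dynamic", "gt")

    def __init__(self, etype: str, rate: float, dynamic: bool) -> None:
        self.etype = etype
        self.rate = rate  # per-member rate (fixed groups) or full rate (dynamic)
        self.members: list[Any] = []
        self.eids: list[int] = []
        self.dynamic = dynamic
        self.gt = 0.0  # cached group total rate

    def total(self) -> float:
        if self.dynamic:
            return self.rate if self.members else 0.0
        return self.rate * len(self.members)


class EventQueue:
    """Dynamic list of scheduled events, organised into rate groups."""

    def __init__(self) -> None:
        self._groups: dict[tuple, _Group] = {}
        self._order: list[_Group] = []
        self._where: dict[int, tuple[_Group, int]] = {}
        self._by_agent: dict[int, list[int]] = {}
        self._agents: dict[int, Any] = {}
        self._next_id = 0
        self._total = 0.0  # incrementally maintained sum of group totals
        self._resync = 0

    # -- scheduling ---------------------------------------------------------

    def schedule(self, event_type: str, agent_ref: Any, mean_wait: float) -> int:
        """Add a recurring fixed-rate event; returns its id."""
        if not mean_wait > 0:
            raise ValueError(f"mean_wait must be positive, got {mean_wait}")
        key = (event_type, mean_wait)
        grp = self._groups.get(key)
        if grp is None:
            grp = _Group(event_type, 1.0 / mean_wait, dynamic=False)
            self._groups[key] = grp
            self._order.append(grp)
        return self._insert(grp, agent_ref)

    def schedule_rate(self, event_type: str, agent_ref: Any, rate: float) -> int:
        """Add a singleton event whose rate is managed explicitly (may be 0)."""
        if rate < 0:
            raise ValueError("rate must be nonnegative")
        grp = _Group(event_type, rate, dynamic=True)
        self._order.append(grp)
        return self._insert(grp, agent_ref)

    def _insert(self, grp: _Group, agent_ref: Any) -> int:
        eid = self._next_id
        self._next_id += 1
        self._where[eid] = (grp, len(grp.members))
        grp.members.append(agent_ref)
        grp.eids.append(eid)
        delta = grp.total() - grp.gt
        grp.gt += delta
        self._total += delta
        if agent_ref is not None:
            aid = id(agent_ref)
            self._by_agent.setdefault(aid, []).append(eid)
            self._agents[aid] = agent_ref
        return eid

    def set_rate(self, event_id: int, rate: float) -> None:
        grp, _ = self._where[event_id]
        if not grp.dynamic:
            raise ValueError("set_rate applies only to rate-managed events")
        grp.rate = rate
        delta = (rate if grp.members else 0.0) - grp.gt
        grp.gt += delta
        self._total += delta

    # -- cancellation -------------------------------------------------------

    def cancel(self, event_id: int) -> None:
        grp, idx = self._where.pop(event_id)
        last = len(grp.members) - 1
        new_total = (grp.rate if last else 0.0) if grp.dynamic else grp.rate * last
        delta = new_total - grp.gt
        grp.gt += delta
        self._total += delta
        agent = grp.members[idx]
        if idx != last:
            grp.members[idx] = grp.members[last]
            moved = grp.eids[idx] = grp.eids[last]
            self._where[moved] = (grp, idx)
        grp.members.pop()
        grp.eids.pop()
        if agent is not None:
            aid = id(agent)
            lst = self._by_agent.get(aid)
            if lst is not None:
                lst.remove(event_id)
                if not lst:
                    del self._by_agent[aid]
                    del self._agents[aid]

    def cancel_agent(self, agent_ref: Any) -> None:
        """Cancel every event owned by an agent (a dead agent never fires)."""
        for eid in list(self._by_agent.get(id(agent_ref), ())):
            self.cancel(eid)

    # -- the race -----------------------------------------------------------

    def total_rate(self) -> float:
        tot = 0.0
        for grp in self._order:
            if grp.dynamic:
                if grp.members:
                    tot += grp.rate
            else:
                tot += grp.rate * len(grp.members)
        return tot

    def draw(self, rng) -> tuple[str, Any, int, float]:
        """One race step: returns (event_type, agent_ref, event_id, dt)."""
        self._resync -= 1
        if self._resync <= 0:  # bound float drift of the incremental total
            self._resync = 16384
            total = 0.0
            for grp in self._order:
                grp.gt = grp.total()
                total += grp.gt
            self._total = total
        total = self._total
        if total <= 0.0:
            raise QueueEmpty
        dt = -_log(1.0 - rng.random()) / total
        u = rng.random() * total
        winner = None
        for grp in self._order:
            gt = grp.gt
            if u < gt:
                winner = grp
                break
            u -= gt
        if winner is None:  # float round-off at the far edge
            for grp in reversed(self._order):
                if grp.total() > 0.0:
                    winner = grp
                    break
        if winner is None:
            # only float residue was left in the incremental total
            self._total = 0.0
            raise QueueEmpty
        n = len(winner.members)
        idx = int(rng.random() * n) if n > 1 else 0
        if idx >= n:
            idx = n - 1
        return winner.etype, winner.members[idx], winner.eids[idx], dt

    def __len__(self) -> int:
        return len(self._where)

    def event(self, event_id: int) -> ScheduledEvent:
        grp, idx = self._where[event_id]
        mw = (1.0 / grp.rate) if grp.rate > 0 else float("inf")
        return ScheduledEvent(event_id, grp.etype, grp.members[idx], mw)


def schedule(queue: EventQueue, event_type: str, agent_ref: Any, mean_wait: float) -> int:
    """Module-level convenience wrapper around :meth:`EventQueue.schedule`."""
    return queue.schedule(event_type, agent_ref, mean_wait)


def draw_next(queue: EventQueue, rng, clock: SimClock) -> tuple[ScheduledEvent, float]:
    """Select the next event by the exponential race and advance the clock.

    Raises :class:`QueueEmpty` when nothing can fire — the simulation-end
    signal.
    """
    etype, agent, eid, dt = queue.draw(rng)
    new_time = clock.advance(dt)
    grp, idx = queue._where[eid]
    mw = (1.0 / grp.rate) if grp.rate > 0 else float("inf")
    return ScheduledEvent(eid, etype, agent, mw), new_time


def logistic_throttle(n: float, K: float, base_rate: float) -> float:
    """Logistic birth-rate control: ``base_rate * max(0, 1 - n/K)``.

    Keeps population sizes in the biologically feasible domain: the per
    capita birth rate falls linearly with the current population size ``n``
    and vanishes at the carrying capacity ``K``.  Death rates are never
    throttled.
    """
    if K <= 0:
        raise ValueError(f"capacity K must be positive, got {K}")
    if n < 0:
        raise ValueError("population size cannot be negative")
    frac = 1.0 - n / K
    return base_rate * frac if frac > 0.0 else 0.0
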