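"""Agent data model.

B and T helper cells are tracked individually (receptor shape, activation
state, timers); self cells, foreign antigens, bone marrow cells, antibodies,
danger signals and interleukins are counted populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .shape_space import ShapePoint

# B / Th activation states
NAIVE = 0
ACTIVATED = 1
STRONG = 2
PLASMA = 3
MEMORY = 4

STATE_NAMES = {NAIVE: "naive", ACTIVATED: "activated", STRONG: "strongly_activated",
               PLASMA: "plasma", MEMORY: "memory"}


class BCell:
    """An individually tracked B cell.

    ``presented`` is the peptide shown in MHCII after engulfing an antigen
    (None when the cell presents nothing); ``presented_self`` is the index of
    the source self population, or -1 for a foreign peptide.  A plasma cell
    keeps its BCR but has neither action nor activation-control events; the
    antibodies it produces share its BCR shape.
    """

    __slots__ = ("bcr", "state", "presented", "presented_self", "presented_at",
                 "last_contact", "strong_streak", "eids", "idx", "pres_idx")

    def __init__(self, bcr: ShapePoint, state: int = NAIVE) -> None:
        self.bcr = bcr
        self.state = state
        self.presented: ShapePoint | None = None
        self.presented_self = -1
        self.presented_at = 0.0
        self.last_contact = 0.0
        self.strong_streak = 0
        self.eids: list[int] = []
        self.idx = -1  # position in the live-cell registry
        self.pres_idx = -1  # position in the presenting-cell registry


class ThCell:
    """An individually tracked T helper cell.

    ``regulatory`` marks positive selection into the characteristic ring of
    self peptide ``ring`` (ERS only): such cells keep self-presenting B cells
    under homeostatic control.
    """

    __slots__ = ("tcr", "state", "regulatory", "ring", "eids", "idx", "ring_idx")

    def __init__(self, tcr: ShapePoint, regulatory: bool = False, ring: int = -1) -> None:
        self.tcr = tcr
        self.state = NAIVE
        self.regulatory = regulatory
        self.ring = ring
        self.eids: list[int] = []
        self.idx = -1
        self.ring_idx = -1


class Population:
    """A counted population of identical agents (one shape per population)."""

    __slots__ = ("kind", "shape", "count", "initial", "division_mean_wait",
                 "capacity", "births", "deaths", "eids", "trace", "injections")

    def __init__(self, kind: str, shape: ShapePoint | None, count: int,
                 division_mean_wait: float = 0.0, capacity: float = 0.0) -> None:
        if count < 0:
            raise ValueError("population count cannot be negative")
        self.kind = kind
        self.shape = shape
        self.count = count
        self.initial = count
        self.division_mean_wait = division_mean_wait
        self.capacity = capacity
        self.births = 0
        self.deaths = 0
        self.eids: list[int] = []
        # (time, count) change-points around the outcome thresholds
        self.trace: list[tuple[float, int]] = []
        self.injections: list[float] = []


@dataclass
class DivisionCounters:
    """Cumulative division counts by interaction type, for T and B cells."""

    weak_T: int = 0
    weak_B: int = 0
    intermediate_T: int = 0
    intermediate_B: int = 0
    strong_T: int = 0
    strong_B: int = 0

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.weak_T, self.weak_B, self.intermediate_T,
                self.intermediate_B, self.strong_T, self.strong_B)


CENSUS_FIELDS = ("nW", "nR", "nB", "nAb", "nTh", "nIL", "nM")


def census(state) -> tuple[int, int, int, int, int, int, int]:
    """The seven output variables of a simulation state.

    ``nW`` total self cells, ``nR`` foreign cells, ``nB`` B cells of every
    state (plasma and memory included), ``nAb`` antibodies, ``nTh`` T helper
    cells, ``nIL`` danger signals, ``nM`` bone marrow cells.
    """
    nW = sum(p.count for p in state.self_pops)
    nR = sum(p.count for p in state.foreign_pops)
    nAb = sum(p.count for p in state.antibody_pops.values())
    return (nW, nR, state.n_b, nAb, state.n_th, state.danger.count, state.marrow.count)
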