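"""Parameter-file parsing, defaults and run outputs.

The parameter file is a plain-text dialect: one ``key value`` pair per line,
``#`` starts a comment, blank lines are ignored.  Missing keys take the
documented defaults, so an empty file describes the default ERS world.  The
thirteen core parameter names (``r0``, ``pmem``, ``crnew``, ``rminnew``,
``crspread``, ``rminsprd``, ``thrad``, ``pmut``, ``taub0``, ``tauth0``,
``tcrit_stress``, ``nr``, ``tr``) are kept verbatim for cross-reference with
the sensitivity-analysis table; every internal rule constant is also exposed
as a key.

Repeatable multi-value keys describe the initial world:

* ``self_pop x y count`` — a non-immune self population (default: three
  populations at (550,300), (700,-200), (850,150), 150 cells each);
* ``infect t nr tr x y`` — an infection scheduled at time ``t`` (steps).

``model ers|crs`` applies the four-parameter model switch
(``medrepr``/``weakrepr``/``comptype``/``tauthm``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

#: (default, type, min, max) — min/max of None mean unbounded on that side.
_SCHEMA: dict[str, tuple[Any, type, Any, Any]] = {
    # core parameters (sensitivity-analysis set)
    "r0": (150, int, 1, 500),
    "pmem": (0.3, float, 0.0, 1.0),
    "crnew": (0.9, float, 0.01, 2.0),
    "rminnew": (5, int, 1, 50),
    "crspread": (0.9, float, 0.01, 2.0),
    "rminsprd": (5, int, 1, 50),
    "thrad": (80, int, 1, 500),
    "pmut": (0.4, float, 0.0, 1.0),
    "taub0": (5.0, float, 1e-9, None),
    "tauth0": (2.0, float, 1e-9, None),
    "tcrit_stress": (2.0, float, 1e-9, None),
    "nr": (350, int, 0, None),
    "tr": (60.0, float, 1e-9, None),
    # model switches (ERS preset; `model crs` flips all four)
    "medrepr": (1, int, 0, 1),
    "weakrepr": (1, int, 0, 1),
    "comptype": (0, int, 0, 1),
    "tauthm": (5.0, float, 1e-9, None),
    # engine
    "t_max": (5000.0, float, 1e-9, None),
    "seed": (0, int, 0, None),
    "record_every": (1.0, float, 1e-9, None),
    # initial world / populations
    "self_tau": (100.0, float, 1e-9, None),
    "self_capacity": (600.0, float, 1e-9, None),
    "marrow_init": (50, int, 0, None),
    "marrow_tau": (50.0, float, 1e-9, None),
    "marrow_capacity": (100.0, float, 1e-9, None),
    "foreign_capacity": (8000.0, float, 1e-9, None),
    "start_step": (100.0, float, 0.0, None),
    # selection geometry
    "b_negsel_radius": (50, int, 0, None),
    "auto_activation_radius": (40, int, 0, None),
    "ring_inner": (50, int, 0, None),
    "negsel_on": (1, int, 0, 1),
    # interaction rules
    "alpha_affinity": (2.0, float, 0.0, None),
    "pweak": (0.05, float, 0.0, 1.0),
    "pweak_t": (0.1, float, 0.0, 1.0),
    "tauctrl": (5.0, float, 1e-9, None),
    "taubm": (2.5, float, 1e-9, None),
    "taub_strong": (3.0, float, 1e-9, None),
    "pres_life": (30.0, float, 1e-9, None),
    "memory_recall_p": (1.0, float, 0.0, 1.0),
    # lifespans and capacities
    "b_life": (1500.0, float, 1e-9, None),
    "th_life": (800.0, float, 1e-9, None),
    "th_strong_life": (120.0, float, 1e-9, None),
    "memory_life": (2000.0, float, 1e-9, None),
    "memory_capacity": (50.0, float, 1e-9, None),
    "plasma_life": (40.0, float, 1e-9, None),
    "b_capacity": (300.0, float, 1e-9, None),
    "th_capacity": (400.0, float, 1e-9, None),
    "b_strong_capacity": (1200.0, float, 1e-9, None),
    "th_strong_capacity": (300.0, float, 1e-9, None),
    # soluble pools
    "plasma_after": (3, int, 1, None),
    "danger_burst": (5, int, 0, None),
    "il_burst": (5, int, 0, None),
    "danger_action_tau": (2.0, float, 1e-9, None),
    "danger_decay_tau": (5.0, float, 1e-9, None),
    "il_action_tau": (2.0, float, 1e-9, None),
    "il_decay_tau": (5.0, float, 1e-9, None),
    "ab_prod_tau": (2.0, float, 1e-9, None),
    "ab_burst": (5, int, 1, None),
    "ab_kill": (25, int, 1, None),
    "ab_action_tau": (2.0, float, 1e-9, None),
    "ab_decay_tau": (12.0, float, 1e-9, None),
    "ab_radius": (100, int, 0, None),
    # default infection shape (antigen-lattice coordinates)
    "foreign_x": (300, int, 0, 1000),
    "foreign_y": (350, int, -500, 500),
}

DEFAULT_SELF_POPS: tuple[tuple[int, int, int], ...] = (
    (550, 300, 150),
    (700, -200, 150),
    (850, 150, 150),
)

#: The four-parameter ERS <-> CRS switch.
MODEL_PRESETS = {
    "ers": {"medrepr": 1, "weakrepr": 1, "comptype": 0, "tauthm": 5.0},
    "crs": {"medrepr": 0, "weakrepr": 0, "comptype": 1, "tauthm": 30.0},
}


class ConfigError(ValueError):
    pass


@dataclass
class ParameterSet:
    """A fully validated parameter set (scalar keys + world description)."""

    values: dict[str, Any] = field(default_factory=dict)
    self_pops: list[tuple[int, int, int]] = field(
        default_factory=lambda: list(DEFAULT_SELF_POPS))
    infections: list[tuple[float, int, float, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        full = {k: v[0] for k, v in _SCHEMA.items()}
        for k, v in self.values.items():
            if k not in _SCHEMA:
                raise ConfigError(f"unknown parameter {k!r}")
            full[k] = _coerce(k, v)
        self.values = full

    def __getattr__(self, name: str):
        try:
            return self.__dict__["values"][name]
        except KeyError:
            raise AttributeError(name) from None

    def with_updates(self, updates: dict[str, Any] | None = None,
                     model: str | None = None,
                     infections: list[tuple[float, int, float, int, int]] | None = None,
                     ) -> "ParameterSet":
        """A copy with scalar overrides, an optional model preset, and schedule."""
        vals = dict(self.values)
        if model is not None:
            if model not in MODEL_PRESETS:
                raise ConfigError(f"unknown model {model!r} (expected ers or crs)")
            vals.update(MODEL_PRESETS[model])
        if updates:
            vals.update(updates)
        return ParameterSet(values=vals, self_pops=list(self.self_pops),
                            infections=list(infections if infections is not None
                                            else self.infections))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (self.values == other.values and self.self_pops == other.self_pops
                and self.infections == other.infections)


def _coerce(key: str, raw: Any):
    default, typ, lo, hi = _SCHEMA[key]
    try:
        if typ is int:
            val = int(raw) if not isinstance(raw, str) else int(raw, 10)
            if isinstance(raw, float) and raw != val:
                raise ValueError
        else:
            val = float(raw)
    except (TypeError, ValueError):
        raise ConfigError(f"parameter {key!r}: malformed value {raw!r}") from None
    if (lo is not None and val < lo) or (hi is not None and val > hi):
        raise ConfigError(
            f"parameter {key!r}: value {val} outside allowed range "
            f"[{lo if lo is not None else '-inf'}, {hi if hi is not None else 'inf'}]")
    return val


def parse_params(source: str | os.PathLike) -> ParameterSet:
    """Parse a parameter file (path or literal text) into a ParameterSet.

    Raises :class:`ConfigError` naming the offending line for unknown keys,
    malformed values and out-of-range values.
    """
    text = source
    if isinstance(source, os.PathLike) or (
            isinstance(source, str) and "\n" not in source and os.path.exists(source)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()

    values: dict[str, Any] = {}
    self_pops: list[tuple[int, int, int]] = []
    infections: list[tuple[float, int, float, int, int]] = []
    model: str | None = None

    for lineno, raw_line in enumerate(str(text).splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key, args = parts[0], parts[1:]

        def bad(msg: str):
            return ConfigError(f"line {lineno}: {msg} ({raw_line.strip()!r})")

        if key == "model":
            if len(args) != 1 or args[0].lower() not in MODEL_PRESETS:
                raise bad("model must be 'ers' or 'crs'")
            model = args[0].lower()
        elif key == "self_pop":
            if len(args) != 3:
                raise bad("self_pop needs: x y count")
            try:
                x, y, count = (int(a) for a in args)
            except ValueError:
                raise bad("self_pop values must be integers") from None
            if count < 0:
                raise bad("self_pop count must be nonnegative")
            self_pops.append((x, y, count))
        elif key == "infect":
            if len(args) != 5:
                raise bad("infect needs: t nr tr x y")
            try:
                t, nr, tr, x, y = float(args[0]), int(args[1]), float(args[2]), \
                    int(args[3]), int(args[4])
            except ValueError:
                raise bad("malformed infect entry") from None
            if t < 0 or nr < 0 or tr <= 0:
                raise bad("infect needs t >= 0, nr >= 0, tr > 0")
            infections.append((t, nr, tr, x, y))
        elif key in _SCHEMA:
            if len(args) != 1:
                raise bad(f"{key} takes exactly one value")
            try:
                values[key] = _coerce(key, args[0])
            except ConfigError as exc:
                raise bad(str(exc)) from None
        else:
            raise bad(f"unknown parameter {key!r}")

    if model is not None:
        merged = dict(MODEL_PRESETS[model])
        merged.update(values)  # explicit keys win over the preset
        values = merged
    return ParameterSet(values=values,
                        self_pops=self_pops or list(DEFAULT_SELF_POPS),
                        infections=infections)


def render_params(params: ParameterSet) -> str:
    """Render a ParameterSet back to the file dialect (parse/render round-trips)."""
    lines = [f"{k} {params.values[k]}" for k in sorted(params.values)]
    for x, y, count in params.self_pops:
        lines.append(f"self_pop {x} {y} {count}")
    for t, nr, tr, x, y in params.infections:
        lines.append(f"infect {t} {nr} {tr} {x} {y}")
    return "\n".join(lines) + "\n"


TIMESERIES_COLUMNS = ("t", "nW", "nR", "nB", "nAb", "nTh", "nIL", "nM",
                      "weak_T", "weak_B", "intermediate_T", "intermediate_B",
                      "strong_T", "strong_B")


def write_run(sim, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the recorded run to ``out_dir``.

    Emits ``timeseries.tsv`` (census and cumulative division counters at each
    recorded step) and ``summary.tsv`` (outcome classification, elimination
    times and the final census).  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    ts_path = os.path.join(out_dir, "timeseries.tsv")
    with open(ts_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TIMESERIES_COLUMNS) + "\n")
        for row in sim.records:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")

    sm_path = os.path.join(out_dir, "summary.tsv")
    with open(sm_path, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        for key, value in sim.summary().items():
            fh.write(f"{key}\t{_fmt(value)}\n")
    return {"timeseries": ts_path, "summary": sm_path}


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
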