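"""Epithelial layer: a logical model replicated over a hexagonal cylinder.

Every cell runs the same :class:`~epilogic.logic_core.LogicalModel`; cells are
static (no proliferation or movement).  Cell-cell signaling enters through
*integration inputs*: input components of the single-cell model (``Rho_ext``,
``Aos_ext``, ``Br_adj``, ``Roof_adj``) whose per-cell level is recomputed at
the start of every tick from the neighbors' component levels.

One tick applies staged synchronous sub-updates to all cells:

1. recompute the integration inputs and the derived signal nodes (S, A, X)
   from the tick-start configuration;
2. update the first priority stage (dpERK in the eggshell models) one unit
   toward target, synchronously over the grid;
3. update the remaining non-input components likewise (honoring delays).

Perturbation clamps and range restrictions are re-imposed after every stage,
so clones are airtight against transient leaks.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .expr import _And, _Atom, _Not, _Or, Expr
from .hexgrid import HexGrid
from .logic_core import LogicalModel, Rule

logger = logging.getLogger(__name__)

__all__ = [
    "IntegrationRule",
    "PerturbationSpec",
    "Epithelium",
    "RunOutcome",
    "run_to_attractor",
]


# ---------------------------------------------------------------------------
# vectorized rule evaluation over grid arrays


def eval_expr(expr: Expr, levels: Mapping[str, np.ndarray]) -> np.ndarray:
    if isinstance(expr, _Atom):
        v = levels[expr.name]
        return v >= expr.level if expr.op == "ge" else v == expr.level
    if isinstance(expr, _Not):
        return np.logical_not(eval_expr(expr.child, levels))
    if isinstance(expr, _And):
        out = eval_expr(expr.children[0], levels)
        for c in expr.children[1:]:
            out = np.logical_and(out, eval_expr(c, levels))
        return out
    if isinstance(expr, _Or):
        out = eval_expr(expr.children[0], levels)
        for c in expr.children[1:]:
            out = np.logical_or(out, eval_expr(c, levels))
        return out
    raise TypeError(f"not an expression: {expr!r}")


def eval_rule(rule: Rule, levels: Mapping[str, np.ndarray], shape) -> np.ndarray:
    """First-match-wins clause evaluation, vectorized (implicit default 0)."""
    target = np.zeros(shape, dtype=np.int8)
    unset = np.ones(shape, dtype=bool)
    for clause in rule.clauses:
        sel = np.logical_and(eval_expr(clause.condition, levels), unset)
        target[sel] = clause.target
        unset &= ~sel
    return target


# ---------------------------------------------------------------------------
# integration inputs


@dataclass(frozen=True)
class IntegrationRule:
    """How an integration input summarizes a neighborhood.

    ``kind='max'``: level = max of ``source`` over neighbors within
    ``distance`` (capped at the input's range) — e.g. Rho_ext is 2 if any
    direct neighbor expresses Rho at 2, 1 if any expresses it at all.

    ``kind='count'``: level = number of ``thresholds`` passed by the count of
    neighbors within ``distance`` expressing ``source`` (level >= 1) — e.g.
    Aos_ext with thresholds (1, 4) over distance 3.
    """

    source: str
    distance: int = 1
    kind: str = "max"
    thresholds: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind not in ("max", "count"):
            raise ValueError(f"unknown integration kind {self.kind!r}")
        if self.kind == "count" and not self.thresholds:
            raise ValueError("count integration needs thresholds")
        if self.thresholds != tuple(sorted(self.thresholds)) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise ValueError("thresholds must be strictly increasing")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


class _NeighborIndex:
    """Padded neighbor index matrices per (grid, distance)."""

    def __init__(self, grid: HexGrid):
        self.grid = grid
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def get(self, distance: int):
        if distance not in self._cache:
            g = self.grid
            lists = [g.neighbors((r, c), distance) for r, c in g.cells()]
            width = max(len(l) for l in lists)
            idx = np.zeros((g.n_cells, width), dtype=np.int64)
            mask = np.zeros((g.n_cells, width), dtype=bool)
            for i, l in enumerate(lists):
                for j, (r, c) in enumerate(l):
                    idx[i, j] = r * g.n_cols + c
                    mask[i, j] = True
            self._cache[distance] = (idx, mask)
        return self._cache[distance]


# ---------------------------------------------------------------------------
# perturbations


@dataclass(frozen=True)
class PerturbationSpec:
    """Clamp or range-restrict a component over a cell mask.

    ``mask=None`` means the whole grid (a whole-epithelium mutant); otherwise
    a boolean (n_rows, n_cols) array (a clone).  ``phases=None`` applies in
    every phase.
    """

    component: str
    mode: str  # "clamp" | "range"
    value: int | None = None
    low: int | None = None
    high: int | None = None
    mask: object = None  # None | np.ndarray
    phases: tuple[str, ...] | None = None
    name: str = ""

    def __post_init__(self):
        if self.mode == "clamp":
            if self.value is None:
                raise ValueError("clamp needs a value")
        elif self.mode == "range":
            if self.low is None or self.high is None or self.low > self.high:
                raise ValueError("range needs low <= high")
        else:
            raise ValueError(f"unknown perturbation mode {self.mode!r}")

    def applies(self, phase: str) -> bool:
        return self.phases is None or phase in self.phases

    def impose(self, field: np.ndarray, phase: str) -> None:
        if not self.applies(phase):
            return
        mask = slice(None) if self.mask is None else np.asarray(self.mask, bool)
        if self.mode == "clamp":
            field[mask] = self.value
        else:
            field[mask] = np.clip(field[mask], self.low, self.high)


def _check_perturbations(model, specs):
    ranges = model.ranges()
    for spec in specs:
        if spec.component not in ranges:
            raise ValueError(f"perturbation on undeclared component {spec.component!r}")
        maxlev = ranges[spec.component]
        lo, hi = (
            (spec.value, spec.value) if spec.mode == "clamp" else (spec.low, spec.high)
        )
        if not (0 <= lo <= hi <= maxlev):
            raise ValueError(f"{spec.component}: perturbation outside 0..{maxlev}")
    by_key: dict = {}
    for spec in specs:
        if spec.mode != "clamp":
            continue
        key = spec.component
        for other, oval in by_key.get(key, []):
            both = (
                np.ones(1, bool)
                if spec.mask is None or other is None
                else np.logical_and(np.asarray(spec.mask, bool), np.asarray(other, bool))
            )
            if oval != spec.value and np.any(both):
                raise ValueError(
                    f"contradictory clamps on {key}: {oval} vs {spec.value}"
                )
        by_key.setdefault(key, []).append((spec.mask, spec.value))


# ---------------------------------------------------------------------------
# the epithelium itself


@dataclass
class Epithelium:
    """Grid configuration: one level array per model component.

    ``fields`` holds an ``(n_rows, n_cols)`` int8 array per component
    (inputs included); ``counters`` the delay bookkeeping per delayed
    component; ``integration`` maps integration-input names to their
    :class:`IntegrationRule`.
    """

    model: LogicalModel
    grid: HexGrid
    fields: dict[str, np.ndarray]
    integration: dict[str, IntegrationRule] = field(default_factory=dict)
    perturbations: tuple[PerturbationSpec, ...] = ()
    counters: dict[str, np.ndarray] = field(default_factory=dict)
    tick: int = 0
    phase: str = "pre"

    def __post_init__(self):
        shape = self.grid.shape
        for c in self.model.components:
            arr = self.fields.get(c.name)
            if arr is None:
                arr = np.zeros(shape, dtype=np.int8)
            arr = np.asarray(arr, dtype=np.int8)
            if arr.shape != shape:
                raise ValueError(f"{c.name}: field shape {arr.shape} != {shape}")
            if arr.min() < 0 or arr.max() > c.max_level:
                raise ValueError(f"{c.name}: levels outside 0..{c.max_level}")
            self.fields[c.name] = arr
        for name in self.integration:
            if not self.model.component(name).is_input:
                raise ValueError(f"integration target {name!r} must be an input")
        for name, d in self.model._delayed.items():
            self.counters.setdefault(name, np.zeros(shape, dtype=np.int8))
        _check_perturbations(self.model, self.perturbations)
        self._nbr = _NeighborIndex(self.grid)

    # -- bookkeeping -------------------------------------------------------

    def copy(self) -> "Epithelium":
        return replace(
            self,
            fields={k: v.copy() for k, v in self.fields.items()},
            counters={k: v.copy() for k, v in self.counters.items()},
        )

    def config_key(self) -> bytes:
        """Hash of the full configuration, including delay counters."""
        h = hashlib.blake2b(digest_size=16)
        h.update(self.phase.encode())
        for name in self.model.names:
            h.update(self.fields[name].tobytes())
        for name in sorted(self.counters):
            h.update(self.counters[name].tobytes())
        return h.digest()

    def cell_state(self, cell) -> tuple[int, ...]:
        r, c = cell
        return tuple(int(self.fields[n][r, c]) for n in self.model.names)

    # -- dynamics ----------------------------------------------------------

    def _impose(self):
        for spec in self.perturbations:
            if spec.component in self.fields:
                spec.impose(self.fields[spec.component], self.phase)

    def _impose_derived(self, derived: dict[str, np.ndarray]):
        # perturbations may target derived signal nodes (e.g. an X mutant)
        for spec in self.perturbations:
            if spec.component in derived:
                spec.impose(derived[spec.component], self.phase)

    def compute_integration(self) -> dict[str, np.ndarray]:
        """Per-cell levels of the integration inputs (from current fields)."""
        out = {}
        for name, rule in self.integration.items():
            idx, mask = self._nbr.get(rule.distance)
            src = self.fields[rule.source].ravel()[idx]
            cap = self.model.component(name).max_level
            if rule.kind == "max":
                lev = np.where(mask, src, 0).max(axis=1)
                lev = np.minimum(lev, cap)
            else:
                count = np.logical_and(mask, src >= 1).sum(axis=1)
                lev = np.zeros(self.grid.n_cells, dtype=np.int64)
                for th in rule.thresholds:
                    lev += count >= th
                lev = np.minimum(lev, cap)
            out[name] = lev.reshape(self.grid.shape).astype(np.int8)
        return out

    def derived_fields(self) -> dict[str, np.ndarray]:
        levels = dict(self.fields)
        out = {}
        for d in self.model.derived:
            arr = eval_rule(d.rule, levels, self.grid.shape)
            levels[d.name] = arr
            out[d.name] = arr
        return out

    def step(self) -> None:
        """One staged synchronous tick, in place."""
        debug = logger.isEnabledFor(logging.DEBUG)
        before = {n: self.fields[n].copy() for n in self.model.internals} if debug else None
        self._impose()
        # stage 1: integration inputs, then derived signal nodes, frozen for the tick
        for name, arr in self.compute_integration().items():
            self.fields[name] = arr
        self._impose()
        frozen_derived = self.derived_fields()
        self._impose_derived(frozen_derived)
        # stages 2..: priority classes
        for stage in self.model.priorities:
            levels = dict(self.fields)
            levels.update(frozen_derived)
            for name in stage:
                target = eval_rule(self.model.rules[name], levels, self.grid.shape)
                cur = self.fields[name]
                step = np.sign(target - cur).astype(np.int8)
                delay = self.model._delayed.get(name, 0)
                if delay == 0:
                    self.fields[name] = (cur + step).astype(np.int8)
                else:
                    cnt = self.counters[name]
                    fresh = cnt * step <= 0
                    ripe = np.logical_and(step != 0, np.abs(cnt) >= delay)
                    new_cnt = np.where(
                        step == 0,
                        0,
                        np.where(fresh, step, np.where(ripe, cnt, cnt + step)),
                    )
                    move = np.logical_and(ripe, ~fresh)
                    self.fields[name] = (cur + step * move).astype(np.int8)
                    self.counters[name] = new_cnt.astype(np.int8)
            self._impose()
        self.tick += 1
        if debug:
            changed = {
                n: int((self.fields[n] != before[n]).sum())
                for n in self.model.internals
                if (self.fields[n] != before[n]).any()
            }
            logger.debug("tick %d phase=%s changed=%s", self.tick, self.phase, changed)

    def extinguish(self, component: str = "Grk", phase: str = "post") -> None:
        """Zero an input field grid-wide and advance the phase tag."""
        self.fields[component] = np.zeros(self.grid.shape, dtype=np.int8)
        self.phase = phase


@dataclass
class RunOutcome:
    kind: str  # "fixed_point" | "cycle" | "cap"
    ticks: int
    period: int = 0

    @property
    def converged(self) -> bool:
        return self.kind != "cap"


def run_to_attractor(
    epi: Epithelium,
    max_ticks: int = 500,
    record_every: int = 0,
) -> tuple[RunOutcome, list[Epithelium]]:
    """Iterate :meth:`Epithelium.step` until the configuration repeats.

    Returns the outcome and (optionally) recorded snapshots.  ``kind`` is
    ``fixed_point`` when the repeat has period 1, ``cycle`` otherwise, and
    ``cap`` when ``max_ticks`` elapsed without a repeat ("undecided").
    """
    if max_ticks < 1:
        raise ValueError("max_ticks must be >= 1")
    seen: dict[bytes, int] = {epi.config_key(): 0}
    snaps: list[Epithelium] = []
    for t in range(1, max_ticks + 1):
        epi.step()
        if record_every and (t % record_every == 0):
            snaps.append(epi.copy())
        key = epi.config_key()
        if key in seen:
            period = t - seen[key]
            kind = "fixed_point" if period == 1 else "cycle"
            return RunOutcome(kind, ticks=t, period=period), snaps
        seen[key] = t
    return RunOutcome("cap", ticks=max_ticks), snaps
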