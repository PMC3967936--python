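"""Multi-valued logical (Thomas) regulatory networks.

A model is a set of discrete components, each taking levels ``0..max_level``,
together with one logical rule per non-input component.  A rule is an ordered
list of ``(condition, target_level)`` clauses; the target of the component in a
given state is the target level of the first clause whose condition holds, and
0 if none does.  Inputs have no rule and keep their level.

Dynamics follow the GINsim conventions:

* **unit-step semantics** — a component whose target differs from its current
  level moves one level toward the target per update;
* **synchronous update** — all unstable components step together (optionally
  in priority stages), giving a unique successor;
* **asynchronous update** — one successor per unstable component;
* **delays** — a component annotated with ``delay: d`` only moves (under the
  synchronous scheme) once its target has differed from its level in the same
  direction for ``d`` consecutive ticks; the counter resets when the target
  reverses direction or matches the level.

*Derived variables* are instantaneous functions of the state (clause lists
like rules, but re-evaluated on the fly rather than integrated as state).
They model signal-integration nodes (S, A, X in the eggshell models) whose
response is much faster than any transcriptional step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .expr import Expr, atoms_of, parse_expr

__all__ = [
    "Component",
    "Clause",
    "Rule",
    "DerivedVar",
    "LogicalModel",
    "ModelError",
    "StateSpaceCapExceeded",
    "evaluate_targets",
    "successor_synchronous",
    "successors_asynchronous",
    "stable_states",
    "is_stable",
]

STATE_SPACE_CAP = 10_000_000


class ModelError(ValueError):
    """Invalid model structure (missing rule, bad target level, ...)."""


class StateSpaceCapExceeded(RuntimeError):
    """Enumeration refused: the state space exceeds the configured cap."""


@dataclass(frozen=True)
class Component:
    name: str
    max_level: int = 1
    is_input: bool = False
    delay: int = 0
    maintenance: bool = False  # documentation flag: rule carries a self-loop

    def __post_init__(self):
        if self.max_level < 1:
            raise ModelError(f"{self.name}: max_level must be >= 1")
        if self.delay < 0:
            raise ModelError(f"{self.name}: delay must be >= 0")


@dataclass(frozen=True)
class Clause:
    condition: Expr
    target: int
    note: str = ""


@dataclass(frozen=True)
class Rule:
    component: str
    clauses: tuple[Clause, ...]

    def target(self, levels: Mapping[str, int]) -> int:
        for clause in self.clauses:
            if clause.condition.eval(levels):
                return clause.target
        return 0


@dataclass(frozen=True)
class DerivedVar:
    name: str
    max_level: int
    rule: Rule


@dataclass
class LogicalModel:
    """A validated multi-valued logical model.

    ``components`` are ordered; a state is a tuple of levels in that order
    (derived variables are not part of the state).  ``priorities`` partitions
    the non-input components into ordered synchronous stages (earlier stages
    update first within a tick, and later stages see the updated levels).
    ``async_priorities`` optionally partitions them into asynchronous urgency
    classes: only the earliest class containing an unstable component
    generates successors (used to encode "fast" signal-transduction steps
    such as dpERK, or a slow, delayed Pnt).
    """

    name: str
    components: tuple[Component, ...]
    rules: dict[str, Rule]
    derived: tuple[DerivedVar, ...] = ()
    priorities: tuple[tuple[str, ...], ...] = ()
    async_priorities: tuple[tuple[str, ...], ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ModelError("duplicate component names")
        self.index = {n: i for i, n in enumerate(names)}
        derived_names = [d.name for d in self.derived]
        if set(derived_names) & set(names):
            raise ModelError("derived variable shadows a component")
        self._ranges = {c.name: c.max_level for c in self.components}
        self._ranges.update({d.name: d.max_level for d in self.derived})
        non_inputs = [c.name for c in self.components if not c.is_input]
        for c in self.components:
            if c.is_input and c.name in self.rules:
                raise ModelError(f"input component {c.name!r} must not have a rule")
            if not c.is_input and c.name not in self.rules:
                raise ModelError(f"missing rule for component {c.name!r}")
        for name, rule in self.rules.items():
            if name not in self.index:
                raise ModelError(f"rule for undeclared component {name!r}")
            for clause in rule.clauses:
                if not 1 <= clause.target <= self._ranges[name]:
                    raise ModelError(
                        f"{name}: clause target {clause.target} outside 1..{self._ranges[name]}"
                    )
        if not self.priorities:
            self.priorities = (tuple(non_inputs),)
        self._check_partition(self.priorities, non_inputs, "priorities")
        if self.async_priorities:
            self._check_partition(self.async_priorities, non_inputs, "async_priorities")
        else:
            self.async_priorities = (tuple(non_inputs),)
        self._delayed = {c.name: c.delay for c in self.components if c.delay > 0}

    @staticmethod
    def _check_partition(classes, non_inputs, what):
        flat = [n for cls in classes for n in cls]
        if sorted(flat) != sorted(non_inputs):
            raise ModelError(f"{what} must partition the non-input components")

    # -- introspection -----------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if c.is_input)

    @property
    def internals(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components if not c.is_input)

    def component(self, name: str) -> Component:
        return self.components[self.index[name]]

    def ranges(self) -> dict[str, int]:
        """Maximum level per component and derived variable."""
        return dict(self._ranges)

    def regulators(self, name: str) -> set[str]:
        """Components whose level the rule of ``name`` may read (derived
        variables are expanded to the components they read)."""
        rule = self.rules.get(name)
        if rule is None:
            return set()
        seen: set[str] = set()
        frontier = {a.name for cl in rule.clauses for a in atoms_of(cl.condition)}
        dmap = {d.name: d for d in self.derived}
        while frontier:
            n = frontier.pop()
            if n in seen:
                continue
            seen.add(n)
            if n in dmap:
                frontier |= {
                    a.name for cl in dmap[n].rule.clauses for a in atoms_of(cl.condition)
                }
        return {n for n in seen if n in self.index}

    # -- state helpers -----------------------------------------------------

    def levels_of(self, state: Sequence[int]) -> dict[str, int]:
        """Component + derived levels for ``state`` as a dict."""
        if len(state) != len(self.components):
            raise ModelError(
                f"state length {len(state)} != {len(self.components)} components"
            )
        levels = {c.name: int(v) for c, v in zip(self.components, state)}
        for c, v in zip(self.components, state):
            if not 0 <= v <= c.max_level:
                raise ModelError(f"{c.name}: level {v} outside 0..{c.max_level}")
        for d in self.derived:
            levels[d.name] = d.rule.target(levels)
        return levels

    def validate_state(self, state: Sequence[int]) -> tuple[int, ...]:
        self.levels_of(state)
        return tuple(int(v) for v in state)

    def state_space_size(self, free: Iterable[str] | None = None) -> int:
        names = self.names if free is None else tuple(free)
        size = 1
        for n in names:
            size *= self.component(n).max_level + 1
        return size

    def zero_state(self, **levels: int) -> tuple[int, ...]:
        """All-zero state, with keyword overrides by component name."""
        vec = [0] * len(self.components)
        for name, v in levels.items():
            vec[self.index[name]] = v
        return self.validate_state(vec)


def _step_toward(current: int, target: int) -> int:
    if target > current:
        return current + 1
    if target < current:
        return current - 1
    return current


def evaluate_targets(
    model: LogicalModel,
    state: Sequence[int],
    clamps: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Target level per non-input component (inputs keep their level).

    ``clamps`` forces components to behave as frozen inputs: their target is
    their clamped level regardless of their rule.
    """
    levels = model.levels_of(state)
    if clamps:
        for n, v in clamps.items():
            levels[n] = v
        for d in model.derived:  # recompute derived with clamped levels
            if d.name not in clamps:  # derived nodes may themselves be clamped
                levels[d.name] = d.rule.target(levels)
    targets: dict[str, int] = {}
    for name in model.internals:
        if clamps and name in clamps:
            targets[name] = clamps[name]
        else:
            targets[name] = model.rules[name].target(levels)
    return targets


def is_stable(
    model: LogicalModel,
    state: Sequence[int],
    clamps: Mapping[str, int] | None = None,
) -> bool:
    targets = evaluate_targets(model, state, clamps)
    idx = model.index
    return all(targets[n] == state[idx[n]] for n in model.internals)


def successor_synchronous(
    model: LogicalModel,
    state: Sequence[int],
    counters: Mapping[str, int] | None = None,
    clamps: Mapping[str, int] | None = None,
):
    """One synchronous tick.

    Components update in priority stages: each stage evaluates its targets
    against the state left by the previous stage, then all its members step
    one unit toward target simultaneously.  Returns ``(state, counters)``
    where ``counters`` carries the delay bookkeeping (signed: the sign is the
    direction being counted).  Pass ``counters=None`` to start fresh.
    """
    vec = list(model.validate_state(state))
    cnt = dict(counters) if counters else {n: 0 for n in model._delayed}
    for n in model._delayed:
        cnt.setdefault(n, 0)
    for stage in model.priorities:
        targets = evaluate_targets(model, vec, clamps)
        for name in stage:
            i = model.index[name]
            cur, tgt = vec[i], targets[name]
            delay = model._delayed.get(name, 0)
            if delay == 0:
                vec[i] = _step_toward(cur, tgt)
                continue
            if tgt == cur:
                cnt[name] = 0
                continue
            direction = 1 if tgt > cur else -1
            prev = cnt[name]
            if prev * direction <= 0:  # reversal or fresh: restart the count
                cnt[name] = direction
            elif abs(prev) >= delay:  # sustained long enough: move
                vec[i] = _step_toward(cur, tgt)
            else:
                cnt[name] = prev + direction
    return tuple(vec), cnt


def successors_asynchronous(
    model: LogicalModel,
    state: Sequence[int],
    clamps: Mapping[str, int] | None = None,
) -> dict[str, tuple[int, ...]]:
    """Asynchronous successors: ``{component: successor_state}``.

    One successor per unstable component of the *earliest* asynchronous
    priority class that contains an unstable component; empty dict iff the
    state is stable.  With the default single class this is the plain
    asynchronous scheme.
    """
    state = model.validate_state(state)
    targets = evaluate_targets(model, state, clamps)
    idx = model.index
    for cls in model.async_priorities:
        unstable = [n for n in cls if targets[n] != state[idx[n]]]
        if unstable:
            out = {}
            for n in unstable:
                vec = list(state)
                vec[idx[n]] = _step_toward(vec[idx[n]], targets[n])
                out[n] = tuple(vec)
            return out
    return {}


def stable_states(
    model: LogicalModel,
    fixed_inputs: Mapping[str, int] | None = None,
    clamps: Mapping[str, int] | None = None,
    cap: int = STATE_SPACE_CAP,
) -> list[tuple[int, ...]]:
    """All stable states, by exhaustive enumeration.

    ``fixed_inputs`` pins (a subset of) input components; unpinned inputs are
    enumerated over their full range.  ``clamps`` freezes arbitrary
    components at a level (they are treated as inputs).  States are returned
    in lexicographic order of the component declaration.
    """
    fixed: dict[str, int] = dict(fixed_inputs or {})
    for name, v in fixed.items():
        comp = model.component(name)
        if not comp.is_input:
            raise ModelError(f"{name!r} is not an input component")
        if not 0 <= v <= comp.max_level:
            raise ModelError(f"{name}: fixed level {v} out of range")
    if clamps:
        fixed.update(clamps)
    free = [c for c in model.components if c.name not in fixed]
    size = 1
    for c in free:
        size *= c.max_level + 1
    if size > cap:
        raise StateSpaceCapExceeded(
            f"state space of {size} states exceeds cap {cap}"
        )
    out = []
    idx = model.index
    base = [0] * len(model.components)
    for name, v in fixed.items():
        base[idx[name]] = v
    for combo in itertools.product(*(range(c.max_level + 1) for c in free)):
        vec = list(base)
        for c, v in zip(free, combo):
            vec[idx[c.name]] = v
        if is_stable(model, vec, clamps):
            out.append(tuple(vec))
    return out
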