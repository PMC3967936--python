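"""Single-cell dynamics analysis: state-transition graphs, attractors,
reachability, and exhaustive input-combination fate censuses.

Attractors are the terminal strongly connected components of the state
transition graph (STG): singleton terminal SCCs are the stable states (fixed
points), larger ones are cyclic (oscillatory) attractors.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .logic_core import (
    STATE_SPACE_CAP,
    LogicalModel,
    StateSpaceCapExceeded,
    evaluate_targets,
    successor_synchronous,
    successors_asynchronous,
)

__all__ = [
    "build_stg",
    "attractors",
    "Attractor",
    "FateTable",
    "reachable_fates",
    "reachable_attractors",
    "enumerate_input_fates",
]


def build_stg(
    model: LogicalModel,
    fixed_inputs: Mapping[str, int] | None = None,
    initial: Sequence[int] | Iterable[Sequence[int]] | None = None,
    scheme: str = "async",
    clamps: Mapping[str, int] | None = None,
    cap: int = STATE_SPACE_CAP,
) -> nx.DiGraph:
    """State transition graph reachable from ``initial``.

    ``initial`` may be a single state, an iterable of states, or ``None`` to
    take the whole state space restricted by ``fixed_inputs``/``clamps`` (the
    free inputs are then enumerated too).  Self-edges of stable states under
    the synchronous scheme are omitted, so stable states always have
    out-degree 0.
    """
    if scheme not in ("async", "sync"):
        raise ValueError(f"unknown scheme {scheme!r}")
    fixed = dict(fixed_inputs or {})
    eff_clamps = dict(clamps or {})
    pinned = {**fixed, **eff_clamps}

    if initial is None:
        free = [c for c in model.components if c.name not in pinned]
        size = 1
        for c in free:
            size *= c.max_level + 1
        if size > cap:
            raise StateSpaceCapExceeded(f"{size} states exceed cap {cap}")
        base = [0] * len(model.components)
        for n, v in pinned.items():
            base[model.index[n]] = v
        seeds = []
        for combo in itertools.product(*(range(c.max_level + 1) for c in free)):
            vec = list(base)
            for c, v in zip(free, combo):
                vec[model.index[c.name]] = v
            seeds.append(tuple(vec))
    else:
        if initial and isinstance(initial[0] if isinstance(initial, (list, tuple)) else None, int):
            seeds = [tuple(initial)]  # a single state
        else:
            seeds = [tuple(s) for s in initial]
        seeds = [model.validate_state(s) for s in seeds]
        for s in seeds:
            for n, v in pinned.items():
                if s[model.index[n]] != v:
                    raise ValueError(
                        f"initial state has {n}={s[model.index[n]]}, pinned to {v}"
                    )

    g = nx.DiGraph(scheme=scheme, model=model.name)
    todo = deque(seeds)
    g.add_nodes_from(seeds)
    while todo:
        s = todo.popleft()
        if scheme == "async":
            succs = list(successors_asynchronous(model, s, clamps=eff_clamps).values())
        else:
            nxt, _ = successor_synchronous(model, s, clamps=eff_clamps)
            succs = [] if nxt == s else [nxt]
        for t in succs:
            if t not in g:
                g.add_node(t)
                todo.append(t)
                if g.number_of_nodes() > cap:
                    raise StateSpaceCapExceeded(f"STG grew past cap {cap}")
            g.add_edge(s, t)
    return g


@dataclass(frozen=True)
class Attractor:
    kind: str  # "fixed_point" | "cyclic"
    states: frozenset

    @property
    def size(self) -> int:
        return len(self.states)

    def signature(self, model: LogicalModel, components: Sequence[str]) -> frozenset:
        """Canonical identity: the set of level-tuples over ``components``."""
        idx = [model.index[c] for c in components]
        return frozenset(tuple(s[i] for i in idx) for s in self.states)

    def sorted_states(self):
        return sorted(self.states)


def attractors(stg: nx.DiGraph) -> list[Attractor]:
    """Terminal SCCs of the STG, labeled fixed_point or cyclic.

    Output order is canonical (sorted by smallest member state) and therefore
    invariant under node-insertion order.
    """
    out = []
    cond = nx.condensation(stg)
    for cid in cond.nodes:
        if cond.out_degree(cid) == 0:
            members = cond.nodes[cid]["members"]
            kind = "fixed_point" if len(members) == 1 else "cyclic"
            out.append(Attractor(kind, frozenset(members)))
    return sorted(out, key=lambda a: min(a.states))


@dataclass
class FateTable:
    """Mapping from internal-component signatures to fate labels.

    ``components`` lists the signature components in order; ``table`` maps a
    level tuple over those components to a label (F1..F8, or the
    phenomenological roof/floor/operculum/mainbody).  Unknown signatures
    classify as ``"other"``.
    """

    components: tuple[str, ...]
    table: dict[tuple[int, ...], str]
    name: str = "fates"

    def __post_init__(self):
        if len(set(self.table.values())) != len(self.table):
            raise ValueError("fate labels must be pairwise distinct")

    def signature_of(self, model: LogicalModel, state: Sequence[int]) -> tuple[int, ...]:
        return tuple(state[model.index[c]] for c in self.components)

    def classify_state(self, model: LogicalModel, state: Sequence[int]) -> str:
        return self.table.get(self.signature_of(model, state), "other")

    def classify_attractor(self, model: LogicalModel, att: Attractor) -> str:
        if att.kind == "fixed_point":
            return self.classify_state(model, next(iter(att.states)))
        sig = sorted(att.signature(model, self.components))
        return "cyclic:" + "/".join("".join(map(str, s)) for s in sig)

    @classmethod
    def from_tsv(cls, path, name: str = "fates") -> "FateTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        comps = tuple(c for c in df.columns if c != "fate")
        table = {
            tuple(int(row[c]) for c in comps): row["fate"] for _, row in df.iterrows()
        }
        return cls(comps, table, name=name)

    def to_tsv(self, path) -> None:
        rows = [
            {**{c: v for c, v in zip(self.components, sig)}, "fate": label}
            for sig, label in sorted(self.table.items(), key=lambda kv: kv[1])
        ]
        pd.DataFrame(rows)[list(self.components) + ["fate"]].to_csv(
            path, sep="\t", index=False
        )


def reachable_attractors(
    model: LogicalModel,
    fixed_inputs: Mapping[str, int],
    initial: Sequence[int],
    scheme: str = "async",
    clamps: Mapping[str, int] | None = None,
) -> list[Attractor]:
    stg = build_stg(model, fixed_inputs, initial=tuple(initial), scheme=scheme, clamps=clamps)
    return attractors(stg)


def reachable_fates(
    model: LogicalModel,
    fixed_inputs: Mapping[str, int],
    initial: Sequence[int],
    fate_table: FateTable,
    scheme: str = "async",
    clamps: Mapping[str, int] | None = None,
) -> set[str]:
    """Fate labels of all attractors reachable from ``initial``."""
    atts = reachable_attractors(model, fixed_inputs, initial, scheme, clamps)
    return {fate_table.classify_attractor(model, a) for a in atts}


def enumerate_input_fates(
    model: LogicalModel,
    fate_table: FateTable,
    input_names: Sequence[str] | None = None,
    pseudo_inputs: Sequence[str] = (),
    fixed: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Attractor census over every combination of input levels.

    ``pseudo_inputs`` are non-input components enumerated and clamped as if
    they were inputs (the eggshell analysis treats Mid this way); ``fixed``
    pins the remaining inputs (e.g. the early signals at 0).  Returns one row
    per combination (stable fates and cyclic attractors present) plus a
    census dict with the distinct counts over all combinations.
    """
    fixed = dict(fixed or {})
    if input_names is None:
        input_names = [n for n in model.inputs if n not in fixed]
    varying = list(input_names) + list(pseudo_inputs)
    ranges = [model.component(n).max_level for n in varying]

    rows = []
    stable_sigs: set = set()
    cyclic_sigs: set = set()
    for combo in itertools.product(*(range(m + 1) for m in ranges)):
        assign = dict(zip(varying, combo))
        clamps = {**fixed, **assign}
        stg = build_stg(model, clamps=clamps, scheme="async")
        atts = attractors(stg)
        fates, cycles = [], []
        for a in atts:
            if a.kind == "fixed_point":
                s = next(iter(a.states))
                stable_sigs.add(fate_table.signature_of(model, s))
                fates.append(fate_table.classify_state(model, s))
            else:
                label = fate_table.classify_attractor(model, a)
                cyclic_sigs.add(a.signature(model, fate_table.components))
                cycles.append(label)
        rows.append(
            {
                **assign,
                "stable_fates": ",".join(sorted(set(fates))),
                "cyclic_attractors": ",".join(sorted(set(cycles))),
            }
        )
    df = pd.DataFrame(rows)
    census = {
        "n_combinations": len(rows),
        "n_distinct_stable_fates": len(stable_sigs),
        "n_distinct_cyclic_attractors": len(cyclic_sigs),
        "stable_signatures": sorted(stable_sigs),
    }
    return df, census
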