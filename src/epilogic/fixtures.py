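"""Seeded random fixtures: small logical models and toy grids.

Used by the property tests to compare the dynamics engine against
brute-force oracles; generation is fully reproducible from the seed.
"""

from __future__ import annotations

import numpy as np

from .expr import parse_expr
from .hexgrid import HexGrid
from .logic_core import Clause, Component, LogicalModel, Rule

__all__ = ["random_model", "random_state", "toy_grid", "toy_fields"]


def _random_condition(rng: np.random.Generator, comps: list[Component]) -> str:
    """A random conjunction/disjunction of literals over the components."""
    n_lit = int(rng.integers(1, 4))
    lits = []
    for _ in range(n_lit):
        c = comps[int(rng.integers(len(comps)))]
        level = int(rng.integers(1, c.max_level + 1))
        op = rng.choice([":", "="]) if c.max_level > 1 else ":"
        atom = c.name if (op == ":" and level == 1) else f"{c.name}{op}{level}"
        if rng.random() < 0.3:
            atom = "!" + (atom if op == ":" and level == 1 else f"({atom})")
        lits.append(atom)
    joiner = " & " if rng.random() < 0.6 else " | "
    return joiner.join(lits)


def random_model(
    seed: int,
    n_components: int = 4,
    max_level: int = 1,
    n_inputs: int = 1,
    max_clauses: int = 2,
) -> LogicalModel:
    """A random multi-valued logical model with ``n_inputs`` inputs."""
    rng = np.random.default_rng(seed)
    comps = []
    for i in range(n_components):
        comps.append(
            Component(
                name=f"v{i}",
                max_level=int(rng.integers(1, max_level + 1)),
                is_input=i < n_inputs,
            )
        )
    ranges = {c.name: c.max_level for c in comps}
    rules = {}
    for c in comps:
        if c.is_input:
            continue
        clauses = []
        for _ in range(int(rng.integers(1, max_clauses + 1))):
            cond = parse_expr(_random_condition(rng, comps), ranges)
            clauses.append(Clause(cond, int(rng.integers(1, c.max_level + 1))))
        rules[c.name] = Rule(c.name, tuple(clauses))
    return LogicalModel(name=f"random{seed}", components=tuple(comps), rules=rules)


def random_state(rng: np.random.Generator, model: LogicalModel) -> tuple[int, ...]:
    return tuple(int(rng.integers(0, c.max_level + 1)) for c in model.components)


def toy_grid(n_rows: int = 5, n_cols: int = 8) -> HexGrid:
    return HexGrid(n_rows, n_cols)


def toy_fields(seed: int, grid: HexGrid, model: LogicalModel) -> dict[str, np.ndarray]:
    """Random in-range input fields (internals start at zero)."""
    rng = np.random.default_rng(seed)
    fields = {}
    for c in model.components:
        if c.is_input:
            fields[c.name] = rng.integers(
                0, c.max_level + 1, size=grid.shape
            ).astype(np.int8)
    return fields
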