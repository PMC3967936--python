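"""Reading and writing logical-model files (``.ylm``).

A model file is YAML with this layout::

    schema: 1
    name: mechanistic
    components:
      - {name: Grk, max: 3, input: true}
      - {name: Aos, max: 1, delay: 2}
      - {name: Br, maintenance: true}
    derived:
      - name: X
        max: 1
        clauses:
          - {to: 1, when: "!Br & Br_adj"}
    rules:
      Aos:
        - {to: 1, when: "Pnt & !Mid", note: "working hypothesis: Pnt relays dpERK"}
    priorities: [[dpERK], [Mirr, Pnt, Rho, Aos, Br, Mid]]
    async_priorities: [[dpERK], [Mirr, Pnt, Rho, Aos, Br, Mid]]

``max`` defaults to 1 (Boolean).  Clause order is significant (first match
wins; the implicit final clause targets 0).  Round-tripping through
:func:`serialize_model` and :func:`parse_model` is lossless.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .expr import ExprError, parse_expr
from .logic_core import Clause, Component, DerivedVar, LogicalModel, ModelError, Rule

__all__ = ["parse_model", "load_model", "serialize_model", "save_model"]

SCHEMA_VERSION = 1


class ModelFileError(ModelError):
    """Located error in a model file."""

    def __init__(self, where: str, message: str):
        super().__init__(f"{where}: {message}")


def _parse_clauses(owner: str, raw, ranges, max_level) -> tuple[Clause, ...]:
    if raw is None:
        raw = []
    if not isinstance(raw, list):
        raise ModelFileError(owner, "clauses must be a list")
    clauses = []
    for k, item in enumerate(raw):
        where = f"{owner}, clause {k + 1}"
        if not isinstance(item, dict) or "when" not in item or "to" not in item:
            raise ModelFileError(where, "each clause needs 'when' and 'to'")
        try:
            cond = parse_expr(str(item["when"]), ranges)
        except ExprError as e:
            raise ModelFileError(where, str(e)) from e
        target = int(item["to"])
        if not 1 <= target <= max_level:
            raise ModelFileError(where, f"target {target} outside 1..{max_level}")
        clauses.append(Clause(cond, target, note=str(item.get("note", ""))))
    return tuple(clauses)


def parse_model(text: str, name: str | None = None) -> LogicalModel:
    """Parse and validate model-file content."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelFileError("document", "model file must be a YAML mapping")
    if int(doc.get("schema", SCHEMA_VERSION)) != SCHEMA_VERSION:
        raise ModelFileError("schema", f"unsupported schema {doc.get('schema')}")

    components = []
    for item in doc.get("components") or []:
        if isinstance(item, str):
            item = {"name": item}
        try:
            components.append(
                Component(
                    name=str(item["name"]),
                    max_level=int(item.get("max", 1)),
                    is_input=bool(item.get("input", False)),
                    delay=int(item.get("delay", 0)),
                    maintenance=bool(item.get("maintenance", False)),
                )
            )
        except KeyError:
            raise ModelFileError("components", f"component without a name: {item!r}")
    if not components:
        raise ModelFileError("components", "no components declared")

    ranges = {c.name: c.max_level for c in components}
    derived = []
    for item in doc.get("derived") or []:
        dname = str(item["name"])
        dmax = int(item.get("max", 1))
        dranges = dict(ranges)
        dranges.update({d.name: d.max_level for d in derived})
        rule = Rule(dname, _parse_clauses(f"derived {dname}", item.get("clauses"), dranges, dmax))
        derived.append(DerivedVar(dname, dmax, rule))

    full_ranges = dict(ranges)
    full_ranges.update({d.name: d.max_level for d in derived})

    rules = {}
    raw_rules = doc.get("rules") or {}
    input_names = {c.name for c in components if c.is_input}
    for cname, raw in raw_rules.items():
        if cname not in ranges:
            raise ModelFileError(f"rule {cname}", "undeclared component")
        if cname in input_names:
            raise ModelFileError(f"rule {cname}", "rules on input components are not allowed")
        rules[cname] = Rule(cname, _parse_clauses(f"rule {cname}", raw, full_ranges, ranges[cname]))

    def _classes(key):
        raw = doc.get(key) or []
        return tuple(tuple(str(n) for n in cls) for cls in raw)

    return LogicalModel(
        name=str(doc.get("name", name or "model")),
        components=tuple(components),
        rules=rules,
        derived=tuple(derived),
        priorities=_classes("priorities"),
        async_priorities=_classes("async_priorities"),
        meta=dict(doc.get("meta") or {}),
    )


def load_model(path: str | Path) -> LogicalModel:
    path = Path(path)
    return parse_model(path.read_text(), name=path.stem)


def serialize_model(model: LogicalModel) -> str:
    doc: dict = {"schema": SCHEMA_VERSION, "name": model.name}
    comps = []
    for c in model.components:
        item: dict = {"name": c.name}
        if c.max_level != 1:
            item["max"] = c.max_level
        if c.is_input:
            item["input"] = True
        if c.delay:
            item["delay"] = c.delay
        if c.maintenance:
            item["maintenance"] = True
        comps.append(item)
    doc["components"] = comps

    def _clauses(rule: Rule):
        out = []
        for cl in rule.clauses:
            item = {"to": cl.target, "when": str(cl.condition)}
            if cl.note:
                item["note"] = cl.note
            out.append(item)
        return out

    if model.derived:
        doc["derived"] = [
            {"name": d.name, "max": d.max_level, "clauses": _clauses(d.rule)}
            for d in model.derived
        ]
    doc["rules"] = {name: _clauses(model.rules[name]) for name in model.internals}
    doc["priorities"] = [list(cls) for cls in model.priorities]
    doc["async_priorities"] = [list(cls) for cls in model.async_priorities]
    if model.meta:
        doc["meta"] = model.meta
    return yaml.safe_dump(doc, sort_keys=False, width=100)


def save_model(model: LogicalModel, path: str | Path) -> None:
    Path(path).write_text(serialize_model(model))
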