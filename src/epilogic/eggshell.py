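"""The bundled eggshell-patterning models and their scenarios.

This module ties the generic machinery to the biology: it loads the two
bundled models (phenomenological and mechanistic), generates the wild-type
input fields on the cylindrical follicular epithelium, defines the region
map (R1..R12 from the realized Grk/Dpp/Mid triples), the fate table
(F1..F8), every mutant/clone scenario preset, and the reachability analyses.

Geometry conventions (all configurable through :class:`WildtypeParams`):
row 0 is anterior, the dorsal midline is a single column; Grk is a graded
dorsal-anterior field with 4 levels falling off with hex distance from a
midline source stripe; Dpp occupies an anterior band slightly wider at the
dorsal side; Mid (the posterior region) arises in the specification phase
from a posterior early-EGF field trimmed by an anterior early-BMP field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .analysis import Attractor, FateTable, attractors, build_stg, reachable_attractors
from .epithelium import Epithelium, IntegrationRule, PerturbationSpec, RunOutcome, run_to_attractor
from .hexgrid import HexGrid
from .logic_core import LogicalModel
from .modelfile import parse_model, serialize_model

__all__ = [
    "WildtypeParams",
    "phenomenological_model",
    "mechanistic_model",
    "fate_table",
    "phenomenological_fate_table",
    "wildtype_inputs",
    "region_label",
    "region_map",
    "integration_config",
    "phenom_integration_config",
    "build_epithelium",
    "Scenario",
    "preset_scenario",
    "preset_names",
    "run_scenario",
    "run_phenomenological",
    "ScenarioResult",
    "classify_pattern",
    "region_reachability_report",
    "naive_state",
]

FATE_COMPONENTS = ("dpERK", "Mirr", "Pnt", "Rho", "Aos", "Br")
DEFAULT_GRID = (24, 40)


# ---------------------------------------------------------------------------
# models


def _load(name: str) -> str:
    return resources.files("epilogic").joinpath("models", name).read_text()


def phenomenological_model() -> LogicalModel:
    """Roof/Floor/Operculum fate model over EGF, BMP, anterior, Roof_adj."""
    return parse_model(_load("phenomenological.ylm"))


def mechanistic_model(pnt_delay: bool = False) -> LogicalModel:
    """The genetic-network model.

    ``pnt_delay=True`` demotes Pnt to the slowest asynchronous urgency class
    (its activation needs isoform expression on top of phosphorylation),
    which is the delay variant used in the reachability analysis.  The
    synchronous epithelial scheme is unaffected.
    """
    model = parse_model(_load("mechanistic.ylm"))
    if pnt_delay:
        fast = ("dpERK",)
        slow = tuple(n for n in model.internals if n not in fast + ("Pnt",))
        model = LogicalModel(
            name=model.name + "+pnt_delay",
            components=model.components,
            rules=model.rules,
            derived=model.derived,
            priorities=model.priorities,
            async_priorities=(fast, slow, ("Pnt",)),
            meta=dict(model.meta),
        )
    return model


def fate_table() -> FateTable:
    """F1..F8 signatures over (dpERK, Mirr, Pnt, Rho, Aos, Br)."""
    with resources.files("epilogic").joinpath("data", "fate_table.tsv").open() as fh:
        return FateTable.from_tsv(fh, name="mechanistic_fates")


def phenomenological_fate_table() -> FateTable:
    table = {
        (0, 0, 0): "mainbody",
        (1, 0, 0): "roof",
        (0, 1, 1): "floor",
        (0, 0, 1): "operculum",
    }
    return FateTable(("Roof", "Floor", "Operculum"), table, name="phenom_fates")


# ---------------------------------------------------------------------------
# wild-type input fields


@dataclass(frozen=True)
class WildtypeParams:
    """Geometry of the wild-type input fields (defaults frozen as the golden
    configuration; fractions scale with the grid so the region census is
    grid-size robust)."""

    stripe_frac: float = 0.70  # Grk source stripe length / n_rows
    mid_frac: float = 0.54  # first Mid-positive row / n_rows
    early_egf_frac: float = 0.33  # anterior reach of the posterior early EGF field
    grk_core: int = 1  # hex distance of the peak (level 3) Grk plateau
    grk_falloff: int = 2  # cells of hex distance per Grk level lost
    dpp_rows: int = 2  # anterior Dpp band depth
    dpp_dorsal_extra: int = 1  # extra band depth near the dorsal midline
    dpp_dorsal_halfwidth: int = 6  # half-width (columns) of the dorsal widening

    def stripe_rows(self, grid: HexGrid) -> int:
        return max(2, round(self.stripe_frac * grid.n_rows))

    def mid_row(self, grid: HexGrid) -> int:
        return max(1, round(self.mid_frac * grid.n_rows))

    def early_egf_row(self, grid: HexGrid) -> int:
        return max(1, round(self.early_egf_frac * grid.n_rows))

    def midline_col(self, grid: HexGrid) -> int:
        return grid.n_cols // 2


def stripe_distance(grid: HexGrid, params: WildtypeParams) -> np.ndarray:
    """Hex distance of every cell to the Grk source stripe (multi-source BFS)."""
    c0 = params.midline_col(grid)
    sources = [(r, c0) for r in range(params.stripe_rows(grid))]
    dist = np.full(grid.shape, -1, dtype=np.int32)
    frontier = []
    for cell in sources:
        dist[cell] = 0
        frontier.append(cell)
    while frontier:
        nxt = []
        for cell in frontier:
            for nb in grid.adjacent(cell):
                if dist[nb] < 0:
                    dist[nb] = dist[cell] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def wildtype_inputs(
    grid: HexGrid, params: WildtypeParams | None = None
) -> dict[str, np.ndarray]:
    """Wild-type input fields: Grk, Dpp, early_EGF, early_BMP.

    Raises if the grid is too small to realize all 12 (Grk, Dpp, Mid)
    regions.
    """
    params = params or WildtypeParams()
    d = stripe_distance(grid, params)
    beyond = np.maximum(d - params.grk_core, 0)
    grk = np.clip(3 - (beyond + params.grk_falloff - 1) // params.grk_falloff, 0, 3)

    rows = np.arange(grid.n_rows)[:, None] * np.ones(grid.n_cols, dtype=int)[None, :]
    c0 = params.midline_col(grid)
    col_off = np.abs(np.arange(grid.n_cols) - c0)
    col_off = np.minimum(col_off, grid.n_cols - col_off)[None, :]
    dpp = (rows < params.dpp_rows) | (
        (rows < params.dpp_rows + params.dpp_dorsal_extra)
        & (col_off <= params.dpp_dorsal_halfwidth)
    )

    mid_row = params.mid_row(grid)
    early_egf = rows >= params.early_egf_row(grid)
    early_bmp = rows < mid_row

    fields = {
        "Grk": grk.astype(np.int8),
        "Dpp": dpp.astype(np.int8),
        "early_EGF": early_egf.astype(np.int8),
        "early_BMP": early_bmp.astype(np.int8),
    }
    mid = (early_egf & ~early_bmp).astype(np.int8)
    triples = {
        (int(g), int(p), int(m))
        for g, p, m in zip(grk.ravel(), fields["Dpp"].ravel(), mid.ravel())
    }
    if len(triples) != 12:
        raise ValueError(
            f"grid {grid.shape} realizes {len(triples)} (Grk,Dpp,Mid) regions, "
            "expected 12; enlarge the grid or adjust WildtypeParams"
        )
    return fields


def expected_mid(grid: HexGrid, params: WildtypeParams | None = None) -> np.ndarray:
    params = params or WildtypeParams()
    f = wildtype_inputs(grid, params)
    return ((f["early_EGF"] == 1) & (f["early_BMP"] == 0)).astype(np.int8)


def region_label(grk: int, dpp: int, mid: int) -> str | None:
    """Canonical region id for a (Grk, Dpp, Mid) triple.

    R1-R4: anterior Dpp band (Dpp=1, Mid=0), Grk 3..0;
    R5-R8: dorsal/main field (Dpp=0, Mid=0), Grk 3..0;
    R9-R12: posterior (Dpp=0, Mid=1), Grk 3..0.
    Dpp=1 with Mid=1 does not occur on the wild-type grid -> None.
    """
    if dpp == 1 and mid == 1:
        return None
    block = 0 if (dpp == 1) else (1 if mid == 0 else 2)
    return f"R{4 * block + (3 - grk) + 1}"


def shipped_region_map() -> pd.DataFrame:
    """The frozen region map of the default grid (data/region_map.tsv)."""
    with resources.files("epilogic").joinpath("data", "region_map.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def region_map(
    grid: HexGrid | None = None, params: WildtypeParams | None = None
) -> pd.DataFrame:
    """Realized regions on the wild-type grid: one row per region with its
    (Grk, Dpp, Mid) triple and cell count."""
    grid = grid or HexGrid(*DEFAULT_GRID)
    params = params or WildtypeParams()
    f = wildtype_inputs(grid, params)
    mid = expected_mid(grid, params)
    rows = {}
    for g, p, m in zip(f["Grk"].ravel(), f["Dpp"].ravel(), mid.ravel()):
        key = (int(g), int(p), int(m))
        rows[key] = rows.get(key, 0) + 1
    data = [
        {"region": region_label(*k), "Grk": k[0], "Dpp": k[1], "Mid": k[2], "n_cells": n}
        for k, n in rows.items()
    ]
    df = pd.DataFrame(data).sort_values(
        "region", key=lambda s: s.str.removeprefix("R").astype(int)
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# integration configurations


def integration_config(
    aos_thresholds: tuple[int, int] = (1, 4),
    aos_distance: int = 3,
    rho_distance: int = 1,
) -> dict[str, IntegrationRule]:
    """Neighbor integration for the mechanistic model: Rho acts short-range,
    Aos long-range, Br_adj strictly juxtacrine."""
    return {
        "Rho_ext": IntegrationRule("Rho", distance=rho_distance, kind="max"),
        "Aos_ext": IntegrationRule(
            "Aos", distance=aos_distance, kind="count", thresholds=aos_thresholds
        ),
        "Br_adj": IntegrationRule("Br", distance=1, kind="max"),
    }


def phenom_integration_config() -> dict[str, IntegrationRule]:
    return {"Roof_adj": IntegrationRule("Roof", distance=1, kind="max")}


def phenom_wildtype_inputs(
    grid: HexGrid, params: WildtypeParams | None = None
) -> dict[str, np.ndarray]:
    """EGF / BMP / anterior input fields for the phenomenological model."""
    params = params or WildtypeParams()
    d = stripe_distance(grid, params)
    lo = params.grk_core + 2 * params.grk_falloff  # outer edge of the EGF-low ring
    egf = np.where(d <= params.grk_core, 2, np.where(d <= lo, 1, 0)).astype(np.int8)
    f = wildtype_inputs(grid, params)
    anterior = (1 - expected_mid(grid, params)).astype(np.int8)
    return {"EGF": egf, "BMP": f["Dpp"], "anterior": anterior}


# ---------------------------------------------------------------------------
# scenarios


FieldTransform = Callable[[dict, HexGrid, WildtypeParams], dict]
PerturbationFactory = Callable[[HexGrid, WildtypeParams], PerturbationSpec]


@dataclass(frozen=True)
class Scenario:
    """A named simulation preset: input-field overrides plus perturbations."""

    name: str
    description: str
    field_transform: FieldTransform | None = None
    perturbations: tuple[PerturbationFactory, ...] = ()

    def build_fields(self, grid: HexGrid, params: WildtypeParams) -> dict:
        fields = wildtype_inputs(grid, params)
        if self.field_transform is not None:
            fields = self.field_transform(fields, grid, params)
        return fields

    def build_perturbations(
        self, grid: HexGrid, params: WildtypeParams
    ) -> tuple[PerturbationSpec, ...]:
        return tuple(p(grid, params) for p in self.perturbations)


def _rect_mask(grid: HexGrid, r0, r1, c0, c1) -> np.ndarray:
    """Rectangular clone mask, wrap-aware in columns ([r0,r1) x [c0,c1))."""
    mask = np.zeros(grid.shape, dtype=bool)
    cols = [(c % grid.n_cols) for c in range(c0, c1)]
    for r in range(max(r0, 0), min(r1, grid.n_rows)):
        for c in cols:
            mask[r, c] = True
    return mask


def roof_clone_mask(grid: HexGrid, params: WildtypeParams) -> np.ndarray:
    """Default clone blob overlapping the right roof patch."""
    c0 = params.midline_col(grid)
    mid_row = params.mid_row(grid)
    r0 = params.dpp_rows + 2
    return _rect_mask(grid, r0, min(r0 + 5, mid_row), c0 + 1, c0 + 5)


def midline_clone_mask(grid: HexGrid, params: WildtypeParams) -> np.ndarray:
    c0 = params.midline_col(grid)
    r0 = params.dpp_rows + 2
    return _rect_mask(grid, r0, r0 + 5, c0 - 1, c0 + 2)


def ventral_clone_mask(grid: HexGrid, params: WildtypeParams) -> np.ndarray:
    c0 = params.midline_col(grid)
    r0 = params.dpp_rows + 2
    cv = (c0 + grid.n_cols // 2) % grid.n_cols
    return _rect_mask(grid, r0, r0 + 4, cv - 2, cv + 2)


def posterior_clone_mask(grid: HexGrid, params: WildtypeParams) -> np.ndarray:
    mid_row = params.mid_row(grid)
    c0 = params.midline_col(grid)
    return _rect_mask(grid, mid_row, min(mid_row + 5, grid.n_rows), c0 - 4, c0 + 5)


def anterior_clone_mask(grid: HexGrid, params: WildtypeParams) -> np.ndarray:
    c0 = params.midline_col(grid)
    return _rect_mask(grid, 0, params.dpp_rows + 2, c0 - 5, c0 + 6)


def _clamp(component, value, mask_fn=None, name=""):
    def factory(grid: HexGrid, params: WildtypeParams) -> PerturbationSpec:
        mask = None if mask_fn is None else mask_fn(grid, params)
        return PerturbationSpec(component, "clamp", value=value, mask=mask, name=name)

    return factory


def _range(component, low, high, mask_fn=None, name=""):
    def factory(grid: HexGrid, params: WildtypeParams) -> PerturbationSpec:
        mask = None if mask_fn is None else mask_fn(grid, params)
        return PerturbationSpec(component, "range", low=low, high=high, mask=mask, name=name)

    return factory


def _grk_overexpression(fields, grid, params):
    fields = dict(fields)
    fields["Grk"] = np.full(grid.shape, 3, dtype=np.int8)
    return fields


def _dpp_mild(fields, grid, params):
    """GR1-driven dpp: early BMP everywhere (Mid never forms) and a wider,
    still dorsally-biased late Dpp band (asymmetry maintained)."""
    fields = dict(fields)
    fields["early_BMP"] = np.ones(grid.shape, dtype=np.int8)
    rows = np.arange(grid.n_rows)[:, None] * np.ones(grid.n_cols, dtype=int)[None, :]
    c0 = params.midline_col(grid)
    col_off = np.abs(np.arange(grid.n_cols) - c0)
    col_off = np.minimum(col_off, grid.n_cols - col_off)[None, :]
    depth = params.dpp_rows + 2
    fields["Dpp"] = (
        (rows < depth) | ((rows < depth + 2) & (col_off <= params.dpp_dorsal_halfwidth))
    ).astype(np.int8)
    return fields


def _dpp_strong(fields, grid, params):
    """CY2-driven dpp: strong, late-only (stage 8 onward): the early phase is
    untouched, late Dpp floods the epithelium."""
    fields = dict(fields)
    fields["Dpp"] = np.ones(grid.shape, dtype=np.int8)
    return fields


def _bmp_lof_early(fields, grid, params):
    fields = dict(fields)
    fields["early_BMP"] = np.zeros(grid.shape, dtype=np.int8)
    fields["Dpp"] = np.zeros(grid.shape, dtype=np.int8)
    return fields


def _bmp_lof_late(fields, grid, params):
    fields = dict(fields)
    fields["Dpp"] = np.zeros(grid.shape, dtype=np.int8)
    return fields


def _bmp_gof_clone(fields, grid, params):
    """Constitutive BMP in a posterior-overlapping clone: early_BMP and Dpp
    both forced on inside the mask."""
    fields = dict(fields)
    mask = posterior_clone_mask(grid, params)
    for name in ("early_BMP", "Dpp"):
        arr = fields[name].copy()
        arr[mask] = 1
        fields[name] = arr
    return fields


def _combine(*transforms):
    def transform(fields, grid, params):
        for t in transforms:
            fields = t(fields, grid, params)
        return fields

    return transform


_PRESETS: dict[str, Scenario] = {}


def _register(scenario: Scenario):
    _PRESETS[scenario.name] = scenario
    return scenario


_register(Scenario("WT", "wild type: unperturbed golden configuration"))
_register(
    Scenario("GR1_dpp", "mild dpp overexpression (GR1 driver, active throughout oogenesis)", _dpp_mild)
)
_register(
    Scenario("CY2_dpp", "strong late dpp overexpression (CY2 driver, from stage 8)", _dpp_strong)
)
_register(Scenario("tub_grk", "ubiquitous grk overexpression (Tub driver)", _grk_overexpression))
_register(
    Scenario(
        "GR1_dpp_tub_grk",
        "mild dpp overexpression in a grk overexpression background",
        _combine(_grk_overexpression, _dpp_mild),
    )
)
_register(
    Scenario(
        "CY2_dpp_tub_grk",
        "strong late dpp overexpression in a grk overexpression background",
        _combine(_grk_overexpression, _dpp_strong),
    )
)
_register(Scenario("BMP_LOF_early", "BMP pathway disrupted before Mid repression (early_BMP=0, Dpp=0)", _bmp_lof_early))
_register(Scenario("BMP_LOF_late", "BMP pathway disrupted after Mid repression (Dpp=0 only)", _bmp_lof_late))
_register(Scenario("BMP_GOF_clone", "constitutive BMP pathway in a posterior clone", _bmp_gof_clone))
_register(
    Scenario(
        "Mid_LOF_clone",
        "Mid loss-of-function in a posterior clone",
        None,
        (_clamp("Mid", 0, posterior_clone_mask, "Mid LOF clone"),),
    )
)
_register(
    Scenario(
        "Mid_GOF_clone",
        "Mid overexpression in an anterior clone",
        None,
        (_clamp("Mid", 1, anterior_clone_mask, "Mid GOF clone"),),
    )
)

# whole-epithelium mutants for the six core components plus X
for comp, gof in [
    ("Aos", _clamp("Aos", 1)),
    ("Br", _clamp("Br", 1)),
    ("Mirr", _clamp("Mirr", 1)),
    ("Pnt", _clamp("Pnt", 1)),
    ("Rho", _range("Rho", 1, 2)),
    ("X", _clamp("X", 1)),
]:
    _register(Scenario(f"{comp}_LOF", f"{comp} loss-of-function (whole epithelium)", None, (_clamp(comp, 0),)))
    _register(Scenario(f"{comp}_GOF", f"{comp} ectopic expression (whole epithelium)", None, (gof,)))
_register(
    Scenario(
        "dpERK_partial_LOF",
        "partial EGFR loss-of-function: dpERK capped at level 1",
        None,
        (_range("dpERK", 0, 1),),
    )
)
_register(
    Scenario("dpERK_GOF", "constitutive EGFR activation: dpERK clamped at 2", None, (_clamp("dpERK", 2),))
)

# clone presets (masks chosen over the regions where the effect is read out)
for comp, lof_mask, gof_mask, gof in [
    ("Aos", midline_clone_mask, ventral_clone_mask, _clamp("Aos", 1, ventral_clone_mask)),
    ("Br", roof_clone_mask, midline_clone_mask, _clamp("Br", 1, midline_clone_mask)),
    ("Mirr", roof_clone_mask, ventral_clone_mask, _clamp("Mirr", 1, ventral_clone_mask)),
    ("Pnt", midline_clone_mask, roof_clone_mask, _clamp("Pnt", 1, roof_clone_mask)),
    ("Rho", midline_clone_mask, ventral_clone_mask, _clamp("Rho", 2, ventral_clone_mask)),
    ("X", roof_clone_mask, anterior_clone_mask, _clamp("X", 1, anterior_clone_mask)),
]:
    _register(
        Scenario(f"{comp}_LOF_clone", f"{comp} loss-of-function clone", None, (_clamp(comp, 0, lof_mask),))
    )
    _register(Scenario(f"{comp}_GOF_clone", f"{comp} gain-of-function clone", None, (gof,)))
_register(
    Scenario(
        "dpERK_LOF_clone",
        "EGF pathway disruption in a roof-overlapping clone",
        None,
        (_clamp("dpERK", 0, roof_clone_mask),),
    )
)
_register(
    Scenario(
        "dpERK_GOF_clone",
        "ectopic EGF pathway activation in a roof-overlapping clone",
        None,
        (_clamp("dpERK", 2, roof_clone_mask),),
    )
)


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset_scenario(name: str) -> Scenario:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None


# ---------------------------------------------------------------------------
# simulation driver


def build_epithelium(
    model: LogicalModel,
    grid: HexGrid,
    fields: Mapping[str, np.ndarray],
    perturbations: tuple[PerturbationSpec, ...] = (),
    integration: dict[str, IntegrationRule] | None = None,
) -> Epithelium:
    integ = integration if integration is not None else integration_config()
    return Epithelium(
        model=model,
        grid=grid,
        fields=dict(fields),
        integration=integ,
        perturbations=perturbations,
        phase="early",
    )


@dataclass
class ScenarioResult:
    scenario: str
    epi_pre: Epithelium
    outcome_pre: RunOutcome
    epi_post: Epithelium
    outcome_post: RunOutcome
    manifest: dict = field(default_factory=dict)


def run_scenario(
    scenario: str | Scenario,
    grid: HexGrid | None = None,
    params: WildtypeParams | None = None,
    max_ticks: int = 200,
    model: LogicalModel | None = None,
) -> ScenarioResult:
    """Run a mechanistic scenario through its three phases.

    Phase "early" establishes Mid from the early fields (one tick of the Mid
    rule); phase "pre" runs with Grk/Dpp applied until an attractor is
    reached; Grk is then extinguished grid-wide and phase "post" resumes to
    its attractor.  Cyclic attractors are legitimate outcomes (Rho GOF).
    """
    if isinstance(scenario, str):
        scenario = preset_scenario(scenario)
    grid = grid or HexGrid(*DEFAULT_GRID)
    params = params or WildtypeParams()
    model = model or mechanistic_model()
    fields = scenario.build_fields(grid, params)
    perturbations = scenario.build_perturbations(grid, params)

    # specification phase: only the early fields are visible
    spec_fields = {
        "early_EGF": fields["early_EGF"],
        "early_BMP": fields["early_BMP"],
    }
    epi = build_epithelium(model, grid, spec_fields, perturbations)
    epi.step()  # Mid rule fires once; everything else stays naive
    epi.step()  # second tick so clamped Mid clones settle

    # patterning phase: late inputs applied, early signals gone
    epi.fields["early_EGF"] = np.zeros(grid.shape, dtype=np.int8)
    epi.fields["early_BMP"] = np.zeros(grid.shape, dtype=np.int8)
    epi.fields["Grk"] = np.asarray(fields["Grk"], dtype=np.int8)
    epi.fields["Dpp"] = np.asarray(fields["Dpp"], dtype=np.int8)
    epi.phase = "pre"
    outcome_pre, _ = run_to_attractor(epi, max_ticks=max_ticks)
    epi_pre = epi.copy()

    epi.extinguish("Grk", phase="post")
    outcome_post, _ = run_to_attractor(epi, max_ticks=max_ticks)

    from . import __version__

    manifest = {
        "version": __version__,
        "scenario": scenario.name,
        "model": model.name,
        "model_hash": hashlib.sha256(serialize_model(model).encode()).hexdigest()[:16],
        "grid": list(grid.shape),
        "phases": {
            "pre": {"outcome": outcome_pre.kind, "ticks": outcome_pre.ticks, "period": outcome_pre.period},
            "post": {"outcome": outcome_post.kind, "ticks": outcome_post.ticks, "period": outcome_post.period},
        },
    }
    return ScenarioResult(scenario.name, epi_pre, outcome_pre, epi, outcome_post, manifest)


def run_phenomenological(
    grid: HexGrid | None = None,
    params: WildtypeParams | None = None,
    max_ticks: int = 60,
) -> tuple[Epithelium, RunOutcome]:
    """Wild-type run of the phenomenological epithelial model.

    A single phase: the static EGF/BMP/anterior fields are applied and the
    grid iterates to its fixed point, with Roof_adj recomputed each tick from
    the emerging Roof field.
    """
    grid = grid or HexGrid(*DEFAULT_GRID)
    params = params or WildtypeParams()
    model = phenomenological_model()
    epi = Epithelium(
        model=model,
        grid=grid,
        fields=dict(phenom_wildtype_inputs(grid, params)),
        integration=phenom_integration_config(),
        phase="pre",
    )
    outcome, _ = run_to_attractor(epi, max_ticks=max_ticks)
    return epi, outcome


# ---------------------------------------------------------------------------
# pattern classification


def _components_of(mask: np.ndarray, grid: HexGrid) -> list[set]:
    """Connected components of a boolean cell mask under hex adjacency."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for cell in grid.cells():
        if mask[cell] and not seen[cell]:
            blob = {cell}
            seen[cell] = True
            frontier = [cell]
            while frontier:
                x = frontier.pop()
                for nb in grid.adjacent(x):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        blob.add(nb)
                        frontier.append(nb)
            comps.append(blob)
    return comps


def classify_pattern(epi: Epithelium, table: FateTable | None = None):
    """Per-cell fate labels plus summary metrics of the final pattern.

    Floor is read out as the Rho=2 cells, roof as the Br-positive cells.
    """
    table = table or fate_table()
    model = epi.model
    labels = np.empty(epi.grid.shape, dtype=object)
    for cell in epi.grid.cells():
        labels[cell] = table.classify_state(model, epi.cell_state(cell))

    roof = epi.fields["Br"] >= 1
    floor = epi.fields["Rho"] == 2
    roof_patches = _components_of(roof, epi.grid)
    floor_cells = [c for c in epi.grid.cells() if floor[c]]
    touches_roof = {
        c: any(roof[nb] for nb in epi.grid.adjacent(c)) for c in floor_cells
    }
    floor_neighbor_counts = {
        c: sum(floor[nb] for nb in epi.grid.adjacent(c)) for c in floor_cells
    }
    summary = {
        "n_roof_cells": int(roof.sum()),
        "n_roof_patches": len(roof_patches),
        "roof_patch_sizes": sorted(len(p) for p in roof_patches),
        "n_floor_cells": len(floor_cells),
        "floor_all_touch_roof": all(touches_roof.values()) if floor_cells else False,
        "floor_max_floor_neighbors": max(floor_neighbor_counts.values(), default=0),
    }
    return labels, summary


# ---------------------------------------------------------------------------
# single-cell reachability on the epithelium configuration


SINGLE_CELL_INPUTS = ("Grk", "Dpp", "Aos_ext", "Rho_ext", "Br_adj")


def naive_state(model: LogicalModel, inputs: Mapping[str, int], mid: int) -> tuple:
    """All-internal-zero state with the given inputs and Mid level."""
    return model.zero_state(Mid=mid, **{k: int(v) for k, v in inputs.items()})


def _cell_inputs(epi: Epithelium, ext: Mapping[str, np.ndarray], cell) -> dict:
    levels = {}
    for name in SINGLE_CELL_INPUTS:
        arr = ext[name] if name in ext else epi.fields[name]
        levels[name] = int(arr[cell])
    return levels


def region_reachability_report(
    epi: Epithelium,
    table: FateTable | None = None,
    phase: str = "pre",
    pnt_delay: bool = False,
    epi_pre: Epithelium | None = None,
) -> pd.DataFrame:
    """Reachable fates of a cell inserted at each realized sub-region.

    ``epi`` must be an attractor configuration of the epithelial model at the
    stated phase.  For each region (distinct realized Grk/Dpp/Mid triple) and
    each realized combination of the neighbor-derived inputs (Aos_ext,
    Br_adj, Rho_ext), the asynchronous reachable attractors are computed —
    from the naive state before extinction, or, after extinction, from the
    cell fate of the previous phase (``epi_pre``) with Grk set to 0.
    """
    table = table or fate_table()
    model = mechanistic_model(pnt_delay=pnt_delay)
    ext = epi.compute_integration()
    mid = epi.fields["Mid"]
    if phase == "post" and epi_pre is None:
        raise ValueError("post-extinction reachability needs epi_pre")

    cases: dict[tuple, dict] = {}
    for cell in epi.grid.cells():
        grk = int(epi.fields["Grk"][cell]) if phase == "pre" else int(epi_pre.fields["Grk"][cell])
        triple = (grk, int(epi.fields["Dpp"][cell]), int(mid[cell]))
        region = region_label(*triple)
        if region is None:
            continue
        inputs = _cell_inputs(epi, ext, cell)
        if phase == "post":
            inputs["Grk"] = 0
            start = list(epi_pre.cell_state(cell))
            for name, v in inputs.items():
                start[model.index[name]] = v
            start[model.index["early_EGF"]] = 0
            start[model.index["early_BMP"]] = 0
            initial = tuple(start)
        else:
            initial = naive_state(model, inputs, mid=triple[2])
        key = (region, tuple(sorted(inputs.items())), initial)
        if key not in cases:
            cases[key] = {"region": region, "triple": triple, "inputs": inputs, "initial": initial, "n_cells": 0}
        cases[key]["n_cells"] += 1

    rows = []
    for case in cases.values():
        fixed = dict(case["inputs"])
        clamps = {"Mid": case["triple"][2], "early_EGF": 0, "early_BMP": 0}
        atts = reachable_attractors(
            model, fixed, case["initial"], scheme="async", clamps={**fixed, **clamps}
        )
        labels = sorted(table.classify_attractor(model, a) for a in atts)
        rows.append(
            {
                "region": case["region"],
                "Grk": case["triple"][0],
                "Dpp": case["triple"][1],
                "Mid": case["triple"][2],
                "Aos_ext": case["inputs"]["Aos_ext"],
                "Br_adj": case["inputs"]["Br_adj"],
                "Rho_ext": case["inputs"]["Rho_ext"],
                "n_cells": case["n_cells"],
                "n_attractors": len(labels),
                "fates": ",".join(labels),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["region", "Aos_ext", "Br_adj", "Rho_ext"],
        key=lambda s: s.str.removeprefix("R").astype(int) if s.name == "region" else s,
    )
    return df.reset_index(drop=True)


def single_fate_region_count(report: pd.DataFrame) -> tuple[int, dict]:
    """Number of regions whose every realized sub-region reaches exactly one
    attractor, plus the per-region maximum attractor count."""
    per_region = report.groupby("region")["n_attractors"].max().to_dict()
    n_single = sum(1 for v in per_region.values() if v == 1)
    return n_single, per_region
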