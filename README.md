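# epilogic

Multi-valued logical (Thomas) regulatory networks on hexagonal epithelial
grids, with two bundled models of dorsal eggshell patterning in the
*Drosophila* follicular epithelium.

## The problem

The two dorsal appendages of the fly eggshell arise from primordia patterned
at stage 10 of oogenesis: on each side of the dorsal midline a group of
*broad*-expressing **roof** cells is framed by a single-cell-wide line of
*rhomboid*-expressing **floor** cells. Two signals dominate the patterning —
graded EGF activity (the oocyte ligand Gurken) and an anterior band of BMP
activity (Dpp) — yet neither explains how a one-cell-wide floor forms
precisely on the operculum side of the roof border, nor why perturbations of
the BMP pathway gave seemingly conflicting results in different studies.

`epilogic` implements a discrete, hierarchical framework for this kind of
question: each cell carries the same **multi-valued logical model** (every
component takes a few levels `0..max`; an ordered clause list gives its
target level per state), and cells are coupled on a **cylindrical hexagonal
grid** through integration variables that summarize neighbor state —
juxtacrine contact signals and short/long-range paracrine fields. The
package ships

* a **phenomenological model** — roof / floor / operculum fates as direct
  logical functions of EGF, BMP, the anterior competence flag, and contact
  with a roof cell; and
* a **mechanistic model** — the genetic network (dpERK, Mirror, Pointed,
  Rhomboid, Argos, Broad, plus Midline for the posterior boundary and a
  hypothesized juxtacrine factor X emanating from roof cells), with signal
  integration nodes S (Spitz), A (Argos) and X,

together with wild-type input-field generators, a library of mutant and
clone scenarios, and single-cell analysis tools: exhaustive stable-state
enumeration, state-transition graphs, attractor identification (terminal
strongly connected components) and asynchronous reachability.

## A worked example

```python
from epilogic import eggshell

res = eggshell.run_scenario("WT")          # specification -> patterning -> extinction
print(res.outcome_pre.kind, res.outcome_post.kind)
# fixed_point fixed_point

labels, summary = eggshell.classify_pattern(res.epi_post)
print(summary)
# {'n_roof_cells': 80, 'n_roof_patches': 2, 'roof_patch_sizes': [40, 40],
#  'n_floor_cells': 29, 'floor_all_touch_roof': True,
#  'floor_max_floor_neighbors': 2}
```

The wild-type run converges in 9 ticks to two mirror-image 40-cell roof
patches flanking the dorsal midline; zeroing the Grk field (vitelline
membrane formation) and resuming converges in 5 more ticks, changing the
Rho/Pnt/Aos patterns but leaving Broad untouched. `examples/
wildtype_simulation.py` prints the fields:

```
final Broad (roof) field — two patches flanking the dorsal midline:
........................................
...............####...####..............
...............####...####..............   (10 rows)
........................................
```

Every floor cell (Rho at level 2 after extinction) touches a roof cell and
has at most two floor neighbors — the one-cell-wide L emerges from the
juxtacrine X signal amplifying EGF activity in roof-adjacent cells that
carry Rho-cleaved Spitz.

The single-cell analyses:

```python
from epilogic.analysis import enumerate_input_fates
df, census = enumerate_input_fates(
    eggshell.mechanistic_model(), eggshell.fate_table(),
    input_names=["Grk", "Dpp", "Aos_ext", "Br_adj", "Rho_ext"],
    pseudo_inputs=["Mid"], fixed={"early_EGF": 0, "early_BMP": 0})
census["n_combinations"], census["n_distinct_stable_fates"]
# (288, 8)

report = eggshell.region_reachability_report(res.epi_pre, phase="pre")
eggshell.single_fate_region_count(report)[0]
# 10   (of the 12 regions; only the roof regions R6/R7 are bistable)
```

See `examples/` for narrative scripts (attractor census, reachability,
mutant screen, writing your own model) and `epilogic --help` for the
command-line surface (`simulate`, `stable-states`, `enumerate-fates`,
`reachability`, `classify`, `fixtures`, `validate`).

## Model files

Models are plain YAML (`.ylm`, see `src/epilogic/models/`): components with
levels/delays, derived integration nodes, ordered rule clauses in a compact
expression dialect (`Name` ≡ level ≥ 1, `Name:k` ≡ level ≥ k, `Name=k`
exact, `& | !`), and priority classes. Parsing and serialization round-trip
losslessly; `epilogic validate model.ylm` reports located errors.

## Limitations

Cells are static (no proliferation, movement or geometry change); ligand
transport is discrete neighborhood integration, not diffusion; and the model
documents its own known failures (aos overexpression has no effect for want
of a second Aos level; strong late dpp overexpression loses the residual
thin Broad band seen experimentally). See `docs/methods.md` for the full
model description, update semantics and design rationale.
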