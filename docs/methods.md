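# Methods

## Logical models

A model is a set of components, each taking integer levels `0..max_level`.
Non-input components carry one rule: an ordered list of
`(condition, target_level)` clauses over atoms `comp >= k` / `comp == k`
with `& | !`; the first matching clause gives the target, none matching
gives 0. Dynamics use unit-step semantics: an unstable component moves one
level per update toward its target, never jumping. A state is stable iff
every target equals the current level — this is equivalent under both
update schemes, and the stable-state set is found by exhaustive enumeration
(refused above a 10^7-state cap; the bundled models have ≤ a few hundred
states per input combination).

**Synchronous scheme.** All unstable components step together, in ordered
priority stages: each stage computes its targets against the state left by
the previous stage. **Asynchronous scheme.** One successor per unstable
component; with *urgency classes*, only the earliest class containing an
unstable component fires. **Delays.** A component with `delay: d` moves
(synchronously) only after its target has pointed the same way for `d`
consecutive ticks; the counter resets on reversal or agreement. In the
asynchronous scheme free interleaving already covers all relative timings,
so numeric delays are ignored there and slow components are instead modeled
as a late urgency class.

*Derived variables* (S, A, X below) are instantaneous functions of the
state, re-evaluated rather than integrated — they stand for signal
transduction much faster than any transcriptional step.

## Attractors and reachability

The asynchronous state-transition graph is built by breadth-first search
from an initial state (or the whole restricted space). Attractors are the
terminal strongly connected components (networkx condensation): singletons
are stable states, larger ones oscillatory attractors. A cyclic attractor's
identity is its set of internal-component signatures, so the census of
distinct attractors is insensitive to which input combination produced it.
Reachable fates from a state are the fate labels of the attractors in its
forward closure.

## The epithelium

Cells sit on a cylinder of offset ("odd-r") hexagon rows: row 0 is
anterior, columns wrap, interior cells have six neighbors, border rows
fewer. Cells are static. All cells share one model; cell-cell signaling
enters through integration inputs recomputed each tick from the neighbors:

| input    | rule                                                        |
|----------|-------------------------------------------------------------|
| Br_adj   | 1 iff any distance-1 neighbor has Br ≥ 1                    |
| Rho_ext  | max Rho over distance-1 neighbors (2 strong, 1 weak)        |
| Aos_ext  | count of Aos⁺ cells within distance 3: ≥1 → 1, ≥4 → 2       |

One tick = (1) recompute integration inputs and the derived nodes S, A, X,
frozen for the tick; (2) dpERK stage; (3) Pnt stage; (4) all remaining
components (unit-step, honoring delays). Perturbations (clamps and range
restrictions, whole-grid or clone masks) are re-imposed after every stage
so clones are airtight against transient leaks. Runs iterate until the full
configuration — including delay counters, which otherwise fake fixed points
— repeats: period 1 is a fixed point, longer a cycle, the tick cap an
explicit "undecided".

## The mechanistic eggshell model

Inputs: early_EGF, early_BMP (specification phase), Grk (0..3), Dpp,
and the neighbor-derived Aos_ext (0..2), Rho_ext (0..2), Br_adj.
Internals: Mid, dpERK (0..2), Mirr, Pnt, Rho (0..2), Aos (delay 2),
Br (delay 2 — see below).
Derived: S = max(Rho, Rho_ext); A = strong paracrine Aos, or local Aos with
paracrine support; X = juxtacrine roof signal (non-roof cell touching a
roof cell).

The rule structure follows the documented genetics: Mid is set by posterior
early EGF unless early BMP represses it, and maintains itself; Mirr responds
to any dpERK and is repressed by Mid; Pnt needs high dpERK; Rho is an EGF
target via Mirr, repressed by Br, with level tracking dpERK; Aos follows Pnt
(a working hypothesis for its high-threshold EGF induction), repressed by
Mid, with a 2-tick delay; Br integrates Mirr activation against Pnt and Dpp
repression, plus a maintenance self-loop confined to the anterior competence
region (`Br & !Mid`) — maintenance stands for protein persistence, not
autoregulation. The dpERK table resolves the free parameters so as to
maximize the juxtacrine effect:

1. `X & (Grk:3 | Rho) → 2` — X amplifies peak Grk or the cell's own
   Rho-cleaved Spitz, overriding Aos;
2. `Grk:3 & (!A | S) → 2` — peak Grk, needing Spitz support only against
   Aos;
3. `Rho:2 & !A → 2` — autocrine hysteresis: strong own Spitz sustains full
   activity unless Aos opposes;
4. `Grk → 1` — any Grk gives at least low activity; lone paracrine Spitz
   cannot ignite the pathway.

Two timing choices matter and were forced by the dynamics. **Pnt is fast**
(its own priority stage after dpERK; the `[dpERK, Pnt]` urgency class
asynchronously): Pnt activity is MAPK phosphorylation of pre-existing
protein. Without this the dorsal midline transiently satisfies the Br rule
while dpERK passes through level 1 and acquires roof identity, and the
midline and ventral-border regions become spuriously multistable in the
reachability analysis. **Br is slow** (`delay: 2`): *br* transcription and
translation take longer than one signaling tick; without the delay, ectopic
Br appears along the cleared midline after Grk extinction, where Mirr takes
two ticks to decay.

### Wild-type input geometry

The Grk field falls off with hex distance from a dorsal-midline source
stripe: level 3 within distance 1 (a three-column core, so the post-
extinction center column is not roof-adjacent and clears — this is what
splits the high-dpERK domain into the two floor Ls), then one level per two
cells. Dpp occupies the two anterior rows, one deeper near the midline
("slightly wider at the dorsal side"). Mid arises in the specification
phase as `early_EGF & !early_BMP`: a posterior early-EGF field trimmed by
an anterior early-BMP band, so disrupting BMP *early* expands Mid (loses
roof competence) while disrupting it *late* only removes Dpp repression —
the reconciliation of the conflicting clone experiments. Fractional
parameters (stripe length 0.70·rows, Mid onset 0.54·rows, early-EGF reach
0.33·rows) scale with the grid; the 24x40 default realizes all 12
(Grk, Dpp, Mid) regions and the census is invariant under 1.5x scaling.
Region ids are canonical: R1–R4 the Dpp band (Grk 3..0), R5–R8 the main
field, R9–R12 the posterior (Mid⁺) zone.

### Fates

The eight stable internal signatures over (dpERK, Mirr, Pnt, Rho, Aos, Br)
are shipped as `data/fate_table.tsv`: F1 undifferentiated (all zero), F2
roof (Mirr⁺ Br⁺, low dpERK), F5 roof under high EGF (Pnt⁺ Aos⁺ Br⁺), F4
Br-only memory, F6 operculum-type (Mirr⁺ Rho¹ under Dpp), F8
operculum/floor (dpERK² Mirr⁺ Pnt⁺ Rho² Aos⁺), and the posterior F3/F7
(dpERK without Mirr). Patterns are classified per cell by signature; the
roof readout is Br ≥ 1, the floor readout Rho = 2 after extinction.

## What the simulations show (and do not)

All quantitative claims the package reproduces are censuses of this finite
discrete system — attractor counts, region counts, reachability counts —
plus qualitative pattern invariants (patch counts, footprints, clone
autonomy). They are exact properties of the stated rules, not statistical
estimates, and say nothing about quantitative expression levels, real-time
kinetics, or cell movement. Two deliberate deviations are documented:

* the census finds **one** distinct oscillatory attractor (a dpERK–Aos
  relaxation cycle in Br⁺ cells under peak Grk with intermediate paracrine
  Aos), fewer than the reconstruction target; every rule variant we found
  that generates more cycles breaks a harder constraint (midline stability,
  the 8-fate census, or the 10/12 reachability census);
* ectopic-Rho overexpression converges directly to its final pattern: the
  fast-Pnt stage suppresses the synchronous Br/Pnt seesaw that otherwise
  produces a (self-described artifactual) transient oscillation.

Known model failures preserved on purpose: aos overexpression does nothing
(a second, stronger Aos level would be needed); strong late dpp
overexpression (CY2-type) loses Br entirely rather than leaving a thin
band; Rho loss-of-function lets a Br line appear along the midline; X
perturbations alter the Br domain more bluntly than the target behavior
(loss leaves it unchanged, gain removes it).

## Numerical/engineering notes

State-space enumeration and STG construction are capped (default 10^7
states) and refuse rather than truncate. Stable-state sets and reports are
emitted in canonical (lexicographic) order, so repeated runs are
byte-identical; nothing in the bundled analyses is stochastic. Random
logical models (seeded) exist solely as test fixtures against brute-force
oracles. Grid fields are int8 numpy arrays; rule evaluation over the grid
is vectorized clause-by-clause with first-match-wins masking.
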