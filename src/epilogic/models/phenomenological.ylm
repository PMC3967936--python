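# Phenomenological single-cell model of dorsal eggshell patterning.
#
# Three Boolean output fates (Roof, Floor, Operculum) read four inputs:
# graded EGF activity (ternary), Boolean BMP activity, the Boolean anterior
# competence flag, and Roof_adj, which reports whether a neighboring cell has
# adopted the roof fate (juxtacrine signal).  Roof forms at intermediate EGF
# in the absence of BMP; operculum at high EGF or EGF combined with BMP;
# floor under the operculum condition plus contact with a roof cell, placing
# the single-cell-wide floor on the operculum side of the roof border.
schema: 1
name: phenomenological
components:
  - {name: EGF, max: 2, input: true}
  - {name: BMP, input: true}
  - {name: anterior, input: true}
  - {name: Roof_adj, input: true}
  - {name: Roof}
  - {name: Floor}
  - {name: Operculum}
rules:
  Roof:
    - {to: 1, when: "anterior & EGF=1 & !BMP",
       note: "intermediate EGF only; repressed by high EGF and by BMP"}
  Operculum:
    - {to: 1, when: "anterior & (EGF:2 | (EGF & BMP))",
       note: "high EGF, or EGF together with BMP"}
  Floor:
    - {to: 1, when: "anterior & (EGF:2 | (EGF & BMP)) & Roof_adj",
       note: "operculum condition plus contact with a roof cell"}
priorities: [[Roof, Floor, Operculum]]
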