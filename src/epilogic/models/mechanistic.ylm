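# Mechanistic single-cell model of dorsal eggshell patterning.
#
# Core network below the inputs: dpERK (EGF pathway activity, ternary),
# Mirr and Pnt (transcription factors responding to low and high dpERK),
# Rho (floor marker, ternary; EGF target via Mirr, repressed by Br),
# Aos (secreted EGF inhibitor, induced via Pnt, delayed), and Br (roof
# marker, BrL enhancer: activated by Mirr, repressed by Pnt and by Dpp).
# Mid defines the posterior region (early EGF) and is repressed by the
# hypothesized early BMP signal; Mirr and Aos are under negative Mid
# control.  Self-loop clauses on Br and Mid stand for protein maintenance,
# not autoregulation; Br maintenance holds within the anterior competence
# region (absence of Mid).
#
# Signal-integration nodes (instantaneous): S combines autocrine Rho/Spitz
# with paracrine Rho_ext; A combines local Aos (effective only with
# paracrine support) with long-range Aos_ext; X is the juxtacrine roof
# signal, active in a non-roof cell contacting a roof cell.  The dpERK
# clause table resolves the free parameters so as to maximize the effect
# of X: any X-carrying cell with EGF input reaches full activity.
schema: 1
name: mechanistic
components:
  - {name: early_EGF, input: true}
  - {name: early_BMP, input: true}
  - {name: Grk, max: 3, input: true}
  - {name: Dpp, input: true}
  - {name: Aos_ext, max: 2, input: true}
  - {name: Rho_ext, max: 2, input: true}
  - {name: Br_adj, input: true}
  - {name: Mid, maintenance: true}
  - {name: dpERK, max: 2}
  - {name: Mirr}
  - {name: Pnt}
  - {name: Rho, max: 2}
  - {name: Aos, delay: 2}
  # Br synthesis (transcription + translation of a large protein) takes
  # longer than one signaling tick; without this delay ectopic Br appears
  # along the cleared midline after Grk extinction.
  - {name: Br, delay: 2, maintenance: true}
derived:
  - name: S
    max: 2
    clauses:
      - {to: 2, when: "Rho:2 | Rho_ext:2", note: "strong Spitz, autocrine or paracrine"}
      - {to: 1, when: "Rho | Rho_ext"}
  - name: A
    max: 1
    clauses:
      - {to: 1, when: "Aos_ext:2 | (Aos & Aos_ext)",
         note: "local Aos needs paracrine support to inhibit EGF"}
  - name: X
    max: 1
    clauses:
      - {to: 1, when: "!Br & Br_adj",
         note: "juxtacrine roof signal in non-roof cells"}
rules:
  Mid:
    - {to: 1, when: "early_EGF & !early_BMP",
       note: "posterior early EGF induces Mid unless early BMP represses it"}
    - {to: 1, when: "Mid", note: "maintenance self-loop"}
  dpERK:
    - {to: 2, when: "X & (Grk:3 | Rho)",
       note: "juxtacrine enhancement: X amplifies peak Grk or the cell's own
              Rho-cleaved Spitz, overriding Aos opposition"}
    - {to: 2, when: "Grk:3 & (!A | S)",
       note: "peak Grk; under Aos opposition it needs Spitz support"}
    - {to: 2, when: "Rho:2 & !A",
       note: "strong autocrine Spitz sustains full activity unless Aos opposes"}
    - {to: 1, when: "Grk",
       note: "any Grk gives at least low activity; Aos gates only the high level,
              and paracrine Spitz alone cannot ignite the pathway"}
  Mirr:
    - {to: 1, when: "dpERK & !Mid", note: "responds to low dpERK; repressed by Mid"}
  Pnt:
    - {to: 1, when: "dpERK:2", note: "requires high dpERK"}
  Rho:
    - {to: 2, when: "Mirr & dpERK:2 & !Br"}
    - {to: 1, when: "Mirr & dpERK & !Br", note: "EGF target via Mirr; Br represses"}
  Aos:
    - {to: 1, when: "Pnt & !Mid",
       note: "high-dpERK induction relayed by Pnt (working hypothesis); Mid represses"}
  Br:
    - {to: 1, when: "Mirr & !Pnt & !Dpp", note: "BrL enhancer"}
    - {to: 1, when: "Br & !Mid",
       note: "maintenance self-loop within the anterior competence region"}
# dpERK (pathway activity) and Pnt (MAPK-phosphorylated effector) respond
# much faster than transcriptional changes: they form the early priority
# stages / the urgent asynchronous class.
priorities: [[dpERK], [Pnt], [Mid, Mirr, Rho, Aos, Br]]
async_priorities: [[dpERK, Pnt], [Mid, Mirr, Rho, Aos, Br]]
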