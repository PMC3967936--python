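"""In-silico mutant screen: whole-epithelium and clonal perturbations.

Runs a panel of loss- and gain-of-function scenarios and prints one summary
line per genotype (roof cell count/patches, floor cells, run outcomes).
"""

import numpy as np

from epilogic import eggshell

PANEL = [
    "WT", "Aos_LOF", "Aos_GOF", "X_LOF", "Rho_GOF", "Br_LOF",
    "GR1_dpp", "CY2_dpp", "tub_grk", "BMP_LOF_early", "BMP_LOF_late",
    "Br_LOF_clone", "Mid_LOF_clone", "Mid_GOF_clone",
]

wt_br = None
for name in PANEL:
    res = eggshell.run_scenario(name)
    _, s = eggshell.classify_pattern(res.epi_post)
    if name == "WT":
        wt_br = res.epi_post.fields["Br"].copy()
    br_as_wt = "=WT" if np.array_equal(res.epi_post.fields["Br"], wt_br) else "   "
    print(
        f"{name:16s} pre:{res.outcome_pre.kind:<11s} "
        f"roof:{s['n_roof_cells']:4d} cells /{s['n_roof_patches']} patch(es) {br_as_wt} "
        f"floor:{s['n_floor_cells']:3d}"
    )

# Reading the screen: Aos or X loss leaves the roof intact but disturbs the
# floor/EGF domain; BMP-pathway loss behaves differently before vs after the
# competence region is set (reconciling conflicting clone experiments); and
# driver-specific dpp overexpression bends the roof into a horseshoe
# (GR1) or removes it (CY2).
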