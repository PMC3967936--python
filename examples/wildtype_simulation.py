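"""Wild-type epithelial simulation, before and after Grk extinction.

Runs the mechanistic model on the 24x40 cylindrical grid through its three
phases (anterior specification, Grk-driven patterning, post-extinction) and
prints the resulting Broad (roof) and Rhomboid (floor) patterns.
"""

from epilogic import eggshell

res = eggshell.run_scenario("WT")

print("pre-extinction :", res.outcome_pre.kind, "after", res.outcome_pre.ticks, "ticks")
print("post-extinction:", res.outcome_post.kind, "after", res.outcome_post.ticks, "ticks")

labels, summary = eggshell.classify_pattern(res.epi_post)
print("\nfinal Broad (roof) field — two patches flanking the dorsal midline:")
for row in res.epi_post.fields["Br"]:
    print("".join(".#"[v] for v in row))

print("\nfinal strong-Rho (floor) field — one-cell-wide L framing each patch:")
for row in res.epi_post.fields["Rho"]:
    print("".join(".-#"[v] for v in row))

print("\nsummary:", {k: v for k, v in summary.items() if not isinstance(v, list)})
# n_roof_patches == 2 (the two appendage primordia), each floor cell touches
# a roof cell, and the floor is nowhere more than one cell wide.
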