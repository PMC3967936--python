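"""Asynchronous reachability of cell fates, region by region.

Takes the wild-type epithelium just before Grk extinction, inserts a naive
cell at every realized (region x neighbor-input) combination, and asks which
attractors it can reach when components update one at a time.
"""

from epilogic import eggshell

wt = eggshell.run_scenario("WT")
report = eggshell.region_reachability_report(wt.epi_pre, phase="pre")
n_single, per_region = eggshell.single_fate_region_count(report)

print(report.to_string(index=False))
print(f"\nregions with a single reachable fate: {n_single} / {len(per_region)}")
print("multistable regions:", sorted(r for r, n in per_region.items() if n > 1))

# Only the two roof regions (R6, R7) admit an alternative outcome; demoting
# Pnt to the slowest asynchronous class (its activation needs new isoform
# expression) removes even that:
delayed = eggshell.region_reachability_report(wt.epi_pre, phase="pre", pnt_delay=True)
n_single_d, _ = eggshell.single_fate_region_count(delayed)
print(f"with the Pnt delay: {n_single_d} / 12 regions are single-fate")
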