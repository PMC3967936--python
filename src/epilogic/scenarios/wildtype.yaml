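# Wild-type simulation on the default grid.
preset: WT
grid: [24, 40]
max_ticks: 200
out: out/wildtype
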