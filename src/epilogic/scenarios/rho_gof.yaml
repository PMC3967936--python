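# Ectopic rhomboid: Rho range-restricted to levels 1..2 grid-wide.
preset: Rho_GOF
grid: [24, 40]
max_ticks: 300
out: out/rho_gof
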