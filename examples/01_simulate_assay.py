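"""Generate a synthetic 2 x 2 factorial growth assay.

The default design: 40 fungal isolates (four multi-isolate species plus 12
singleton taxa) x 2 temperatures (5, 17 degC) x 2 media (control, litter)
x 4 replicate dishes, weighed once after 49-53 days.
"""

from psychrosap import SimulationConfig, simulate_experiment

config = SimulationConfig(seed=1)
plates, truth = simulate_experiment(config)

print(f"{len(plates)} dishes for {config.n_isolates} isolates")
print(plates.head(4).to_string(index=False))
print("\nGround truth for the first two isolates:")
print(truth.head(2).to_string(index=False))
print(
    "\ndelta_cold / delta_warm are the true saprotrophic capacities (mg/day):"
    "\nthe extra growth rate the litter medium provides at 5 and 17 degC."
)
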