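"""Cold/warm specialisation test: correlate capacities at 5 and 17 degC.

A negative correlation would indicate a temperature tradeoff (cold vs warm
specialists); a positive one, that good litter consumers are good at both
temperatures.
"""

from psychrosap import (
    SimulationConfig,
    capacity_table,
    compute_growth_rates,
    correlate_capacities,
    simulate_experiment,
)

plates, truth = simulate_experiment(SimulationConfig(seed=1))
rates = compute_growth_rates(plates)

cold = capacity_table(rates, 5.0, seed=1)
warm = capacity_table(rates, 17.0, seed=1)
res = correlate_capacities(cold, warm)

print(f"n = {res.n} isolates")
print(f"Pearson r = {res.r:.4f}, two-sided p = {res.p:.2e}")
sign = "positive: no cold/warm tradeoff" if res.r > 0 else "negative: tradeoff"
print(f"The correlation is {sign}.")
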