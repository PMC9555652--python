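"""One-way ANOVA from summary statistics plus Tukey-Kramer letters.

Reconstructs a species-level analysis from per-group (n, mean, SEM) alone --
the form results are usually published in -- and groups the species with a
compact letter display.
"""

from psychrosap import GroupSummary, anova_from_summaries, tukey_hsd

# Published capacity summaries (mg/day at 5 degC) for the four species with
# more than one isolate: mean (SEM), n.
species = [
    GroupSummary("Apiognomonia errabunda", 4, 0.3549, sem=0.0831),
    GroupSummary("Ophiognomonia setacea", 6, 0.3194, sem=0.0678),
    GroupSummary("Cladosporium herbarum", 3, 0.1637, sem=0.0959),
    GroupSummary("Ophiognomonia sp.", 15, 0.0668, sem=0.0429),
]

anova = anova_from_summaries(species)
print(anova.to_frame().to_string(index=False))
print(f"\namong-species share of total SS: {anova.percent_among:.0f}%")
print(f"within-species share:            {anova.percent_within:.0f}%")

tukey = tukey_hsd(species, ms_within=anova["within"].ms,
                  df_within=anova["within"].df, alpha=0.05)
print(f"\nTukey-Kramer letters (q_crit {tukey.q_critical:.3f}):")
for label, letters in tukey.letters.items():
    print(f"  {label:28s} {letters}")
print("\nSpecies sharing a letter do not differ significantly at alpha=0.05.")
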