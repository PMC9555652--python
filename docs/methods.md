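# Methods

## The assay and its model

The package analyses a 2 × 2 factorial endpoint growth assay: each fungal
isolate is grown at a cold and a warm temperature on a control medium
(starter glucose) and a litter medium (starter glucose plus ground leaf
litter), with replicate dishes per cell, and each dish is weighed once after
several weeks. The implicit growth model is linear accumulation of biomass:
a dish's dry weight after t days is (μ + δ·𝟙[litter] + ε)·t, where μ is the
isolate's control growth rate at that temperature, δ its saprotrophic
capacity (the additive rate gain from litter), and ε replicate noise. All
rates are carried in mg·day⁻¹; with ~50-day incubations and ≤0.02 g mycelia
this puts capacities in the 0.05–0.45 range. The published tables the worked
examples rebuild are unit-silent; mg·day⁻¹ is this package's choice, made
because it renders those magnitudes plausible, not a fact of the source
assay.

## Capacity bootstrap

Litter and control replicates are unpaired, so the capacity estimator
enumerates all n_L × n_C ordered differences L_i − C_j (litter-major order)
and resamples k of them with replacement, n_boot times, recording each
resample's mean. Defaults: k = n_L (4), n_boot = 1000. The estimate is the
mean and SD (denominator n_boot − 1) of the resample means and their
percentile 95% CI, with quantiles taken by linear interpolation between
order statistics (`numpy.quantile` default). A normal-approximation CI
(mean ± z·SD) and a one-sided lower bound are available because the original
procedure's interval type is not fully specified; the percentile two-sided
interval is the default and the conservative classification rule is strict:
an isolate is psychrotolerant iff ci_low > 0, so an interval touching zero
does not count.

Because the mean of all pairwise differences equals mean(L) − mean(C), the
bootstrap mean is a consistent estimate of the capacity; the resample
distribution converges to the exhaustive enumeration over all k-tuples of
differences, which the tests verify directly at k = 2.

Per-isolate RNG streams are derived from the master seed and a CRC-32 of the
isolate id (`SeedSequence([seed, crc32(id)])`), making the capacity table
invariant to input row order; replicate rows are additionally sorted into a
canonical (medium, replicate) order before differencing.

## Variance partitioning

The bootstrap yields per-isolate summaries, not raw differences, so the
among-isolate ANOVA is computed from summary statistics:
SS_within = Σ(nᵢ−1)sᵢ², SS_among = Σnᵢ(mᵢ − m̄)² with m̄ the n-weighted grand
mean, df = (k−1, N−k), F = MS_among/MS_within, p from the upper F tail, and
the partition reported as percent of total SS. Feeding each isolate's
bootstrap mean and SD with n = 4 dish replicates mirrors the summary-ANOVA
procedure the capacity bootstrap was designed to feed, but note the caveat:
the bootstrap SD describes the resampled mean-of-4, not the raw replicate
spread, so the within-isolate stratum is roughly a factor √4 narrower than a
replicate-level ANOVA would give and the among-isolate share is
correspondingly inflated. This is a faithful-reproduction choice, kept
because it is the procedure the summary statistics exist for.

`anova_raw` implements the conventional one-way decomposition directly from
deviations; it is used for the species-level analysis (isolates as
replicates within multi-isolate species) and doubles as the independent
check that the summary route is exact, not approximate: the two agree to
1e−10 relative on random instances, and F/p match `scipy.stats.f_oneway`.

Degenerate inputs are flagged rather than rejected: zero within-group
variance with among-group signal reports F = ∞, p = 0; zero total SS reports
NaN F and percentages.

## Tukey–Kramer grouping

Species comparisons use the Tukey–Kramer statistic for unequal group sizes,
q_ij = |mᵢ − mⱼ| / √((MS_within/2)(1/nᵢ + 1/nⱼ)), against the
studentized-range quantile q(α; k, df_within) from
`scipy.stats.studentized_range`; adjusted p-values are its upper tail at
q_ij. The original species table has n = 4, 6, 3, 15 and does not state how
unequal sizes were handled; Tukey–Kramer is the standard resolution. The
compact letter display uses insert-and-absorb: start with one letter set
holding all groups, split any set containing a significantly different pair,
absorb subsets and duplicates, with groups processed in descending-mean
order (ties by label) so the output is deterministic. Letters are a clique
cover of the non-significance graph: two groups share a letter iff their
comparison is non-significant — verified property-wise in the tests.

## Temperature-specialization correlation

Capacities at the two temperatures are paired per isolate on the bootstrap
means (the simple difference of means coincides in expectation) and
correlated with Pearson's r via `scipy.stats.pearsonr`; the two-sided p is
the exact t transform on n − 2 df. Mismatched isolate sets are an error
reporting the symmetric difference, not silently intersected.

## Synthetic-data generator

`simulate_experiment` draws per-isolate (μ_cold, μ_warm) control rates
(normal, clipped at 0) and per-isolate capacities (δ_cold, δ_warm) from a
bivariate normal with species-specific means/SDs and a configurable
cross-temperature correlation ρ; dish weights are
max(0, (rate + ε)·days)/1000 g with ε ~ N(0, σ_rep) drawn per dish. Noise
acts on the rate scale and is multiplied by elapsed days, so the 49–53-day
jitter between incubation sets (isolates are grouped into 8 sets sharing an
endpoint day) does not bias recovered rates. Negative weights are truncated
to zero (a balance cannot read a negative mass) and truncations are logged.

Default conditions reproduce the original design: 40 isolates — four
multi-isolate species of 4, 6, 3 and 15 isolates plus 12 singleton taxa —
2 temperatures (5/17 °C), 2 media, 4 replicates. Cold-capacity species means
(0.355, 0.319, 0.164, 0.067 mg·day⁻¹) come from the published species table;
the within-species capacity SD of 0.166 mg·day⁻¹ is that table's SEM·√n,
which is ≈0.166 for all four species. σ_rep = 0.09 mg·day⁻¹ is
back-calculated from the published within-isolate mean square (0.00416 ≈
mean bootstrap-SD²; the bootstrap SD of a mean of 4 differences is ≈
sd(differences)/2 = σ_rep/√2). ρ defaults to 0.55, the order of the reported
cross-temperature correlation. Warm-capacity means are set at roughly twice
the cold means (growth is faster at 17 °C); control rates default to
0.15/0.40 mg·day⁻¹ at cold/warm.

What the generator does **not** emulate: set-to-set batch effects beyond the
shared endpoint day, heteroscedastic noise (real plate noise likely scales
with growth rate), non-normal capacity distributions, and any site or
elevation structure (the `site` column is plumbing only). One consequence to
be aware of: because species means are themselves aligned across
temperatures, the observed cross-temperature correlation over all 40 default
isolates (~0.6–0.8 across seeds) exceeds the isolate-level ρ = 0.55 — the
species structure adds a between-species correlation component. Under the
default conditions typically 25–28 of 40 isolates classify as
psychrotolerant, fewer than a real assay in which most isolates grow on
litter, because the smallest-capacity species (mean 0.067, SD 0.166) puts
many true capacities near or below zero. Passing tests on this generator
demonstrate correctness of the estimators and classifier under the stated
model, not that any particular field result is expected.

## Operating characteristics (computed by tests and acceptance script)

- **Null false-positive rate.** With δ ≡ 0, the strict CI rule flags ≈7–9%
  of 500 simulated isolates. The nominal one-sided error of a two-sided 95%
  interval is 2.5%; the excess is the known anticonservatism of a percentile
  bootstrap built on 4 + 4 replicates. The suite asserts ≤10%.
- **Power.** At δ_cold = 10·σ_rep, essentially every one of 200 simulated
  isolates is detected (asserted ≥95%).
- **Correlation recovery.** With small replicate noise, the pipeline's r̂
  recovers the generating ρ within 0.15 at 200 isolates (typically within
  0.03).

## Problem sizes and determinism

Simulation-based tests use 200–500 isolates with n_boot = 1000 — large
enough for stable Monte-Carlo rates, small enough that the whole suite runs
in seconds. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; hypothesis runs derandomized. Re-running the
pipeline with one config is byte-identical, including the JSON summary.

## Known limitations

- The among-isolate ANOVA inherits the bootstrap-SD caveat above; its
  within-isolate percentage understates replicate-level noise.
- The percentile CI with 4 + 4 replicates undercovers; the classification is
  a screening rule, not a calibrated 2.5% test.
- Reproduction of the original raw per-dish data requires the deposited data
  set converted to the plate CSV schema at `data/deposited/plate_data.csv`;
  it is not redistributed here, and the corresponding reproduction test
  fails until it is supplied.
- Single endpoint weights only: no time-course fitting, no colony-area
  metrics, no mixed models or site covariates.
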