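"""Synthetic plate-level dry-weight tables with known ground truth.

Emulates a 2 x 2 factorial growth assay: n isolates, each grown at two
temperatures on control and litter media with replicate dishes, weighed once
after ~50 days. Each isolate has a true control growth rate per temperature
and a true saprotrophic capacity (the additive litter effect) per
temperature; the capacity pair (cold, warm) is drawn from a bivariate normal
with a configurable cross-temperature correlation. Replicate noise acts on
the growth-rate scale and is multiplied by the elapsed days, so jitter in
incubation length (different experimental sets run 49-53 days) does not bias
the recovered rates. Dry weights are truncated at zero, as a balance cannot
read a negative mass; truncation events are logged.

The default configuration reproduces the structure of the original assay:
40 isolates in four multi-isolate species (4, 6, 3 and 15 isolates) plus 12
singleton taxa, temperatures 5 and 17 degC, 4 replicate dishes per cell,
8 sets incubated 49-53 days. Capacity means and spreads are calibrated so
that capacities fall in the 0.05-0.45 mg/day range typical of ~50-day,
<= 0.02 g mycelia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Documented default master seed for the generator.
DEFAULT_SEED = 20221012

_SITES = ("DevilsKitchen", "SlateCanyon")


@dataclass(frozen=True)
class SpeciesSpec:
    """True capacity distribution for the isolates of one species.

    ``delta_cold``/``delta_warm`` are the species-level mean capacities
    (mg/day) at the cold and warm temperature; ``delta_sd_cold``/``_warm``
    the among-isolate SD within the species.
    """

    label: str
    n_isolates: int
    delta_cold: float
    delta_warm: float
    delta_sd_cold: float = 0.166
    delta_sd_warm: float = 0.25

    def __post_init__(self):
        if self.n_isolates < 1:
            raise ValueError(f"species {self.label!r}: n_isolates must be >= 1")
        if self.delta_sd_cold < 0 or self.delta_sd_warm < 0:
            raise ValueError(f"species {self.label!r}: delta SDs must be >= 0")


def _default_species() -> tuple[SpeciesSpec, ...]:
    # Four multi-isolate species (sizes 4/6/3/15) plus 12 singleton taxa.
    singles = tuple(
        SpeciesSpec(f"singleton_{i+1:02d}", 1, 0.25, 0.50, 0.25, 0.35)
        for i in range(12)
    )
    return (
        SpeciesSpec("species_A", 4, 0.355, 0.70),
        SpeciesSpec("species_B", 6, 0.319, 0.65),
        SpeciesSpec("species_C", 3, 0.164, 0.35),
        SpeciesSpec("species_D", 15, 0.067, 0.15),
    ) + singles


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the original assay design."""

    species: tuple[SpeciesSpec, ...] = field(default_factory=_default_species)
    temperatures: tuple[float, float] = (5.0, 17.0)  # (cold, warm) degC
    replicates_per_cell: int = 4
    elapsed_days_range: tuple[int, int] = (49, 53)
    n_sets: int = 8  # isolates are incubated in sets sharing an endpoint day
    sigma_rep: float = 0.09  # replicate noise SD on the rate scale, mg/day
    rho: float = 0.55  # corr(delta_cold, delta_warm) across isolates
    mu_control_cold: float = 0.15  # mean control growth rate at cold T, mg/day
    mu_control_warm: float = 0.40
    mu_control_sd: float = 0.05  # among-isolate SD of control rates
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not self.species:
            raise ValueError("at least one species is required")
        if self.n_isolates < 1:
            raise ValueError("n_isolates must be >= 1")
        if self.replicates_per_cell < 2:
            raise ValueError(
                f"replicates_per_cell must be >= 2, got {self.replicates_per_cell}"
            )
        lo, hi = self.elapsed_days_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid elapsed_days_range {self.elapsed_days_range}")
        if self.sigma_rep < 0:
            raise ValueError(f"sigma_rep must be >= 0, got {self.sigma_rep}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")
        if len(self.temperatures) != 2:
            raise ValueError("exactly two temperatures (cold, warm) are expected")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")

    @property
    def n_isolates(self) -> int:
        return sum(s.n_isolates for s in self.species)

    @classmethod
    def uniform(
        cls,
        n_isolates: int,
        delta_cold: float = 0.0,
        delta_warm: float = 0.0,
        delta_sd_cold: float = 0.0,
        delta_sd_warm: float = 0.0,
        **kwargs,
    ) -> "SimulationConfig":
        """Single-species configuration, handy for null/power simulations."""
        spec = SpeciesSpec(
            "species_U", n_isolates, delta_cold, delta_warm,
            delta_sd_cold, delta_sd_warm,
        )
        return cls(species=(spec,), **kwargs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one simulated isolate."""

    isolate_id: str
    species_label: str
    mu_control_cold: float
    mu_control_warm: float
    delta_cold: float
    delta_warm: float
    sigma_rep: float
    rho: float


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic experiment.

    Returns
    -------
    (plates, truth)
        ``plates`` has one row per dish (columns: isolate_id, species, site,
        temperature_c, medium, replicate, dry_weight_g, elapsed_days) with
        exactly ``n_isolates * 2 temperatures * 2 media * replicates`` rows.
        ``truth`` has one row per isolate with the generating parameters.
        The same config (same seed) always yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    cold_t, warm_t = config.temperatures
    n = config.n_isolates

    # per-isolate true parameters
    labels: list[str] = []
    species_of: list[str] = []
    for spec in config.species:
        for i in range(spec.n_isolates):
            labels.append(f"{spec.label}.{i + 1}")
            species_of.append(spec.label)

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    z_warm = config.rho * z1 + np.sqrt(1.0 - config.rho**2) * z2

    delta_cold = np.empty(n)
    delta_warm = np.empty(n)
    pos = 0
    for spec in config.species:
        sl = slice(pos, pos + spec.n_isolates)
        delta_cold[sl] = spec.delta_cold + spec.delta_sd_cold * z1[sl]
        delta_warm[sl] = spec.delta_warm + spec.delta_sd_warm * z_warm[sl]
        pos += spec.n_isolates

    mu_cold = np.clip(
        rng.normal(config.mu_control_cold, config.mu_control_sd, size=n), 0.0, None
    )
    mu_warm = np.clip(
        rng.normal(config.mu_control_warm, config.mu_control_sd, size=n), 0.0, None
    )

    # incubation sets share an endpoint day in the configured range
    lo, hi = config.elapsed_days_range
    day_choices = np.arange(lo, hi + 1)
    set_of = np.arange(n) % config.n_sets
    set_days = day_choices[
        rng.integers(0, day_choices.size, size=config.n_sets)
    ]
    days_of = set_days[set_of]
    site_of = [_SITES[i % len(_SITES)] for i in range(n)]

    rows: list[dict] = []
    n_truncated = 0
    for i in range(n):
        for temp, mu, delta in (
            (cold_t, mu_cold[i], delta_cold[i]),
            (warm_t, mu_warm[i], delta_warm[i]),
        ):
            for medium in ("control", "litter"):
                true_rate = mu + (delta if medium == "litter" else 0.0)
                for rep in range(1, config.replicates_per_cell + 1):
                    noise = rng.normal(0.0, config.sigma_rep)
                    weight_mg = (true_rate + noise) * days_of[i]
                    if weight_mg < 0.0:
                        n_truncated += 1
                        weight_mg = 0.0
                    rows.append({
                        "isolate_id": labels[i],
                        "species": species_of[i],
                        "site": site_of[i],
                        "temperature_c": float(temp),
                        "medium": medium,
                        "replicate": rep,
                        "dry_weight_g": weight_mg / 1000.0,
                        "elapsed_days": int(days_of[i]),
                    })
    if n_truncated:
        logger.info("truncated %d negative dry weights to 0", n_truncated)

    truth = pd.DataFrame([
        asdict(SyntheticTruth(
            isolate_id=labels[i],
            species_label=species_of[i],
            mu_control_cold=float(mu_cold[i]),
            mu_control_warm=float(mu_warm[i]),
            delta_cold=float(delta_cold[i]),
            delta_warm=float(delta_warm[i]),
            sigma_rep=config.sigma_rep,
            rho=config.rho,
        ))
        for i in range(n)
    ])
    return pd.DataFrame(rows), truth
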