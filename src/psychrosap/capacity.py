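"""Bootstrapped saprotrophic capacity of an isolate at one temperature.

Saprotrophic capacity is the difference between an isolate's biomass growth
rate on litter-containing medium and on control (glucose-only) medium.
Replicate dishes on the two media are unpaired, so the uncertainty of the
difference is obtained by an unpaired bootstrap: all n_L x n_C pairwise
litter-minus-control differences are enumerated, then resampled with
replacement in groups of k (default: the number of litter replicates, 4).
The mean, SD and percentile 95% confidence interval of the resample means
summarise the capacity. An isolate whose CI at the cold temperature lies
strictly above zero is classified psychrotolerant.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Resamples per bootstrap distribution.
DEFAULT_N_BOOT = 1000

#: Master seed used when the caller does not provide one.
DEFAULT_SEED = 20221012


@dataclass(frozen=True)
class BootstrapResult:
    """Summary of one bootstrap distribution of the capacity statistic."""

    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    n_boot: int
    k: int


@dataclass(frozen=True)
class CapacityEstimate:
    """Per isolate x temperature capacity estimate with classification.

    ``psychrotolerant`` is ``ci_low > 0``; it is scientifically meaningful
    when ``temperature`` is the cold assay temperature (5 degC in the
    original design) but is computed for every temperature.
    """

    isolate_id: str
    temperature: float
    boot_mean: float
    boot_sd: float
    ci_low: float
    ci_high: float
    n_litter: int
    n_control: int
    n_boot: int
    seed: int
    psychrotolerant: bool


def pairwise_differences(
    litter_rates: np.ndarray | list[float],
    control_rates: np.ndarray | list[float],
) -> np.ndarray:
    """All ordered litter-minus-control rate differences, litter-major.

    For n_L litter and n_C control replicates the result has n_L * n_C
    entries ``L_i - C_j`` ordered as (L_0-C_0, L_0-C_1, ..., L_1-C_0, ...);
    with 4 + 4 replicates this is the 16-difference set the capacity
    bootstrap resamples.
    """
    litter = np.asarray(litter_rates, dtype=float)
    control = np.asarray(control_rates, dtype=float)
    if litter.size == 0 or control.size == 0:
        raise ValueError("litter and control rate lists must be non-empty")
    return np.subtract.outer(litter, control).ravel()


def bootstrap_capacity(
    differences: np.ndarray | list[float],
    k: int | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = DEFAULT_SEED,
    ci_method: str = "percentile",
    ci_level: float = 0.95,
    one_sided: bool = False,
) -> BootstrapResult:
    """Bootstrap the mean of ``k`` differences drawn with replacement.

    Parameters
    ----------
    differences
        The enumerated pairwise differences (mg/day).
    k
        Resample size per draw; defaults to ``sqrt(len(differences))``
        rounded, i.e. the litter replicate count when the difference set is
        the full n x n cross (4 for the 16-difference design).
    n_boot
        Number of bootstrap draws (default 1000).
    seed
        Integer seed or a ready ``numpy.random.Generator``.
    ci_method
        ``"percentile"`` (quantiles of the resample means, linear
        interpolation between order statistics) or ``"normal"``
        (mean +/- z * SD of the resample means).
    ci_level
        Two-sided confidence level (default 0.95).
    one_sided
        If true, report a lower confidence bound at level ``ci_level``
        (``ci_high`` becomes +inf), matching a one-sided reading of
        "significantly greater than zero".

    Returns
    -------
    BootstrapResult
        Mean, SD (denominator ``n_boot - 1``) and CI of the resample means.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size == 0:
        raise ValueError("differences must be non-empty")
    if k is None:
        k = max(1, round(math.sqrt(diffs.size)))
    if k <= 0:
        raise ValueError(f"resample size k must be >= 1, got {k}")
    if n_boot <= 0:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(n_boot, k))
    boot_means = diffs[idx].mean(axis=1)

    mean = float(boot_means.mean())
    sd = float(boot_means.std(ddof=1)) if n_boot > 1 else 0.0

    alpha = 1.0 - ci_level
    if ci_method == "percentile":
        if one_sided:
            lo = float(np.quantile(boot_means, alpha))
            hi = math.inf
        else:
            lo, hi = (float(q) for q in
                      np.quantile(boot_means, [alpha / 2, 1 - alpha / 2]))
    elif ci_method == "normal":
        if one_sided:
            z = sps.norm.ppf(1 - alpha)
            lo, hi = mean - z * sd, math.inf
        else:
            z = sps.norm.ppf(1 - alpha / 2)
            lo, hi = mean - z * sd, mean + z * sd
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return BootstrapResult(boot_mean=mean, boot_sd=sd, ci_low=lo, ci_high=hi,
                           n_boot=n_boot, k=k)


def classify_psychrotolerant(estimate: CapacityEstimate | BootstrapResult) -> bool:
    """True iff the capacity CI lies strictly above zero.

    An interval touching zero is read conservatively as not significant.
    """
    return estimate.ci_low > 0.0


def _isolate_seed(master_seed: int, isolate_id: str) -> np.random.Generator:
    # CRC32 of the id keeps sub-seeding stable across row orderings and runs.
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(str(isolate_id).encode())])
    )


def capacity_table(
    rates: pd.DataFrame,
    temperature: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    ci_method: str = "percentile",
    ci_level: float = 0.95,
    one_sided: bool = False,
    k: int | None = None,
) -> pd.DataFrame:
    """Capacity estimates for every isolate at one temperature.

    Expects the growth-rate table produced by
    :func:`psychrosap.growth.compute_growth_rates`. Each isolate gets its own
    RNG stream derived from the master seed and a stable hash of its id, so
    the output is independent of input row order. Isolates missing either
    medium at the requested temperature are skipped with a logged warning.

    Returns a DataFrame with one :class:`CapacityEstimate` row per isolate,
    sorted by isolate_id.
    """
    at_temp = rates[rates["temperature_c"] == temperature]
    if at_temp.empty:
        raise ValueError(f"no growth-rate rows at temperature {temperature}")
    # canonical replicate order, so results are independent of row order
    at_temp = at_temp.sort_values(["isolate_id", "medium", "replicate"])

    records: list[dict] = []
    for isolate_id, grp in at_temp.groupby("isolate_id", sort=True):
        litter = grp.loc[grp["medium"] == "litter", "rate_mg_per_day"].to_numpy()
        control = grp.loc[grp["medium"] == "control", "rate_mg_per_day"].to_numpy()
        if litter.size == 0 or control.size == 0:
            logger.warning(
                "isolate %s lacks %s replicates at %s degC; skipped",
                isolate_id,
                "litter" if litter.size == 0 else "control",
                temperature,
            )
            continue
        diffs = pairwise_differences(litter, control)
        res = bootstrap_capacity(
            diffs,
            k=litter.size if k is None else k,
            n_boot=n_boot,
            seed=_isolate_seed(seed, isolate_id),
            ci_method=ci_method,
            ci_level=ci_level,
            one_sided=one_sided,
        )
        est = CapacityEstimate(
            isolate_id=str(isolate_id),
            temperature=float(temperature),
            boot_mean=res.boot_mean,
            boot_sd=res.boot_sd,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            n_litter=int(litter.size),
            n_control=int(control.size),
            n_boot=n_boot,
            seed=seed,
            psychrotolerant=classify_psychrotolerant(res),
        )
        records.append(asdict(est))

    if not records:
        raise ValueError(
            f"no isolate at {temperature} degC had both media represented"
        )
    return pd.DataFrame.from_records(records)
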