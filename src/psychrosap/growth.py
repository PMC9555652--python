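"""Endpoint biomass growth rates from plate dry weights.

Rate = (DW2 - DW1) / elapsed_days, with the initial mycelium dry weight DW1
assumed 0 unless a ``dry_weight_initial_g`` column is present (the inoculum
plug weighs less than the balance's 0.0001 g resolution). Rates are reported
in mg/day.
"""

from __future__ import annotations

import pandas as pd

#: Columns a plate table must provide.
REQUIRED_COLUMNS = (
    "isolate_id",
    "temperature_c",
    "medium",
    "replicate",
    "dry_weight_g",
    "elapsed_days",
)

#: Factorial coordinates that must be unique within a plate table.
KEY_COLUMNS = ("isolate_id", "temperature_c", "medium", "replicate")

VALID_MEDIA = frozenset({"control", "litter"})

MG_PER_G = 1000.0


def compute_growth_rates(observations: pd.DataFrame) -> pd.DataFrame:
    """Convert a plate-observation table into per-dish growth rates.

    Parameters
    ----------
    observations
        One row per dish with columns :data:`REQUIRED_COLUMNS`; an optional
        ``dry_weight_initial_g`` column (default 0) and pass-through
        ``species`` / ``site`` columns are honoured.

    Returns
    -------
    pandas.DataFrame
        One row per input row with ``rate_mg_per_day`` appended; dry-weight
        columns are dropped.

    Raises
    ------
    ValueError
        On missing columns, non-positive elapsed days, negative final dry
        weights, unknown media, or duplicated factorial coordinates (the
        offending key is reported).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"plate table is missing columns: {missing}")

    obs = observations.copy()

    bad_days = obs["elapsed_days"] <= 0
    if bad_days.any():
        raise ValueError(
            f"elapsed_days must be > 0; offending rows: "
            f"{obs.index[bad_days].tolist()}"
        )
    if (obs["dry_weight_g"] < 0).any():
        raise ValueError("dry_weight_g must be >= 0")
    bad_media = set(obs["medium"]) - VALID_MEDIA
    if bad_media:
        raise ValueError(f"unknown media {sorted(bad_media)}; expected control/litter")

    dup = obs.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        keys = (
            obs.loc[dup, list(KEY_COLUMNS)]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValueError(f"duplicate factorial coordinates: {keys}")

    dw1 = obs.get("dry_weight_initial_g", 0.0)
    obs["rate_mg_per_day"] = (
        (obs["dry_weight_g"] - dw1) * MG_PER_G / obs["elapsed_days"]
    )

    keep = [c for c in ("species", "site") if c in obs.columns]
    cols = ["isolate_id", *keep, "temperature_c", "medium", "replicate",
            "rate_mg_per_day"]
    return obs[cols].reset_index(drop=True)
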