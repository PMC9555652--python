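import pandas as pd
import pytest
from hypothesis import settings

from psychrosap.stats import GroupSummary

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def printed_species_summaries() -> list[GroupSummary]:
    """Published per-species capacity summaries (mg/day) at 5 degC:
    mean (SEM) with isolate counts 4/6/3/15."""
    return [
        GroupSummary("Apiognomonia errabunda", 4, 0.3549, sem=0.0831),
        GroupSummary("Ophiognomonia setacea", 6, 0.3194, sem=0.0678),
        GroupSummary("Cladosporium herbarum", 3, 0.1637, sem=0.0959),
        GroupSummary("Ophiognomonia sp.", 15, 0.0668, sem=0.0429),
    ]


@pytest.fixture
def small_plate_table() -> pd.DataFrame:
    """Two isolates x one temperature x two media x two replicates."""
    rows = []
    weights = {
        ("iso1", "control"): (0.0050, 0.0060),
        ("iso1", "litter"): (0.0150, 0.0160),
        ("iso2", "control"): (0.0040, 0.0040),
        ("iso2", "litter"): (0.0045, 0.0035),
    }
    for (iso, medium), (w1, w2) in weights.items():
        for rep, w in enumerate((w1, w2), start=1):
            rows.append({
                "isolate_id": iso,
                "temperature_c": 5.0,
                "medium": medium,
                "replicate": rep,
                "dry_weight_g": w,
                "elapsed_days": 50,
            })
    return pd.DataFrame(rows)
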