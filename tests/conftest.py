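import numpy as np
import pandas as pd
import pytest

from vrtpipe.categories import CATEGORY_LABELS
from vrtpipe.simulate import default_calibration, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort of 60 participants, fixed seed."""
    cfg = default_calibration()
    cfg.n_participants = 60
    return simulate_cohort(cfg, seed=12345)


def make_trials(latencies_by_category: dict, participant_id: str = "P1") -> pd.DataFrame:
    """Build a trial table from {category: [latencies (None = missing)]}."""
    rows = []
    idx = 0
    for cat, lats in latencies_by_category.items():
        for lat in lats:
            rows.append(
                {
                    "participant_id": participant_id,
                    "sex": cat[0],
                    "tanner": int(cat[2]),
                    "trial_index": idx,
                    "latency_ms": np.nan if lat is None else float(lat),
                    "rating": np.nan if lat is None else 1.0,
                    "category": cat,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def make_profile(means: dict, participant_id: str = "P1", basis: str = "ipsatized") -> pd.DataFrame:
    """Profile table with one mean per category on the chosen basis."""
    col = "mean_ipsatized" if basis == "ipsatized" else "mean_raw_ms"
    other = "mean_raw_ms" if basis == "ipsatized" else "mean_ipsatized"
    rows = []
    for cat in CATEGORY_LABELS:
        rows.append(
            {
                "participant_id": participant_id,
                "category": cat,
                col: means[cat],
                other: np.nan if cat not in means else means[cat],
                "n_valid": 8,
                "n_missing": 0,
            }
        )
    return pd.DataFrame(rows)
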