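"""CSV reading/writing and validation of trial and participant tables.

Trials CSV columns: participant_id, sex, tanner, trial_index, latency_ms,
rating.  An empty latency cell marks a non-response trial (the stimulus
timed out at 5000 ms); such trials record neither latency nor rating.

Participants CSV columns: participant_id, pedohebephilia, cso, csam,
days_interview_to_vrt.  Flags are coded 0/1 with an empty cell for
"unknown"; unknown diagnosis later excludes the participant from inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import CATEGORY_LABELS, StimulusCategory

MAX_LATENCY_MS = 5000.0

TRIAL_COLUMNS = ["participant_id", "sex", "tanner", "trial_index", "latency_ms", "rating"]
PARTICIPANT_COLUMNS = ["participant_id", "pedohebephilia", "cso", "csam", "days_interview_to_vrt"]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table in place, raising on paradigm violations.

    Raises ``ValueError`` naming the offending row for: unknown category
    codes, latencies outside (0, 5000], or trials where exactly one of
    latency/rating is missing (a non-response records neither).
    """
    missing_cols = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing_cols:
        raise ValueError(f"trials table lacks required columns: {missing_cols}")

    sex = trials["sex"].astype(str).str.upper()
    bad_sex = ~sex.isin(["M", "F"])
    if bad_sex.any():
        row = trials.index[bad_sex][0]
        raise ValueError(f"row {row}: unknown sex code {trials.loc[row, 'sex']!r}")
    tanner = pd.to_numeric(trials["tanner"], errors="coerce")
    bad_t = ~tanner.isin([1, 2, 3, 4, 5])
    if bad_t.any():
        row = trials.index[bad_t][0]
        raise ValueError(f"row {row}: Tanner stage {trials.loc[row, 'tanner']!r} outside 1-5")

    lat = pd.to_numeric(trials["latency_ms"], errors="coerce")
    rat = pd.to_numeric(trials["rating"], errors="coerce")
    too_slow = lat > MAX_LATENCY_MS
    if too_slow.any():
        row = trials.index[too_slow][0]
        raise ValueError(
            f"row {row}: latency {lat[row]} ms exceeds the 5000 ms response window; "
            "such trials must be recorded as missing"
        )
    nonpos = lat <= 0
    if nonpos.any():
        row = trials.index[nonpos][0]
        raise ValueError(f"row {row}: non-positive latency {lat[row]}")
    half = lat.isna() != rat.isna()
    if half.any():
        row = trials.index[half][0]
        raise ValueError(
            f"row {row}: latency and rating must be missing together (non-response trial)"
        )
    bad_rating = rat.notna() & ~rat.isin([1, 2, 3, 4])
    if bad_rating.any():
        row = trials.index[bad_rating][0]
        raise ValueError(f"row {row}: rating {trials.loc[row, 'rating']!r} outside 1-4")

    out = trials.copy()
    out["sex"] = sex
    out["tanner"] = tanner.astype(int)
    out["latency_ms"] = lat
    out["rating"] = rat
    out["trial_index"] = pd.to_numeric(out["trial_index"]).astype(int)
    out["participant_id"] = out["participant_id"].astype(str)
    out["category"] = out["sex"] + "T" + out["tanner"].astype(str)
    return out


def read_trials(path, *, sep: str = ",", na_values=("", "NA")) -> pd.DataFrame:
    """Read and validate a trials CSV.

    Empty cells (or the configured sentinel) in latency_ms/rating mark
    non-response trials.  Returns the validated table with an added
    ``category`` label column.
    """
    raw = pd.read_csv(path, sep=sep, na_values=list(na_values), keep_default_na=False)
    return validate_trials(raw)


def write_trials(trials: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    trials[cols].to_csv(path, index=False, na_rep="")


def _parse_flag(col: pd.Series, name: str) -> pd.Series:
    vals = pd.to_numeric(col, errors="coerce")
    bad = col.notna() & (col.astype(str).str.strip() != "") & ~vals.isin([0, 1])
    if bad.any():
        row = col.index[bad][0]
        raise ValueError(f"row {row}: flag {name} must be 0/1 or empty, got {col[row]!r}")
    return vals.map({0.0: False, 1.0: True})


def validate_participants(participants: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in PARTICIPANT_COLUMNS if c not in participants.columns]
    if missing_cols:
        raise ValueError(f"participants table lacks required columns: {missing_cols}")
    out = participants.copy()
    out["participant_id"] = out["participant_id"].astype(str)
    if out["participant_id"].duplicated().any():
        dup = out.loc[out["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"duplicate participant_id {dup!r}")
    for flag in ("pedohebephilia", "cso", "csam"):
        out[flag] = _parse_flag(out[flag], flag)
    days = pd.to_numeric(out["days_interview_to_vrt"], errors="coerce")
    if (days < 0).any():
        row = out.index[(days < 0).fillna(False)][0]
        raise ValueError(f"row {row}: negative interview-to-test interval")
    out["days_interview_to_vrt"] = days
    return out


def read_participants(path, *, sep: str = ",") -> pd.DataFrame:
    raw = pd.read_csv(path, sep=sep, na_values=[""], keep_default_na=False)
    return validate_participants(raw)


def write_participants(participants: pd.DataFrame, path) -> None:
    out = participants.copy()
    for flag in ("pedohebephilia", "cso", "csam"):
        if flag in out.columns:
            out[flag] = out[flag].map({True: 1, False: 0, 1: 1, 0: 0})
    cols = [c for c in out.columns if c in PARTICIPANT_COLUMNS or c == "latent_deviance"]
    out[cols].to_csv(path, index=False, na_rep="")


def category_of_row(sex: str, tanner: int) -> StimulusCategory:
    return StimulusCategory.from_label(f"{sex}T{tanner}")


__all__ = [
    "MAX_LATENCY_MS",
    "TRIAL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "read_trials",
    "write_trials",
    "read_participants",
    "write_participants",
    "validate_trials",
    "validate_participants",
    "CATEGORY_LABELS",
]
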