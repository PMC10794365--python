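"""Eligibility filtering of participants before scoring.

A participant is retained only if (a) no more than the tolerated fraction
of trials timed out (default: strictly more than 10% missing excludes),
(b) every one of the ten stimulus categories has at least one valid trial,
(c) the test was taken within four weeks of the clinical interview, and
(d) the clinical diagnosis is known.  Exclusion reasons are not mutually
exclusive; a participant may carry several.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .categories import CATEGORY_LABELS


class ExclusionReason(str, Enum):
    MISSING_GT_THRESHOLD = "MISSING_GT_THRESHOLD"
    EMPTY_CATEGORY = "EMPTY_CATEGORY"
    INTERVAL_GT_4W = "INTERVAL_GT_4W"
    UNKNOWN_DIAGNOSIS = "UNKNOWN_DIAGNOSIS"
    NO_VRT_DATA = "NO_VRT_DATA"


def apply_eligibility(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    *,
    threshold: float = 0.10,
    max_interval_days: int = 28,
    exclude_unknown_interval: bool = False,
) -> pd.DataFrame:
    """Build the per-participant eligibility report.

    The missingness rule is a strict inequality: a participant with a
    missing fraction exactly equal to ``threshold`` is retained.  Unknown
    interview-to-test intervals are eligible by default (exclusions were
    made on documented intervals only); set ``exclude_unknown_interval``
    to treat them as violations.

    Returns a DataFrame indexed like ``participants`` with columns
    missing_fraction, empty_categories (list of labels), interval_violation,
    reasons (list of ExclusionReason values), eligible.
    """
    unknown_trial_pids = set(trials["participant_id"]) - set(participants["participant_id"])
    if unknown_trial_pids:
        raise ValueError(
            f"trials reference participants absent from the participant table: "
            f"{sorted(unknown_trial_pids)[:5]}"
        )

    n_total = trials.groupby("participant_id").size()
    n_missing = trials.groupby("participant_id")["latency_ms"].agg(lambda s: s.isna().sum())
    valid = trials[trials["latency_ms"].notna()]
    valid_cats = valid.groupby("participant_id")["category"].agg(set)

    rows = []
    for _, p in participants.iterrows():
        pid = p["participant_id"]
        reasons: list[str] = []
        total = int(n_total.get(pid, 0))
        if total == 0:
            frac = float("nan")
            empty = list(CATEGORY_LABELS)
            reasons.append(ExclusionReason.NO_VRT_DATA.value)
        else:
            frac = float(n_missing.get(pid, 0)) / total
            if frac > threshold:  # strictly greater: exactly-at-threshold retained
                reasons.append(ExclusionReason.MISSING_GT_THRESHOLD.value)
            present = valid_cats.get(pid, set())
            empty = [c for c in CATEGORY_LABELS if c not in present]
            if empty:
                reasons.append(ExclusionReason.EMPTY_CATEGORY.value)
        days = p.get("days_interview_to_vrt")
        interval_violation = False
        if pd.isna(days):
            if exclude_unknown_interval:
                interval_violation = True
        elif days > max_interval_days:
            interval_violation = True
        if interval_violation:
            reasons.append(ExclusionReason.INTERVAL_GT_4W.value)
        if pd.isna(p.get("pedohebephilia")):
            reasons.append(ExclusionReason.UNKNOWN_DIAGNOSIS.value)
        rows.append(
            {
                "participant_id": pid,
                "missing_fraction": frac,
                "empty_categories": empty,
                "interval_violation": interval_violation,
                "reasons": reasons,
                "eligible": not reasons,
            }
        )
    return pd.DataFrame(rows)


def filter_eligible(
    trials: pd.DataFrame, participants: pd.DataFrame, report: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to participants the report marks eligible."""
    keep = set(report.loc[report["eligible"], "participant_id"])
    return (
        trials[trials["participant_id"].isin(keep)].reset_index(drop=True),
        participants[participants["participant_id"].isin(keep)].reset_index(drop=True),
    )


__all__ = ["ExclusionReason", "apply_eligibility", "filter_eligible"]
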