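"""Ipsatization and the viewing-reaction-time index.

Ipsatization here means within-person z-standardization: each participant's
valid latencies, pooled across all ten categories, are centered on their own
mean and scaled by their own SD (n-1 denominator).  This removes individual
differences in general response speed, so the resulting index is in units of
within-person SDs.  Mean-centering only (no rescaling) is available via
``mode="center"``.

The index is the difference between the maximum mean (ipsatized) latency
over the six child categories (Tanner 1-3, both sexes) and the maximum over
the four adult categories (Tanner 4-5).  A participant dwelling longer on
child stimuli than adult stimuli scores positive.  Maxima of the two sexes
are taken separately-then-maximized so that a strong interest in either sex
is not diluted by averaging over both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import ADULT_LABELS, CATEGORY_LABELS, CHILD_LABELS, StimulusCategory


def ipsatize(trials: pd.DataFrame, *, mode: str = "z") -> pd.DataFrame:
    """Add a ``latency_ips`` column of within-person standardized latencies.

    Accepts a table of one or many participants; standardization is always
    per participant over all of that participant's non-missing trials pooled
    across categories.  Missing trials stay missing.

    Raises ``ValueError`` if any participant has fewer than 2 valid trials
    or zero latency spread (degenerate latencies).
    """
    if mode not in ("z", "center"):
        raise ValueError(f"mode must be 'z' or 'center', got {mode!r}")
    grp = trials.groupby("participant_id")["latency_ms"]
    n_valid = grp.count()
    if (n_valid < 2).any():
        bad = n_valid.index[n_valid < 2][0]
        raise ValueError(f"participant {bad}: fewer than 2 valid trials, cannot ipsatize")
    mean = grp.transform("mean")
    if mode == "z":
        sd = grp.transform("std")  # ddof=1
        sd_per = grp.std()
        if (sd_per == 0).any():
            bad = sd_per.index[sd_per == 0][0]
            raise ValueError(f"participant {bad}: degenerate latencies (zero spread)")
        ips = (trials["latency_ms"] - mean) / sd
    else:
        ips = trials["latency_ms"] - mean
    out = trials.copy()
    out["latency_ips"] = ips
    return out


def category_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant per-category latency profile.

    Returns one row per (participant, category) for all ten categories, with
    mean_raw_ms, mean_ipsatized (NaN unless ``ipsatize`` ran first), n_valid
    and n_missing.  Means are NaN where a category has no valid trial.
    """
    t = trials if "latency_ips" in trials.columns else trials.assign(latency_ips=np.nan)
    g = t.groupby(["participant_id", "category"])
    prof = g.agg(
        mean_raw_ms=("latency_ms", "mean"),
        mean_ipsatized=("latency_ips", "mean"),
        n_valid=("latency_ms", "count"),
        n_total=("latency_ms", "size"),
    ).reset_index()
    prof["n_missing"] = prof["n_total"] - prof["n_valid"]
    # materialize all 10 categories per participant, absent ones as empty
    full = pd.MultiIndex.from_product(
        [prof["participant_id"].unique(), CATEGORY_LABELS], names=["participant_id", "category"]
    )
    prof = prof.set_index(["participant_id", "category"]).reindex(full).reset_index()
    prof["n_valid"] = prof["n_valid"].fillna(0).astype(int)
    prof["n_total"] = prof["n_total"].fillna(0).astype(int)
    prof["n_missing"] = prof["n_missing"].fillna(0).astype(int)
    return prof.drop(columns="n_total")


@dataclass(frozen=True)
class VrtIndex:
    """Max-child minus max-adult latency contrast for one participant."""

    participant_id: str
    value: float
    basis: str  # "ipsatized" or "raw"
    argmax_child: StimulusCategory
    argmax_adult: StimulusCategory


def vrt_index(profile: pd.DataFrame, basis: str = "ipsatized") -> pd.DataFrame:
    """Compute the index for every participant in a category-profile table.

    ``basis`` selects the mean column: "ipsatized" or "raw".  All ten
    category means must be defined for each participant; an undefined mean
    raises with a pointer to eligibility filtering / imputation.  Ties in
    the maxima break deterministically by fixed category order (male before
    female, ascending Tanner stage); the winning categories are recorded.

    Returns a DataFrame with participant_id, value, basis, argmax_child,
    argmax_adult.
    """
    if basis not in ("ipsatized", "raw"):
        raise ValueError(f"basis must be 'ipsatized' or 'raw', got {basis!r}")
    col = "mean_ipsatized" if basis == "ipsatized" else "mean_raw_ms"
    wide = profile.pivot(index="participant_id", columns="category", values=col)
    missing_cats = [c for c in CATEGORY_LABELS if c not in wide.columns]
    if missing_cats or wide.isna().any().any():
        bad = missing_cats or list(wide.columns[wide.isna().any()])
        raise ValueError(
            f"undefined {basis} category means (e.g. {bad[:3]}); apply eligibility "
            "filtering and imputation before computing the index"
        )
    child = wide[list(CHILD_LABELS)].to_numpy()
    adult = wide[list(ADULT_LABELS)].to_numpy()
    ic = child.argmax(axis=1)  # argmax takes the first maximum: the fixed-order tie-break
    ia = adult.argmax(axis=1)
    return pd.DataFrame(
        {
            "participant_id": wide.index.to_numpy(),
            "value": child.max(axis=1) - adult.max(axis=1),
            "basis": basis,
            "argmax_child": np.array(CHILD_LABELS)[ic],
            "argmax_adult": np.array(ADULT_LABELS)[ia],
        }
    )


def score_cohort(trials: pd.DataFrame, *, basis: str = "ipsatized", mode: str = "z") -> pd.DataFrame:
    """Convenience: ipsatize (if needed), profile, and index a trial table."""
    t = ipsatize(trials, mode=mode) if basis == "ipsatized" else trials
    return vrt_index(category_means(t), basis=basis)


__all__ = ["ipsatize", "category_means", "vrt_index", "score_cohort", "VrtIndex"]
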