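"""Missing-latency imputation and pooling of multiply imputed analyses.

Three schemes for the timed-out trials of the viewing-reaction-time task:

* ``INDIVIDUAL_MEAN`` - replace a missing latency by the participant's own
  observed mean in the same stimulus category (simple, deterministic; the
  analysis reference point).
* ``WHOLE_SAMPLE_REGRESSION`` - per target category, an ordinary
  least-squares model over the whole sample predicts a participant's
  category mean from that participant's other observed category means;
  missing trials take the model prediction (simple, deterministic).
* ``PMM_CATEGORY`` / ``PMM_CATEGORY_BY_INDIVIDUAL`` - predictive mean
  matching on the same predictive model (type-1 matching: predicted-to-
  predicted distance), drawing an observed donor value from the k nearest
  donors; repeated m times (default 5) to yield multiple completed
  datasets.  With individuals as separate classes, the donor pool is
  restricted to the participant's own observed trials in that category.

Predictive models operate on the participant-by-category mean matrix;
values are assigned per missing trial, retaining per-category trial counts.

Multiply imputed analyses are combined by Rubin's rules with the
Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .categories import CATEGORY_LABELS


class ImputationMethod(str, Enum):
    INDIVIDUAL_MEAN = "INDIVIDUAL_MEAN"
    PMM_CATEGORY = "PMM_CATEGORY"
    PMM_CATEGORY_BY_INDIVIDUAL = "PMM_CATEGORY_BY_INDIVIDUAL"
    WHOLE_SAMPLE_REGRESSION = "WHOLE_SAMPLE_REGRESSION"


@dataclass
class ImputationResult:
    method: ImputationMethod
    m: int
    datasets: list = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        assert len(self.datasets) == self.m
        for d in self.datasets:
            assert not d["latency_ms"].isna().any(), "completed dataset contains missing latencies"


def _check_category_support(trials: pd.DataFrame) -> None:
    """Every (participant, category) holding a missing trial needs >=1 observed trial."""
    miss = trials[trials["latency_ms"].isna()]
    if miss.empty:
        return
    obs = trials[trials["latency_ms"].notna()].groupby(["participant_id", "category"]).size()
    for pid, cat in miss[["participant_id", "category"]].drop_duplicates().itertuples(index=False):
        if (pid, cat) not in obs.index:
            raise ValueError(
                f"participant {pid} has no observed trials in category {cat}; "
                "eligibility filtering (empty-category rule) was bypassed"
            )


def impute_individual_mean(trials: pd.DataFrame) -> ImputationResult:
    """Replace each missing latency by the participant's observed category mean."""
    _check_category_support(trials)
    out = trials.copy()
    cat_mean = out.groupby(["participant_id", "category"])["latency_ms"].transform("mean")
    out["latency_ms"] = out["latency_ms"].fillna(cat_mean)
    return ImputationResult(ImputationMethod.INDIVIDUAL_MEAN, 1, [out])


def _mean_matrix(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant-by-category matrix of observed mean latencies (NaN if none)."""
    m = (
        trials.pivot_table(index="participant_id", columns="category", values="latency_ms", aggfunc="mean")
        .reindex(columns=list(CATEGORY_LABELS))
    )
    return m


def _fit_predict(mat: pd.DataFrame, target: str, predict_for: pd.Index) -> pd.Series:
    """OLS of the target category mean on the other category means.

    Trained on participants observed in the target and in all predictors;
    participants with incomplete predictors fall back to the submodel on
    their available predictors (rank deficiency handled by least squares).
    """
    predictors = [c for c in mat.columns if c != target]
    preds = pd.Series(index=predict_for, dtype=float)
    need = mat.loc[predict_for, predictors]
    patterns = need.notna().apply(tuple, axis=1)
    for pattern in patterns.unique():
        avail = [p for p, ok in zip(predictors, pattern) if ok]
        who = patterns.index[patterns == pattern]
        if not avail:
            preds.loc[who] = mat[target].mean()
            continue
        train = mat[[target, *avail]].dropna()
        if len(train) < 2:
            preds.loc[who] = mat[target].mean()
            continue
        X = np.column_stack([np.ones(len(train)), train[avail].to_numpy()])
        y = train[target].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        Xnew = np.column_stack([np.ones(len(who)), mat.loc[who, avail].to_numpy()])
        preds.loc[who] = Xnew @ beta
    return preds


def impute_regression(trials: pd.DataFrame) -> ImputationResult:
    """Whole-sample linear regression per category; deterministic."""
    _check_category_support(trials)
    out = trials.copy()
    mat = _mean_matrix(trials)
    miss = out["latency_ms"].isna()
    for cat in out.loc[miss, "category"].unique():
        rows = miss & (out["category"] == cat)
        pids = pd.Index(out.loc[rows, "participant_id"].unique())
        preds = _fit_predict(mat, cat, pids)
        out.loc[rows, "latency_ms"] = out.loc[rows, "participant_id"].map(preds)
    return ImputationResult(ImputationMethod.WHOLE_SAMPLE_REGRESSION, 1, [out])


class PmmClasses(str, Enum):
    NONE = "NONE"
    BY_INDIVIDUAL = "BY_INDIVIDUAL"


def impute_pmm(
    trials: pd.DataFrame,
    *,
    m: int = 5,
    k_donors: int = 5,
    classes: PmmClasses | str = PmmClasses.NONE,
    seed: int = 0,
) -> ImputationResult:
    """Predictive mean matching per category, yielding m completed datasets."""
    classes = PmmClasses(classes)
    _check_category_support(trials)
    rng = np.random.default_rng(seed)
    mat = _mean_matrix(trials)
    miss_mask = trials["latency_ms"].isna()
    obs = trials[~miss_mask]

    # precompute predictions and donor pools per category
    plans: list[tuple[np.ndarray, np.ndarray]] = []  # (row positions, donor values)
    for cat in trials.loc[miss_mask, "category"].unique():
        rows = np.flatnonzero(miss_mask.to_numpy() & (trials["category"] == cat).to_numpy())
        pids = trials["participant_id"].iloc[rows]
        if classes is PmmClasses.BY_INDIVIDUAL:
            own = obs[obs["category"] == cat].groupby("participant_id")["latency_ms"].agg(list)
            for r, pid in zip(rows, pids):
                pool = np.asarray(own.loc[pid])
                if len(pool) < k_donors:
                    warnings.warn(
                        f"PMM donor pool for {pid}/{cat} has {len(pool)} < k={k_donors} donors; "
                        "using the full pool",
                        stacklevel=2,
                    )
                plans.append((np.array([r]), pool))
        else:
            preds = _fit_predict(mat, cat, pd.Index(pids.unique()))
            donors = mat[cat].dropna()  # observed category means across the sample
            donor_pred = _fit_predict(mat, cat, donors.index)
            donor_vals = donors.to_numpy()
            donor_pred = donor_pred.to_numpy()
            if len(donor_vals) < k_donors:
                warnings.warn(
                    f"PMM donor pool for category {cat} has {len(donor_vals)} < k={k_donors} "
                    "donors; using the full pool",
                    stacklevel=2,
                )
            for r, pid in zip(rows, pids):
                d = np.abs(donor_pred - preds.loc[pid])
                kk = min(k_donors, len(donor_vals))
                nearest = np.argpartition(d, kk - 1)[:kk] if kk < len(donor_vals) else np.arange(len(donor_vals))
                plans.append((np.array([r]), donor_vals[nearest]))

    datasets = []
    lat = trials["latency_ms"].to_numpy()
    for _ in range(m):
        filled = lat.copy()
        for rows, pool in plans:
            filled[rows] = rng.choice(pool, size=len(rows))
        d = trials.copy()
        d["latency_ms"] = filled
        datasets.append(d)
    method = (
        ImputationMethod.PMM_CATEGORY_BY_INDIVIDUAL
        if classes is PmmClasses.BY_INDIVIDUAL
        else ImputationMethod.PMM_CATEGORY
    )
    return ImputationResult(method, m, datasets, seed=seed)


def impute(trials: pd.DataFrame, method: ImputationMethod | str, **kwargs) -> ImputationResult:
    """Dispatch by method name."""
    method = ImputationMethod(method)
    if method is ImputationMethod.INDIVIDUAL_MEAN:
        return impute_individual_mean(trials)
    if method is ImputationMethod.WHOLE_SAMPLE_REGRESSION:
        return impute_regression(trials)
    classes = (
        PmmClasses.BY_INDIVIDUAL
        if method is ImputationMethod.PMM_CATEGORY_BY_INDIVIDUAL
        else PmmClasses.NONE
    )
    return impute_pmm(trials, classes=classes, **kwargs)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of one scalar estimate across m imputations."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def pool_rubin(
    estimates, variances, df_complete: float, *, alpha: float = 0.05
) -> PooledEstimate:
    """Combine m estimates and their variances by Rubin's rules.

    total variance T = W + (1 + 1/m) B; degrees of freedom by the
    Barnard-Rubin small-sample formula with complete-data df
    ``df_complete``; CI from t(df) at level 1 - alpha.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = len(est)
    if m < 2:
        raise ValueError("pooling requires multiple imputations (m >= 2)")
    if (var < 0).any():
        raise ValueError("variances must be non-negative")
    qbar = est.mean()
    W = var.mean()
    B = est.var(ddof=1)
    T = W + (1 + 1 / m) * B
    if B == 0:
        df = float(df_complete)
    else:
        lam = (1 + 1 / m) * B / T
        df_old = (m - 1) / lam**2
        df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
        df = 1 / (1 / df_old + 1 / df_obs)
    tq = stats.t.ppf(1 - alpha / 2, df)
    half = tq * np.sqrt(T)
    return PooledEstimate(float(qbar), float(W), float(B), float(T), float(df), (float(qbar - half), float(qbar + half)), m)


__all__ = [
    "ImputationMethod",
    "ImputationResult",
    "PmmClasses",
    "PooledEstimate",
    "impute",
    "impute_individual_mean",
    "impute_regression",
    "impute_pmm",
    "pool_rubin",
]
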