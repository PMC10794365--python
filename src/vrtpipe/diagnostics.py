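"""Diagnostic-accuracy and descriptive-comparison statistics.

ROC machinery for the subgroup-accuracy question (does the index separate
diagnosed from non-diagnosed individuals equally well with and without an
offense history): empirical AUC with the Mann-Whitney tie convention,
stratified bootstrap percentile CIs, the unpaired DeLong test with
Welch-Satterthwaite degrees of freedom, the Youden-J optimal cutoff, and
the CI-encompassment equivalence rule (the offense-history group's 95% CI
must contain the no-history group's 90% CI).

Plus the criterion-validity and cohort-description statistics: pairwise
Spearman matrices, Yates-corrected 2x2 chi-square, Welch's t, and the
one-way random-effects intraclass correlation ICC(1) for inter-rater
reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class RocCurve:
    """Empirical ROC of a score against a binary label (higher = positive)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    scores_pos: np.ndarray = field(repr=False, default=None)
    scores_neg: np.ndarray = field(repr=False, default=None)


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability, ties counted 1/2."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels) -> RocCurve:
    """Empirical ROC curve and AUC.  Raises if either class is absent."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1 - fpr,
        auc=_auc_mann_whitney(pos, neg),
        n_pos=len(pos),
        n_neg=len(neg),
        scores_pos=pos,
        scores_neg=neg,
    )


def bootstrap_auc_ci(scores, labels, *, level: float = 0.95, reps: int = 2000, seed: int = 0):
    """Stratified (within-class) bootstrap percentile CI for the AUC."""
    if reps < 100:
        raise ValueError("reps must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    chunk = max(1, int(5e6 // (len(pos) * len(neg))))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        ps = pos[rng.integers(0, len(pos), size=(b, len(pos)))]
        ns = neg[rng.integers(0, len(neg), size=(b, len(neg)))]
        gt = (ps[:, :, None] > ns[:, None, :]).mean(axis=(1, 2))
        eq = (ps[:, :, None] == ns[:, None, :]).mean(axis=(1, 2))
        aucs[done : done + b] = gt + 0.5 * eq
        done += b
    a = (1 - level) / 2
    return (float(np.quantile(aucs, a)), float(np.quantile(aucs, 1 - a)))


def _delong_variance(curve: RocCurve) -> float:
    """DeLong variance of one AUC via placement values."""
    pos, neg = curve.scores_pos, curve.scores_neg
    v10 = ((pos[:, None] > neg[None, :]).mean(axis=1) + 0.5 * (pos[:, None] == neg[None, :]).mean(axis=1))
    v01 = ((pos[:, None] > neg[None, :]).mean(axis=0) + 0.5 * (pos[:, None] == neg[None, :]).mean(axis=0))
    return float(np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg))


def delong_unpaired(curve_a: RocCurve, curve_b: RocCurve) -> tuple[float, float, float]:
    """Unpaired DeLong comparison of two AUCs from disjoint samples.

    Returns (D, df, p): D is the AUC difference over its combined DeLong
    standard error, df by Welch-Satterthwaite on the two variance
    components (fractional), p two-sided from t(df).
    """
    for c in (curve_a, curve_b):
        if c.n_pos < 2 or c.n_neg < 2:
            raise ValueError("each curve needs at least 2 cases and 2 controls")
    va, vb = _delong_variance(curve_a), _delong_variance(curve_b)
    d = (curve_a.auc - curve_b.auc) / np.sqrt(va + vb)
    na = curve_a.n_pos + curve_a.n_neg
    nb = curve_b.n_pos + curve_b.n_neg
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = float(2 * stats.t.sf(abs(d), df))
    return float(d), float(df), p


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    A score strictly above the cutoff predicts positive.  The reported
    threshold is the midpoint between the adjacent observed scores; J-ties
    resolve toward the higher-specificity (higher) cutoff.
    """
    all_scores = np.unique(np.concatenate([curve.scores_pos, curve.scores_neg]))
    mids = (all_scores[:-1] + all_scores[1:]) / 2
    candidates = np.concatenate([[all_scores[0] - 1], mids, [all_scores[-1] + 1]])
    pos, neg = curve.scores_pos, curve.scores_neg
    sens = (pos[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] <= candidates[:, None]).mean(axis=1)
    j = sens + spec - 1
    best = np.flatnonzero(j == j.max())[-1]  # last index: highest cutoff => highest specificity
    return float(candidates[best]), float(sens[best]), float(spec[best])


def ci_encompassment(outer: tuple[float, float], inner: tuple[float, float]) -> bool:
    """True iff the closed interval ``inner`` lies within ``outer``."""
    return outer[0] <= inner[0] and inner[1] <= outer[1]


@dataclass
class RocComparison:
    """Subgroup accuracy comparison with the CI-encompassment equivalence rule."""

    auc_a: float
    auc_b: float
    ci95_a: tuple[float, float]
    ci90_b: tuple[float, float]
    delong_D: float
    delong_df: float
    delong_p: float
    encompassed: bool
    youden_cutoff: float
    youden_sens: float
    youden_spec: float


def compare_roc(
    scores_a, labels_a, scores_b, labels_b, *, reps: int = 2000, seed: int = 0
) -> RocComparison:
    """Full subgroup comparison: AUCs, bootstrap CIs, DeLong, encompassment.

    Group "a" is the offense-history subgroup (its 95% CI is the outer
    interval), group "b" the no-history subgroup (90% CI inner).  The
    Youden cutoff is determined on both groups combined.
    """
    ca = roc_auc(scores_a, labels_a)
    cb = roc_auc(scores_b, labels_b)
    ci95_a = bootstrap_auc_ci(scores_a, labels_a, level=0.95, reps=reps, seed=seed)
    ci90_b = bootstrap_auc_ci(scores_b, labels_b, level=0.90, reps=reps, seed=seed + 1)
    d, df, p = delong_unpaired(ca, cb)
    overall = roc_auc(
        np.concatenate([np.asarray(scores_a, float), np.asarray(scores_b, float)]),
        np.concatenate([np.asarray(labels_a).astype(bool), np.asarray(labels_b).astype(bool)]),
    )
    cut, sens, spec = youden_cutoff(overall)
    return RocComparison(
        auc_a=ca.auc,
        auc_b=cb.auc,
        ci95_a=ci95_a,
        ci90_b=ci90_b,
        delong_D=d,
        delong_df=df,
        delong_p=p,
        encompassed=ci_encompassment(ci95_a, ci90_b),
        youden_cutoff=cut,
        youden_sens=sens,
        youden_spec=spec,
    )


# ---------------------------------------------------------------------------
# correlations and cohort descriptives

def spearman_matrix(columns: pd.DataFrame, *, pairwise: bool = True, min_n: int = 3):
    """Pairwise Spearman rho with per-pair n and t-approximation p-values.

    Returns (rho, n, p) DataFrames over the input columns.  Ranks are
    averaged over ties.  Pairs with fewer than ``min_n`` pairwise-complete
    observations, or with a constant column, yield NaN (flagged by warning).
    """
    cols = list(columns.columns)
    k = len(cols)
    rho = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            pair = columns[[a, b]] if a != b else columns[[a]]
            pair = pair.dropna() if pairwise else pair
            nn = len(pair)
            n.loc[a, b] = n.loc[b, a] = nn
            if a == b:
                rho.loc[a, b] = 1.0
                continue
            if nn < min_n:
                continue
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                warnings.warn(f"constant column in pair ({a}, {b}); rho undefined", stacklevel=2)
                continue
            r, pv = stats.spearmanr(x, y)
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = pv
    return rho, n, p


def chisq_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square for the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    N = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero marginal total")
    num = N * max(abs(a * d - b * c) - N / 2, 0.0) ** 2
    chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def welch_t(*args) -> tuple[float, float, float]:
    """Welch's unequal-variance t test.

    Call with two raw samples ``welch_t(x, y)`` or six summaries
    ``welch_t(mean_a, sd_a, n_a, mean_b, sd_b, n_b)``.  Returns (t, df, p)
    with Satterthwaite degrees of freedom.
    """
    if len(args) == 2:
        x, y = (np.asarray(v, dtype=float) for v in args)
        args = (x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
    elif len(args) != 6:
        raise TypeError("welch_t takes two samples or six summary statistics")
    mean_a, sd_a, n_a, mean_b, sd_b, n_b = args
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def icc_oneway(ratings) -> tuple[float, tuple[float, float] | None]:
    """One-way random-effects intraclass correlation ICC(1) with F-based 95% CI.

    ``ratings`` is an items x raters array; items with any missing cell are
    dropped (balanced one-way ANOVA), with a warning.  Returns
    ``(nan, None)`` when the ratings carry no variance (the published
    convention "n.a. - ICC not calculable due to zero variance").
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters array")
    keep = ~np.isnan(x).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} item(s) with missing ratings", stacklevel=2)
    x = x[keep]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 raters after dropping incomplete items")
    grand = x.mean()
    item_means = x.mean(axis=1)
    msb = k * np.sum((item_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - item_means[:, None]) ** 2) / (n * (k - 1))
    if msb == 0 and msw == 0:
        return float("nan"), None
    if msw == 0:
        return 1.0, (1.0, 1.0)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    fl = f_obs / stats.f.ppf(0.975, n - 1, n * (k - 1))
    fu = f_obs * stats.f.ppf(0.975, n * (k - 1), n - 1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return float(icc), (float(lo), float(hi))


__all__ = [
    "RocCurve",
    "RocComparison",
    "roc_auc",
    "bootstrap_auc_ci",
    "delong_unpaired",
    "youden_cutoff",
    "ci_encompassment",
    "compare_roc",
    "spearman_matrix",
    "chisq_yates",
    "welch_t",
    "icc_oneway",
]
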