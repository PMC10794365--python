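"""Interaction regression and SESOI equivalence tests for the VRT index.

The index is regressed on dummy-coded clinical diagnosis (pedohebephilia),
prior child sexual offenses (CSO), prior child sexual abuse material use
(CSAM), and all their two- and three-way interactions, by ordinary least
squares with t-based confidence intervals.

Equivalence logic: the region of negligible interaction effects is
[-LL95(beta_P), 0], where LL95(beta_P) is the lower limit of the 95% CI of
the simple diagnosis effect - an interaction that negative would cancel
the diagnosis effect, and the upper bound of zero is conservative.  A term
is negligible when its 90% CI lies inside the region (alpha = 0.05, TOST
logic).  Violations mirror the reporting convention: the upper boundary is
violated when UL90 > 0 (strict), the lower when LL90 + LL95(beta_P) <= 0.

Four null hypotheses make up the composite hypothesis report: H0.1 is the
two-sided test of the diagnosis effect; H0.2-H0.4 are the equivalence
verdicts of the diagnosis-by-CSO, diagnosis-by-CSAM and three-way
interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import pool_rubin

TERMS = (
    "intercept",
    "pedohebephilia",
    "cso",
    "csam",
    "pedohebephilia:cso",
    "pedohebephilia:csam",
    "cso:csam",
    "pedohebephilia:cso:csam",
)
INTERACTION_TERMS = ("pedohebephilia:cso", "pedohebephilia:csam", "pedohebephilia:cso:csam")


def t_ci(beta: float, se: float, df: float, level: float = 0.95) -> tuple[float, float]:
    """t-distribution confidence interval for a regression coefficient.

    The same construction the model fit uses (``beta ± t(1-alpha/2, df) * se``);
    exposed so published coefficient tables can be re-derived from printed
    estimates and standard errors.
    """
    half = stats.t.ppf(1 - (1 - level) / 2, df) * se
    return (beta - half, beta + half)


@dataclass
class RegressionFit:
    """OLS (or Rubin-pooled) fit of the full interaction model."""

    beta: dict
    se: dict
    ci90: dict
    ci95: dict
    pvalues: dict
    df_resid: float
    r2: float
    r2_adj: float
    fvalue: float
    f_pvalue: float
    n: int
    outliers: list = field(default_factory=list)
    nonidentifiable: list = field(default_factory=list)
    pooled_m: int = 1

    def to_table(self) -> pd.DataFrame:
        rows = []
        for t in TERMS:
            rows.append(
                {
                    "term": t,
                    "beta": self.beta[t],
                    "se": self.se[t],
                    "ci90_ll": self.ci90[t][0],
                    "ci90_ul": self.ci90[t][1],
                    "ci95_ll": self.ci95[t][0],
                    "ci95_ul": self.ci95[t][1],
                    "p": self.pvalues[t],
                }
            )
        return pd.DataFrame(rows)


def _design(participants: pd.DataFrame) -> np.ndarray:
    P = participants["pedohebephilia"].astype(float).to_numpy()
    C = participants["cso"].astype(float).to_numpy()
    M = participants["csam"].astype(float).to_numpy()
    return np.column_stack([np.ones_like(P), P, C, M, P * C, P * M, C * M, P * C * M])


def fit_interaction_model(index: pd.DataFrame, participants: pd.DataFrame) -> RegressionFit:
    """Fit the dummy-coded interaction regression of the VRT index.

    ``index`` carries participant_id and value (one row per participant);
    ``participants`` carries complete boolean diagnosis/CSO/CSAM flags.
    Participants with unknown flags are rejected.  Empty design cells do
    not abort the fit (pseudoinverse solution); the affected interaction
    terms are flagged non-identifiable.  Outliers are reported as the
    participants with externally studentized residuals beyond |3|.
    """
    data = index.merge(participants, on="participant_id", how="inner", validate="1:1")
    for flag in ("pedohebephilia", "cso", "csam"):
        if data[flag].isna().any():
            raise ValueError(f"participants with unknown {flag} must be excluded before inference")
    n = len(data)
    if n <= len(TERMS):
        raise ValueError(f"need more than {len(TERMS)} participants, got {n}")
    if not np.isfinite(data["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite index values")
    X = _design(data)
    y = data["value"].to_numpy(dtype=float)

    nonidentifiable = []
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        running = X[:, :1]
        for j, term in enumerate(TERMS[1:], start=1):
            cand = np.column_stack([running, X[:, j]])
            if np.linalg.matrix_rank(cand) == running.shape[1]:
                nonidentifiable.append(term)
            else:
                running = cand

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pinv path warns on singular designs
        res = sm.OLS(y, X).fit()
        ci90 = res.conf_int(alpha=0.10)
        ci95 = res.conf_int(alpha=0.05)
        try:
            student = res.get_influence().resid_studentized_external
            out_mask = np.abs(student) > 3
            outliers = list(data.loc[out_mask, "participant_id"])
        except Exception:  # singular hat matrix on degenerate designs
            outliers = []

    return RegressionFit(
        beta={t: float(res.params[j]) for j, t in enumerate(TERMS)},
        se={t: float(res.bse[j]) for j, t in enumerate(TERMS)},
        ci90={t: (float(ci90[j, 0]), float(ci90[j, 1])) for j, t in enumerate(TERMS)},
        ci95={t: (float(ci95[j, 0]), float(ci95[j, 1])) for j, t in enumerate(TERMS)},
        pvalues={t: float(res.pvalues[j]) for j, t in enumerate(TERMS)},
        df_resid=float(res.df_resid),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        n=n,
        outliers=outliers,
        nonidentifiable=nonidentifiable,
    )


def pool_fits(fits: list[RegressionFit], *, df_complete: float | None = None) -> RegressionFit:
    """Rubin's-rules combination of m interaction-model fits (one per imputation)."""
    m = len(fits)
    if m < 2:
        raise ValueError("pooling requires multiple imputations (m >= 2)")
    df_com = df_complete if df_complete is not None else fits[0].df_resid
    beta, se, ci90, ci95, pvals = {}, {}, {}, {}, {}
    for t in TERMS:
        ests = [f.beta[t] for f in fits]
        vars_ = [f.se[t] ** 2 for f in fits]
        p95 = pool_rubin(ests, vars_, df_com, alpha=0.05)
        p90 = pool_rubin(ests, vars_, df_com, alpha=0.10)
        beta[t] = p95.estimate
        se[t] = p95.se
        ci95[t] = p95.ci
        ci90[t] = p90.ci
        tstat = p95.estimate / p95.se if p95.se > 0 else np.inf
        pvals[t] = float(2 * stats.t.sf(abs(tstat), p95.df))
    return RegressionFit(
        beta=beta,
        se=se,
        ci90=ci90,
        ci95=ci95,
        pvalues=pvals,
        df_resid=float(df_com),
        r2=float(np.mean([f.r2 for f in fits])),
        r2_adj=float(np.mean([f.r2_adj for f in fits])),
        fvalue=float(np.mean([f.fvalue for f in fits])),
        f_pvalue=float(np.mean([f.f_pvalue for f in fits])),
        n=fits[0].n,
        pooled_m=m,
    )


@dataclass(frozen=True)
class EquivalenceBounds:
    """Region of negligible interaction effects: (-LL95(beta_P), 0]."""

    lower: float
    upper: float = 0.0

    @property
    def degenerate(self) -> bool:
        return self.lower >= self.upper


def sesoi_bounds(fit: RegressionFit) -> EquivalenceBounds:
    """Bounds from the fitted diagnosis effect: lower = -LL95(beta_P), upper = 0.

    If the 95% CI of the diagnosis effect includes 0 the region is empty
    (lower >= upper); the bounds are returned with a warning.
    """
    ll95 = fit.ci95["pedohebephilia"][0]
    bounds = EquivalenceBounds(lower=-ll95)
    if bounds.degenerate:
        warnings.warn(
            "equivalence region empty: the 95% CI of the diagnosis effect includes 0",
            stacklevel=2,
        )
    return bounds


@dataclass(frozen=True)
class EquivalenceVerdict:
    term: str
    negligible: bool
    violates_upper: bool  # UL90 > 0
    violates_lower: bool  # LL90 + LL95(beta_P) <= 0


def equivalence_verdict(fit: RegressionFit, term: str, bounds: EquivalenceBounds) -> EquivalenceVerdict:
    """Assess one term's 90% CI against the equivalence region (alpha = 0.05)."""
    ll90, ul90 = fit.ci90[term]
    violates_upper = ul90 > 0
    violates_lower = ll90 <= bounds.lower
    return EquivalenceVerdict(term, not (violates_upper or violates_lower), violates_upper, violates_lower)


def verdicts_from_intervals(ci90: dict, ll95_p: float) -> dict:
    """Verdicts straight from printed 90% CIs and the diagnosis effect's LL95.

    Accepts a mapping term -> (LL90, UL90); useful for checking a published
    coefficient table without refitting.  Returns term -> EquivalenceVerdict.
    """
    lower = -ll95_p
    out = {}
    for term, (ll, ul) in ci90.items():
        vu = ul > 0
        vl = ll <= lower
        out[term] = EquivalenceVerdict(term, not (vu or vl), vu, vl)
    return out


def h1_report(fit: RegressionFit, *, alpha: float = 0.05) -> dict:
    """Structured composite-hypothesis report.

    H0.1: the diagnosis effect is zero (two-sided t test).  H0.2-H0.4: the
    three diagnosis interactions lie outside the negligible region
    (equivalence verdicts; rejecting both one-sided composite nulls means
    the interaction is negligible).
    """
    bounds = sesoi_bounds(fit)
    report = {
        "H0.1": {
            "term": "pedohebephilia",
            "beta": fit.beta["pedohebephilia"],
            "se": fit.se["pedohebephilia"],
            "p": fit.pvalues["pedohebephilia"],
            "rejected": fit.pvalues["pedohebephilia"] < alpha,
        },
        "bounds": {"lower": bounds.lower, "upper": bounds.upper, "degenerate": bounds.degenerate},
    }
    for h, term in zip(("H0.2", "H0.3", "H0.4"), INTERACTION_TERMS):
        v = equivalence_verdict(fit, term, bounds)
        report[h] = {
            "term": term,
            "beta": fit.beta[term],
            "ci90": list(fit.ci90[term]),
            "negligible": v.negligible,
            "violates_upper": v.violates_upper,
            "violates_lower": v.violates_lower,
        }
    return report


__all__ = [
    "TERMS",
    "INTERACTION_TERMS",
    "t_ci",
    "RegressionFit",
    "EquivalenceBounds",
    "EquivalenceVerdict",
    "fit_interaction_model",
    "pool_fits",
    "sesoi_bounds",
    "equivalence_verdict",
    "verdicts_from_intervals",
    "h1_report",
]
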