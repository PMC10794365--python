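"""Interaction regression, SESOI bounds, and equivalence verdicts."""


import numpy as np
import pandas as pd
import pytest

from vrtpipe.inference import (
    TERMS,
    EquivalenceBounds,
    RegressionFit,
    equivalence_verdict,
    fit_interaction_model,
    h1_report,
    pool_fits,
    sesoi_bounds,
    t_ci,
    verdicts_from_intervals,
)

# published coefficient table: term -> (beta, (LL90, UL90), expected dagger,
# expected double-dagger); dagger = lower-boundary violation, double-dagger
# = upper-boundary violation
PUBLISHED_TABLE = {
    "intercept": (-1.0945, (-1.2818, -0.9071), True, False),
    "pedohebephilia": (1.0875, (0.6727, 1.5023), False, True),
    "cso": (-0.1192, (-0.4748, 0.2363), False, True),
    "csam": (0.0087, (-0.4061, 0.4235), False, True),
    "pedohebephilia:cso": (0.2796, (-0.3111, 0.8703), False, True),
    "pedohebephilia:csam": (0.0972, (-0.4675, 0.6618), False, True),
    "cso:csam": (0.4955, (-0.2828, 1.2737), False, True),
    "pedohebephilia:cso:csam": (-0.5741, (-1.5046, 0.3565), True, True),
}
PUBLISHED_LL95_P = 1.0875 - 1.9687 * 0.2513  # ~0.5928


def _toy_data(n=12, seed=0):
    rng = np.random.default_rng(seed)
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "pedohebephilia": rng.random(n) < 0.5,
            "cso": rng.random(n) < 0.5,
            "csam": rng.random(n) < 0.5,
        }
    )
    index = pd.DataFrame(
        {"participant_id": participants["participant_id"], "value": rng.normal(size=n)}
    )
    return index, participants


class TestFit:
    def test_matches_normal_equations(self):
        """OLS coefficients equal the brute-force normal-equations solution."""
        index, participants = _toy_data(n=40, seed=3)
        fit = fit_interaction_model(index, participants)
        P = participants["pedohebephilia"].astype(float).to_numpy()
        C = participants["cso"].astype(float).to_numpy()
        M = participants["csam"].astype(float).to_numpy()
        X = np.column_stack([np.ones_like(P), P, C, M, P * C, P * M, C * M, P * C * M])
        y = index["value"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose([fit.beta[t] for t in TERMS], beta, atol=1e-10)

    def test_ci_construction_matches_t_quantiles(self):
        index, participants = _toy_data(n=40, seed=3)
        fit = fit_interaction_model(index, participants)
        for t in TERMS:
            lo, hi = t_ci(fit.beta[t], fit.se[t], fit.df_resid, level=0.90)
            assert fit.ci90[t] == pytest.approx((lo, hi), abs=1e-12)

    def test_all_zero_flags_collapse_to_intercept(self):
        index, participants = _toy_data(n=20, seed=1)
        for f in ("pedohebephilia", "cso", "csam"):
            participants[f] = False
        fit = fit_interaction_model(index, participants)
        assert fit.beta["intercept"] == pytest.approx(index["value"].mean())
        assert len(fit.nonidentifiable) == 7

    def test_unknown_flags_rejected(self):
        index, participants = _toy_data()
        participants["cso"] = participants["cso"].astype(object)
        participants.loc[0, "cso"] = np.nan
        with pytest.raises(ValueError, match="unknown cso"):
            fit_interaction_model(index, participants)

    def test_pooled_fit_shrinks_nothing_and_widens_ci(self):
        index, participants = _toy_data(n=60, seed=5)
        fits = []
        rng = np.random.default_rng(9)
        for _ in range(5):
            jitter = index.copy()
            jitter["value"] = jitter["value"] + rng.normal(0, 0.1, len(jitter))
            fits.append(fit_interaction_model(jitter, participants))
        pooled = pool_fits(fits)
        assert pooled.pooled_m == 5
        for t in TERMS:
            assert pooled.beta[t] == pytest.approx(np.mean([f.beta[t] for f in fits]))
            assert pooled.se[t] >= min(f.se[t] for f in fits) - 1e-12


class TestEquivalence:
    def test_published_ci_arithmetic(self):
        """90% CI from the printed coefficient and SE via t(274) quantiles."""
        lo, hi = t_ci(1.0875, 0.2513, 274, level=0.90)
        assert lo == pytest.approx(0.6727, abs=5e-5)
        assert hi == pytest.approx(1.5023, abs=5e-5)

    def test_bounds_from_published_diagnosis_effect(self):
        ll95, _ = t_ci(1.0875, 0.2513, 274, level=0.95)
        fit = _fake_fit(ci95_p=(ll95, 2.0))
        bounds = sesoi_bounds(fit)
        assert bounds.lower == pytest.approx(-0.5927, abs=2e-4)
        assert bounds.upper == 0.0
        assert not bounds.degenerate

    def test_degenerate_bounds_warn(self):
        fit = _fake_fit(ci95_p=(-0.1, 0.4))
        with pytest.warns(UserWarning, match="equivalence region empty"):
            bounds = sesoi_bounds(fit)
        assert bounds.degenerate

    def test_upper_only_violation(self):
        fit = _fake_fit(ci90={"pedohebephilia:cso": (-0.3111, 0.8703)})
        v = equivalence_verdict(fit, "pedohebephilia:cso", EquivalenceBounds(lower=-0.5927))
        assert v.violates_upper and not v.violates_lower and not v.negligible

    def test_both_violations_on_three_way(self):
        fit = _fake_fit(ci90={"pedohebephilia:cso:csam": (-1.5046, 0.3565)})
        v = equivalence_verdict(fit, "pedohebephilia:cso:csam", EquivalenceBounds(lower=-0.5927))
        assert v.violates_upper and v.violates_lower

    def test_ci_inside_region_is_negligible(self):
        fit = _fake_fit(ci90={"pedohebephilia:cso": (-0.3, -0.1)})
        v = equivalence_verdict(fit, "pedohebephilia:cso", EquivalenceBounds(lower=-0.59))
        assert v.negligible

    def test_published_pattern_row_for_row(self):
        ci90 = {t: ci for t, (_, ci, _, _) in PUBLISHED_TABLE.items()}
        verdicts = verdicts_from_intervals(ci90, PUBLISHED_LL95_P)
        for term, (_, _, dagger, ddagger) in PUBLISHED_TABLE.items():
            assert verdicts[term].violates_lower == dagger, term
            assert verdicts[term].violates_upper == ddagger, term


class TestH1Report:
    def test_structure_and_composite_nulls(self):
        rng = np.random.default_rng(12)
        n = 200
        participants = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "pedohebephilia": rng.random(n) < 0.6,
                "cso": rng.random(n) < 0.4,
                "csam": rng.random(n) < 0.5,
            }
        )
        y = -1.0 + 1.0 * participants["pedohebephilia"].to_numpy() + rng.normal(0, 0.7, n)
        index = pd.DataFrame({"participant_id": participants["participant_id"], "value": y})
        fit = fit_interaction_model(index, participants)
        rep = h1_report(fit)
        assert rep["H0.1"]["rejected"]  # strong simple effect present
        assert set(rep) == {"H0.1", "H0.2", "H0.3", "H0.4", "bounds"}
        for h in ("H0.2", "H0.3", "H0.4"):
            assert rep[h]["negligible"] == (
                not rep[h]["violates_upper"] and not rep[h]["violates_lower"]
            )


def _fake_fit(ci95_p=(0.5, 1.5), ci90=None) -> RegressionFit:
    base_ci = {t: (-1.0, 1.0) for t in TERMS}
    if ci90:
        base_ci.update(ci90)
    return RegressionFit(
        beta={t: 0.0 for t in TERMS},
        se={t: 0.1 for t in TERMS},
        ci90=base_ci,
        ci95={**{t: (-1.0, 1.0) for t in TERMS}, "pedohebephilia": ci95_p},
        pvalues={t: 0.5 for t in TERMS},
        df_resid=274.0,
        r2=0.3,
        r2_adj=0.29,
        fvalue=10.0,
        f_pvalue=1e-6,
        n=282,
    )
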