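# vrtpipe

Analysis pipeline for **viewing reaction time (VRT)** data — a latency-based
indirect measure of sexual interest used in clinical assessment of
pedohebephilia in non-forensic, help-seeking ("Dunkelfeld") settings.
Participants rate the sexual attractiveness of figures of males and females
in Tanner stages 1–5 (8 trials per each of the 10 sex × stage categories,
5000 ms response window); people dwell longer on categories they find
sexually salient.  The package is for biostatisticians and clinical
researchers who need the complete, reproducible chain from trial-level
latencies to equivalence-tested group conclusions — including a calibrated
synthetic-cohort generator, since real data of this kind are not publicly
deposited.

## The statistic at its core

Per participant, latencies are ipsatized (within-person z-standardized over
all valid trials) and averaged per category; the **VRT index** is

```
VRT index = max{ z̄_c : c ∈ child categories (Tanner 1–3) }
          − max{ z̄_c : c ∈ adult categories (Tanner 4–5) }
```

so a positive index means longer dwelling on child than adult stimuli, in
within-person SD units.  Downstream, the package provides:

* **Eligibility filters** — >10% missing trials, any empty category, test
  more than 4 weeks from interview, unknown diagnosis.
* **Imputation** of timed-out trials: individual category mean,
  whole-sample regression, predictive mean matching (with or without
  individuals as donor classes; m = 5), with Rubin's-rules pooling
  (Barnard–Rubin df).
* **Equivalence-testing regression** (TOST logic): OLS of the index on
  diagnosis × prior-CSO × prior-CSAM dummies; interactions count as
  negligible only when their 90% CI lies inside (−LL95(β_diagnosis), 0].
* **Subgroup ROC comparison**: Mann–Whitney AUC, stratified bootstrap CIs,
  unpaired DeLong test, Youden cutoff, and the CI-encompassment
  equivalence rule.
* **Criterion validity**: scoring of SSPI-2, an adapted static actuarial
  risk scale, STABLE-2007 and ACUTE-2007 (with factor scores), and
  pairwise Spearman tables; ICC(1) for inter-rater reliability.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

```python
import vrtpipe as vp

cfg = vp.default_calibration()            # published cohort structure, n = 282
trials, participants = vp.simulate_cohort(cfg, seed=1)

report = vp.apply_eligibility(trials, participants)
trials, participants = vp.filter_eligible(trials, participants, report)

completed = vp.impute_individual_mean(trials).datasets[0]
index = vp.score_cohort(completed)        # ipsatize -> category means -> index

fit = vp.fit_interaction_model(index, participants)
print(f"diagnosis effect: {fit.beta['pedohebephilia']:.4f} "
      f"(90% CI {fit.ci90['pedohebephilia'][0]:.4f}, {fit.ci90['pedohebephilia'][1]:.4f})")
print(f"intercept: {fit.beta['intercept']:.4f}   adj R2: {fit.r2_adj:.3f}")

h1 = vp.h1_report(fit)
print("equivalence bounds:", [round(h1['bounds']['lower'], 4), 0.0])
for h in ("H0.2", "H0.3", "H0.4"):
    r = h1[h]
    print(f"{h} {r['term']}: negligible={r['negligible']} "
          f"(upper violated: {r['violates_upper']}, lower violated: {r['violates_lower']})")
```

prints

```
diagnosis effect: 1.1017 (90% CI 0.7355, 1.4678)
intercept: -1.0512   adj R2: 0.310
equivalence bounds: [-0.6649, 0.0]
H0.2 pedohebephilia:cso: negligible=False (upper violated: True, lower violated: False)
H0.3 pedohebephilia:csam: negligible=False (upper violated: True, lower violated: False)
H0.4 pedohebephilia:cso:csam: negligible=False (upper violated: True, lower violated: False)
```

Read: non-diagnosed, non-offending participants respond about one
within-person SD slower to adult than to child stimuli (intercept ≈ −1);
a clinical diagnosis raises the index by about one SD (β ≈ +1.1, its 90%
CI well above zero), and none of the offense-history interactions can be
declared negligible — each 90% CI pokes above the conservative upper
equivalence bound of 0 — mirroring the inconclusive equivalence pattern
such cohorts produce.

The same analysis, end to end with the sensitivity grid (4 imputation
methods × 2 index bases), subgroup ROC and correlation table:

```sh
vrt-pipeline run --seed 1 --out-dir results/
# -> report.json, table4.csv, table5.csv, roc.json, eligibility.csv
```

Per-stage subcommands: `vrt-pipeline simulate | score | impute | analyze`.

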