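"""Synthetic cohort generator for the viewing-reaction-time paradigm.

Emulates the data-generating situation the analysis assumes: a clinical
cohort of help-seeking men, each completing 8 trials in each of the 10
(sex x Tanner stage) stimulus categories, with a 5000 ms response window
(slower latent responses are recorded as missing), ordinal attractiveness
ratings 1-4, and group-specific latency profiles.  Defaults reproduce the
published descriptive structure of the study cohort: per-group per-category
latency means/SDs, group sizes 68 (no sexual interest in minors) vs 214
(any sexual interest in minors), and offense-history prevalences.

Generative model per trial::

    latency = group/category mean + speed_i + pref_ic + noise,
    speed_i ~ N(0, speed_sd)           (general response speed)
    pref_ic ~ N(0, person_preference_sd)  (person x category preference)
    noise   ~ N(0, category SD)        (trial noise)

clipped below at a small positive floor.  Latent latencies above
``censor_at`` become missing trials (missing-at-random by category: slow
categories lose more trials); an extra MCAR rate adds mechanism-free
missingness.  A log-normal trial-noise option is exposed since reaction
times are right-skewed.

The participant table carries a ``latent_deviance`` column: the person's
true (noise-free) max-child minus max-adult latency contrast in ms, which
the criterion-scale simulator treats as the deviance construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .categories import ADULT_LABELS, CATEGORY_LABELS, CHILD_LABELS

# Per-group per-category latency means and SDs (ms) of the study cohort,
# keyed by diagnosis group.  "interest" = any sexual interest in minors.
LATENCY_MEANS = {
    "no_interest": {
        "MT5": 1161, "MT4": 1126, "MT3": 1098, "MT2": 994, "MT1": 1005,
        "FT1": 1154, "FT2": 1217, "FT3": 1379, "FT4": 1999, "FT5": 2201,
    },
    "interest": {
        "MT5": 1191, "MT4": 1390, "MT3": 1460, "MT2": 1433, "MT1": 1426,
        "FT1": 1932, "FT2": 2001, "FT3": 2053, "FT4": 2112, "FT5": 1996,
    },
}
LATENCY_SDS = {
    "no_interest": {
        "MT5": 572, "MT4": 523, "MT3": 490, "MT2": 456, "MT1": 429,
        "FT1": 516, "FT2": 568, "FT3": 690, "FT4": 651, "FT5": 757,
    },
    "interest": {
        "MT5": 554, "MT4": 691, "MT3": 777, "MT2": 786, "MT1": 741,
        "FT1": 743, "FT2": 742, "FT3": 759, "FT4": 749, "FT5": 722,
    },
}
RATING_MEANS = {
    "no_interest": {
        "MT5": 1.21, "MT4": 1.21, "MT3": 1.11, "MT2": 1.09, "MT1": 1.07,
        "FT1": 1.08, "FT2": 1.09, "FT3": 1.14, "FT4": 1.74, "FT5": 2.26,
    },
    "interest": {
        "MT5": 1.12, "MT4": 1.30, "MT3": 1.41, "MT2": 1.47, "MT1": 1.36,
        "FT1": 1.90, "FT2": 2.01, "FT3": 2.08, "FT4": 2.23, "FT5": 2.01,
    },
}

# Offense-history cell frequencies of the included cohort (n=282): any CSO
# 84, any CSAM 202, neither 49 => CSO-only 31, CSAM-only 149, both 53.
OFFENSE_CELLS = {
    (False, False): 49 / 282,
    (True, False): 31 / 282,
    (False, True): 149 / 282,
    (True, True): 53 / 282,
}

# Default latent rank-correlation targets between the deviance construct
# and each criterion scale, taken from the published correlation table's
# index column (calibration of the construct-validity structure).
DEFAULT_RHO = {
    "sspi2": 0.2704,
    "static_sum": 0.1420,
    "static_paraphilia": 0.1419,
    "static_youthful_stranger_aggression": 0.1534,
    "static_general_criminality": -0.0210,
    "stable_sum": 0.3081,
    "stable_antisociality": 0.1917,
    "stable_sexual_deviance": 0.4704,
    "stable_hypersexuality": 0.2364,
    "acute_sum": 0.3374,
}

# (max score, binomial success prob) giving marginals near the published
# criterion-scale descriptives.
SCALE_MARGINALS = {
    "sspi2": (5, 0.604),
    "static_sum": (8, 0.244),
    "static_paraphilia": (6, 0.292),
    "static_youthful_stranger_aggression": (4, 0.178),
    "static_general_criminality": (4, 0.095),
    "stable_sum": (26, 0.336),
    "stable_antisociality": (14, 0.287),
    "stable_sexual_deviance": (4, 0.558),
    "stable_hypersexuality": (4, 0.525),
    "acute_sum": (14, 0.309),
}


@dataclass
class CohortConfig:
    """Full parameterization of one simulated cohort."""

    n_participants: int = 282
    p_diagnosis: float = 214 / 282
    offense_cell_probs: dict = field(default_factory=lambda: dict(OFFENSE_CELLS))
    latency_means: dict = field(default_factory=lambda: {g: dict(v) for g, v in LATENCY_MEANS.items()})
    latency_sds: dict = field(default_factory=lambda: {g: dict(v) for g, v in LATENCY_SDS.items()})
    rating_means: dict = field(default_factory=lambda: {g: dict(v) for g, v in RATING_MEANS.items()})
    rating_sd: float = 0.7
    speed_sd: float = 470.0
    person_preference_sd: float = 400.0
    censor_at: float = 5000.0
    mcar_rate: float = 0.02
    trials_per_category: int = 8
    latency_floor: float = 150.0
    lognormal_noise: bool = False
    max_interval_days: int = 21
    rho_targets: dict = field(default_factory=lambda: dict(DEFAULT_RHO))
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if not 0 <= self.p_diagnosis <= 1:
            raise ValueError("p_diagnosis must lie in [0, 1]")
        cellsum = sum(self.offense_cell_probs.values())
        if not np.isclose(cellsum, 1.0):
            raise ValueError(f"offense cell probabilities must sum to 1, got {cellsum}")
        for g in ("no_interest", "interest"):
            if any(sd <= 0 for sd in self.latency_sds[g].values()):
                raise ValueError("all latency SDs must be positive")
        if not 0 <= self.mcar_rate <= 1:
            raise ValueError("mcar_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["offense_cell_probs"] = {f"cso={k[0]},csam={k[1]}": v for k, v in self.offense_cell_probs.items()}
        return d


def default_calibration() -> CohortConfig:
    """Cohort configuration reproducing the published descriptive structure."""
    return CohortConfig()


def _group_arrays(table: dict, labels=CATEGORY_LABELS) -> np.ndarray:
    return np.array(
        [[table["no_interest"][c] for c in labels], [table["interest"][c] for c in labels]],
        dtype=float,
    )


def simulate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns (trials, participants) tables.

    Reproducible: the same config and seed yield identical tables, and all
    randomness is drawn before censoring is applied, so lowering
    ``censor_at`` on the same seed only ever adds missing trials.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants
    k = len(CATEGORY_LABELS)
    tpc = config.trials_per_category

    if n == 0:
        trials = pd.DataFrame(
            columns=["participant_id", "sex", "tanner", "trial_index", "latency_ms", "rating", "category"]
        )
        participants = pd.DataFrame(
            columns=["participant_id", "pedohebephilia", "cso", "csam", "days_interview_to_vrt", "latent_deviance"]
        )
        return trials, participants

    diagnosis = rng.random(n) < config.p_diagnosis
    cells = list(config.offense_cell_probs.items())
    cell_idx = rng.choice(len(cells), size=n, p=[p for _, p in cells])
    cso = np.array([cells[i][0][0] for i in cell_idx])
    csam = np.array([cells[i][0][1] for i in cell_idx])

    mean_gc = _group_arrays(config.latency_means)
    sd_gc = _group_arrays(config.latency_sds)
    rmean_gc = _group_arrays(config.rating_means)
    g = diagnosis.astype(int)

    speed = rng.normal(0.0, config.speed_sd, size=n)
    pref = rng.normal(0.0, config.person_preference_sd, size=(n, k))
    person_mean = mean_gc[g] + speed[:, None] + pref  # (n, k) latent category means

    child_cols = [CATEGORY_LABELS.index(c) for c in CHILD_LABELS]
    adult_cols = [CATEGORY_LABELS.index(c) for c in ADULT_LABELS]
    latent_deviance = person_mean[:, child_cols].max(axis=1) - person_mean[:, adult_cols].max(axis=1)

    trial_sd = sd_gc[g]  # (n, k)
    if config.lognormal_noise:
        # log-normal with the same per-trial mean and SD as the Gaussian model
        m = person_mean[:, :, None]
        s = trial_sd[:, :, None]
        m = np.clip(m, config.latency_floor, None)
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2
        latent = rng.lognormal(mu, np.sqrt(sigma2), size=(n, k, tpc))
    else:
        latent = person_mean[:, :, None] + rng.normal(0.0, 1.0, size=(n, k, tpc)) * trial_sd[:, :, None]
    latent = np.clip(latent, config.latency_floor, None)

    rating_latent = rng.normal(rmean_gc[g][:, :, None], config.rating_sd, size=(n, k, tpc))
    ratings = np.clip(np.rint(rating_latent), 1, 4)

    mcar_u = rng.random(size=(n, k, tpc))
    missing = (latent > config.censor_at) | (mcar_u < config.mcar_rate)

    pids = np.array([f"P{i:04d}" for i in range(n)])
    cat_labels = np.array(CATEGORY_LABELS)
    trials = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, k * tpc),
            "category": np.tile(np.repeat(cat_labels, tpc), n),
            "trial_index": np.tile(np.arange(k * tpc), n),
            "latency_ms": np.where(missing, np.nan, latent).ravel(),
            "rating": np.where(missing, np.nan, ratings).ravel(),
        }
    )
    trials["sex"] = trials["category"].str[0]
    trials["tanner"] = trials["category"].str[2].astype(int)
    trials = trials[["participant_id", "sex", "tanner", "trial_index", "latency_ms", "rating", "category"]]

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "pedohebephilia": diagnosis,
            "cso": cso,
            "csam": csam,
            "days_interview_to_vrt": rng.integers(0, config.max_interval_days + 1, size=n),
            "latent_deviance": latent_deviance,
        }
    )
    return trials, participants


def simulate_criteria(
    participants: pd.DataFrame,
    config: CohortConfig,
    *,
    rho_target: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate criterion-scale scores correlated with the deviance construct.

    Uses a Gaussian copula: the participant's latent deviance is converted
    to normal scores by rank, blended with independent noise at the
    copula correlation 2*sin(pi*rho/6) that yields the requested Spearman
    rho, then discretized through binomial quantiles matching each scale's
    published marginal.  ``rho_target`` (scalar) overrides every per-scale
    default.  Returns one row per participant with scale-score columns.
    """
    if rho_target is not None and not -1 < rho_target < 1:
        raise ValueError(f"rho_target must lie in (-1, 1), got {rho_target}")
    if "latent_deviance" not in participants.columns:
        raise ValueError("participants must carry a latent_deviance column (see simulate_cohort)")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(participants)
    out = pd.DataFrame({"participant_id": participants["participant_id"].to_numpy()})
    if n == 0:
        for name in SCALE_MARGINALS:
            out[name] = pd.Series(dtype=float)
        return out

    dev = participants["latent_deviance"].to_numpy(dtype=float)
    ranks = stats.rankdata(dev, method="average")
    z = stats.norm.ppf(ranks / (n + 1))

    for name, (kmax, p) in SCALE_MARGINALS.items():
        rho_s = rho_target if rho_target is not None else config.rho_targets[name]
        rho_z = 2 * np.sin(np.pi * rho_s / 6)  # Spearman -> Gaussian copula correlation
        latent = rho_z * z + np.sqrt(1 - rho_z**2) * rng.normal(size=n)
        u = stats.norm.cdf(latent)
        out[name] = stats.binom.ppf(u, kmax, p).astype(int)
    return out


__all__ = [
    "CohortConfig",
    "default_calibration",
    "simulate_cohort",
    "simulate_criteria",
    "LATENCY_MEANS",
    "LATENCY_SDS",
    "RATING_MEANS",
    "OFFENSE_CELLS",
    "DEFAULT_RHO",
    "SCALE_MARGINALS",
]
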