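"""Scoring of the external criterion instruments, as adapted for a
non-forensic help-seeking ("Dunkelfeld") setting.

Four instruments, raw scores only (no risk norms or recidivism tables):

* SSPI-2: five yes/no offense-history items, simple sum 0-5.
* STATIC-99-Dunkelfeld: the actuarial static-risk scale adapted for
  self-referred clients: the index-offense violence item is dropped, age
  at assessment replaces age at release, and the remaining eight items
  are rated from clinical files.  Besides the total, three factor scores
  are computed; because of the adaptation, "youthful stranger aggression"
  sums age-at-assessment < 25, never having lived with an intimate
  partner for 2+ years, prior non-sexual violence and unrelated/stranger
  victims, and "general criminality" sums the prior-convictions count and
  prior non-sexual violence.
* STABLE-2007: thirteen dynamic risk items scored 0-2; factors
  antisociality (7 items, capacity for relationship stability reverse
  coded), sexual deviance (2 items) and hypersexuality (2 items).
* ACUTE-2007: seven acute risk items scored 0-2, sum 0-14.

Any unknown item propagates to NA for exactly the scores containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


def _sum_or_none(values) -> int | None:
    vals = list(values)
    if any(v is None for v in vals):
        return None
    return int(sum(vals))


# ---------------------------------------------------------------------------
# SSPI-2

SSPI2_ITEMS = ("male_victim", "victim_under_12", "extrafamilial_victim", "multiple_victims", "csam_offense")


def score_sspi2(items: dict) -> tuple[int | None, int]:
    """Simple sum of the five yes/no items; returns (sum or None, items present)."""
    vals = [items.get(k) for k in SSPI2_ITEMS]
    present = sum(v is not None for v in vals)
    total = _sum_or_none(int(bool(v)) if v is not None else None for v in vals)
    return total, present


# ---------------------------------------------------------------------------
# STATIC-99-Dunkelfeld

@dataclass
class StaticDunkelfeldItems:
    """Adapted static-risk items (index-offense violence dropped).

    Binary items are 0/1; ``prior_sex_offenses`` keeps the instrument's
    0-3 charge/conviction grading and ``prior_convictions_count`` its 0-3
    grading.  ``None`` marks an unknown item.
    """

    ever_lived_with_partner_2y: int | None = None  # reverse-scored in the total
    prior_nonsexual_violence: int | None = None
    prior_sex_offenses: int | None = None  # 0-3
    prior_convictions_count: int | None = None  # 0-3
    noncontact_sex_conviction: int | None = None
    unrelated_victims: int | None = None
    stranger_victims: int | None = None
    male_victim: int | None = None
    two_or_more_young_victims: int | None = None  # from file; enters the paraphilia factor

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            hi = 3 if f.name in ("prior_sex_offenses", "prior_convictions_count") else 1
            if not 0 <= v <= hi:
                raise ValueError(f"{f.name}={v} outside 0-{hi}")


# documented maximum of the adapted total (age point + 8 items with
# prior_sex_offenses graded 0-3): 1+1+1+3+1+1+1+1+1
STATIC_DUNKELFELD_MAX_TOTAL = 11
STATIC_PARAPHILIA_MAX = 7
STATIC_YSA_MAX = 4
STATIC_GENERAL_CRIMINALITY_MAX = 4


@dataclass(frozen=True)
class StaticScores:
    total: int | None
    paraphilia: int | None
    youthful_stranger_aggression: int | None
    general_criminality: int | None


def score_static_dunkelfeld(items: StaticDunkelfeldItems, age_at_assessment: float | None) -> StaticScores:
    """Adapted total and the three factor scores; unknowns give NA per score."""
    items.validate()
    age_point = None if age_at_assessment is None else int(age_at_assessment < 25)
    partner_rev = None if items.ever_lived_with_partner_2y is None else 1 - items.ever_lived_with_partner_2y
    # the total uses the instrument's binary prior-sentencing point; the
    # general-criminality factor keeps the 0-3 convictions count
    convictions_point = (
        None if items.prior_convictions_count is None else min(items.prior_convictions_count, 1)
    )
    total = _sum_or_none(
        [
            age_point,
            partner_rev,
            items.prior_nonsexual_violence,
            items.prior_sex_offenses,
            convictions_point,
            items.noncontact_sex_conviction,
            items.unrelated_victims,
            items.stranger_victims,
            items.male_victim,
        ]
    )
    paraphilia = _sum_or_none(
        [
            items.prior_sex_offenses,
            items.noncontact_sex_conviction,
            items.male_victim,
            items.two_or_more_young_victims,
            items.unrelated_victims,
        ]
    )
    if None in (items.unrelated_victims, items.stranger_victims):
        unrelated_or_stranger = None
    else:
        unrelated_or_stranger = int(bool(items.unrelated_victims) or bool(items.stranger_victims))
    ysa = _sum_or_none(
        [age_point, partner_rev, items.prior_nonsexual_violence, unrelated_or_stranger]
    )
    crim = _sum_or_none([items.prior_convictions_count, items.prior_nonsexual_violence])
    return StaticScores(total, paraphilia, ysa, crim)


# ---------------------------------------------------------------------------
# STABLE-2007

STABLE_ITEMS = (
    "significant_social_influences",
    "capacity_for_relationship_stability",  # reverse coded in the antisociality factor
    "emotional_identification_with_children",
    "hostility_toward_women",
    "general_social_rejection",
    "lack_of_concern_for_others",
    "impulsive_acts",
    "poor_cognitive_problem_solving",
    "negative_emotionality",
    "sex_drive_preoccupation",
    "sex_as_coping",
    "deviant_sexual_interest",
    "cooperation_with_supervision",
)
STABLE_ANTISOCIALITY_ITEMS = (
    "capacity_for_relationship_stability",
    "hostility_toward_women",
    "general_social_rejection",
    "lack_of_concern_for_others",
    "impulsive_acts",
    "poor_cognitive_problem_solving",
    "negative_emotionality",
)
STABLE_SEXUAL_DEVIANCE_ITEMS = ("emotional_identification_with_children", "deviant_sexual_interest")
STABLE_HYPERSEXUALITY_ITEMS = ("sex_drive_preoccupation", "sex_as_coping")


@dataclass(frozen=True)
class StableScores:
    total: int | None
    antisociality: int | None
    sexual_deviance: int | None  # 0-4
    hypersexuality: int | None  # 0-4


def score_stable_factors(items: dict) -> StableScores:
    """Total (plain sum of 13 items, each 0-2) and the three factor scores."""
    for k in STABLE_ITEMS:
        v = items.get(k)
        if v is not None and not 0 <= v <= 2:
            raise ValueError(f"STABLE item {k}={v} outside 0-2")
    total = _sum_or_none(items.get(k) for k in STABLE_ITEMS)

    def anti_item(k):
        v = items.get(k)
        if v is None:
            return None
        return 2 - v if k == "capacity_for_relationship_stability" else v

    return StableScores(
        total=total,
        antisociality=_sum_or_none(anti_item(k) for k in STABLE_ANTISOCIALITY_ITEMS),
        sexual_deviance=_sum_or_none(items.get(k) for k in STABLE_SEXUAL_DEVIANCE_ITEMS),
        hypersexuality=_sum_or_none(items.get(k) for k in STABLE_HYPERSEXUALITY_ITEMS),
    )


# ---------------------------------------------------------------------------
# ACUTE-2007

ACUTE_ITEMS = (
    "victim_access",
    "hostility",
    "sexual_preoccupation",
    "rejection_of_supervision",
    "emotional_collapse",
    "collapse_of_social_support",
    "substance_abuse",
)


def score_acute(items: dict) -> int | None:
    """Sum of the seven acute risk items (each 0-2), range 0-14."""
    for k in ACUTE_ITEMS:
        v = items.get(k)
        if v is not None and not 0 <= v <= 2:
            raise ValueError(f"ACUTE item {k}={v} outside 0-2")
    return _sum_or_none(items.get(k) for k in ACUTE_ITEMS)


__all__ = [
    "SSPI2_ITEMS",
    "STABLE_ITEMS",
    "STABLE_ANTISOCIALITY_ITEMS",
    "STABLE_SEXUAL_DEVIANCE_ITEMS",
    "STABLE_HYPERSEXUALITY_ITEMS",
    "ACUTE_ITEMS",
    "STATIC_DUNKELFELD_MAX_TOTAL",
    "StaticDunkelfeldItems",
    "StaticScores",
    "StableScores",
    "score_sspi2",
    "score_static_dunkelfeld",
    "score_stable_factors",
    "score_acute",
]
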