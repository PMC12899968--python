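"""Questionnaire-derived quantities: IPAQ MET-minutes, activity-group
classification, and the composite appetite score.

MET-minutes per week weight self-reported activity minutes by metabolic
intensity: moderate minutes x 4 METs, vigorous minutes x 8 METs. A
participant belongs to the regular-physical-activity group (RPG) when they
report >=3 days/week of moderate-or-vigorous activity, >=30 min per
session, a total volume >=600 MET-min/week, and regular activity (>=2x/week
for >=30 min) over the prior six months. The inactive group (IAG) reports
no regular activity over six months and sits at the lowest IPAQ level,
operationalized here as total volume below 600 MET-min/week without
meeting the frequency-and-duration pattern. Everyone else is unclassified
and dropped from analysis; refused/unknown IPAQ answers are excluded
outright.

The composite appetite score averages four 0-100 mm visual-analog items
with fullness reverse-coded: (hunger + (100 - fullness) + desire +
prospective) / 4.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

MODERATE_MET = 4.0
VIGOROUS_MET = 8.0
RPG_MIN_DAYS = 3
RPG_MIN_SESSION_MIN = 30.0
RPG_MIN_METS = 600.0


def compute_mets(moderate_min_wk: float, vigorous_min_wk: float) -> float:
    """Weekly activity volume in MET-min/week: 4 x moderate + 8 x vigorous."""
    if moderate_min_wk < 0 or vigorous_min_wk < 0:
        raise ValueError(
            f"activity minutes must be nonnegative, got "
            f"({moderate_min_wk}, {vigorous_min_wk})"
        )
    return MODERATE_MET * moderate_min_wk + VIGOROUS_MET * vigorous_min_wk


def composite_appetite(
    hunger: float, fullness: float, desire: float, prospective: float
) -> float:
    """(hunger + (100 - fullness) + desire + prospective) / 4, all in mm."""
    for name, v in (
        ("hunger", hunger),
        ("fullness", fullness),
        ("desire", desire),
        ("prospective", prospective),
    ):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must be in [0, 100] mm, got {v}")
    return (hunger + (100.0 - fullness) + desire + prospective) / 4.0


def classify_group(record: Mapping) -> str:
    """Assign RPG / IAG / unclassified / excluded from IPAQ answers.

    ``record`` needs days_mvpa_per_wk, session_min, mets,
    six_month_regular, and ipaq_refused (truthy -> excluded).
    """
    if record.get("ipaq_refused", False):
        return "excluded"
    days = record["days_mvpa_per_wk"]
    session = record["session_min"]
    mets = record["mets"]
    six_month = bool(record["six_month_regular"])

    rpg = (
        days >= RPG_MIN_DAYS
        and session >= RPG_MIN_SESSION_MIN
        and mets >= RPG_MIN_METS
        and six_month
    )
    if rpg:
        return "RPG"
    iag = (
        not six_month
        and mets < RPG_MIN_METS
        and not (days >= RPG_MIN_DAYS and session >= RPG_MIN_SESSION_MIN)
    )
    if iag:
        return "IAG"
    return "unclassified"


def score_participants(participants: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh mets, composite_appetite and group columns on a
    participant table (returns a copy)."""
    df = participants.copy()
    df["mets"] = [
        compute_mets(m, v)
        for m, v in zip(df["moderate_min_wk"], df["vigorous_min_wk"])
    ]
    df["composite_appetite"] = [
        composite_appetite(h, f, d, p)
        for h, f, d, p in zip(df["hunger"], df["fullness"], df["desire"], df["prospective"])
    ]
    df["group"] = [classify_group(row) for row in df.to_dict("records")]
    return df
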