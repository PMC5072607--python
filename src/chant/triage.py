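"""Second-stage triage: neuropathic pain in the presence of neuropathy.

A screen-positive participant with bilateral feet pain on the body map is
assessed with the 7-item pain interview (the interview subset of the 10-item
neuropathic-pain questionnaire; the 3 examination items are excluded by
construction).  A score of >= 3/7 indicates neuropathic pain (NeP); bilateral
feet pain below that cutoff is classified as pain of probably neuropathic
origin (POPNO) pending confirmatory follow-up.  A screen-negative
participant with bilateral feet pain is referred for closer follow-up
(possible subclinical neuropathy).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ConfigurationError

DN4_POSITIVE_CUT = 3  # inclusive

#: the interview items, in scoring order
DN4_ITEM_NAMES = (
    "burning", "painful_cold", "electric_shocks", "tingling",
    "pins_and_needles", "numbness", "itching",
)

#: documented body-map vocabulary
BODYMAP_REGIONS = frozenset({
    "left_foot", "right_foot", "left_leg", "right_leg",
    "left_hand", "right_hand", "left_arm", "right_arm",
    "trunk", "head",
})


class TriageCategory(enum.Enum):
    NEP = "NeP"
    POPNO = "POPNO"
    NEUROPATHY_NO_BFP = "neuropathy_no_BFP"
    NO_NEUROPATHY_BFP_FOLLOWUP = "no_neuropathy_BFP_followup"
    NO_NEUROPATHY = "no_neuropathy"


@dataclass(frozen=True)
class TriageResult:
    chant_positive: bool
    bfp: bool
    dn4_score: int
    category: TriageCategory


def dn4i_score(items: Sequence[bool]) -> int:
    """Number of positive interview items (0-7)."""
    vals = list(items)
    if len(vals) != 7:
        raise ConfigurationError(f"the pain interview has 7 items, got {len(vals)}")
    return sum(bool(v) for v in vals)


def dn4i_positive(items: Sequence[bool]) -> bool:
    return dn4i_score(items) >= DN4_POSITIVE_CUT


def bfp_from_bodymap(marked_regions: Iterable[str]) -> bool:
    """Bilateral feet pain: both foot regions marked on the body map."""
    regions = set(marked_regions)
    unknown = regions - BODYMAP_REGIONS
    if unknown:
        raise ConfigurationError(
            f"unknown body-map regions: {sorted(unknown)}; "
            f"vocabulary: {sorted(BODYMAP_REGIONS)}"
        )
    return "left_foot" in regions and "right_foot" in regions


def classify(chant_positive: bool, bfp: bool, dn4_score: int) -> TriageResult:
    """Assign exactly one triage category."""
    if not 0 <= int(dn4_score) <= 7:
        raise ConfigurationError(f"dn4_score outside 0-7: {dn4_score}")
    chant_positive, bfp, dn4_score = bool(chant_positive), bool(bfp), int(dn4_score)
    if chant_positive and bfp:
        category = (TriageCategory.NEP if dn4_score >= DN4_POSITIVE_CUT
                    else TriageCategory.POPNO)
    elif chant_positive:
        category = TriageCategory.NEUROPATHY_NO_BFP
    elif bfp:
        category = TriageCategory.NO_NEUROPATHY_BFP_FOLLOWUP
    else:
        category = TriageCategory.NO_NEUROPATHY
    return TriageResult(chant_positive=chant_positive, bfp=bfp,
                        dn4_score=dn4_score, category=category)


def triage_cohort(cohort: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Triage every participant; ``scores`` is the output of
    :func:`chant.scorer.score_cohort` (matched on id)."""
    merged = cohort.merge(scores[["id", "chant_positive"]], on="id", validate="1:1")
    if len(merged) != len(cohort):
        raise ConfigurationError("cohort and score ids do not match")
    rows = []
    dn4_cols = [f"dn4_{i}" for i in range(1, 8)]
    for _, row in merged.iterrows():
        score = dn4i_score([row[c] for c in dn4_cols])
        result = classify(row["chant_positive"], row["bfp"], score)
        rows.append({
            "id": row["id"],
            "chant_positive": result.chant_positive,
            "bfp": result.bfp,
            "dn4_score": result.dn4_score,
            "category": result.category.value,
        })
    return pd.DataFrame(rows)
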