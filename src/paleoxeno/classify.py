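"""Rule-based consumption classification.

Drink type is a pure function of which methylxanthines are detected:
theobromine alone marks local herbal teas (Ivan tea contains theobromine
only), theobromine + caffeine marks green tea (theophylline is often absent
from green teas), all three mark black tea, and caffeine-led patterns mark
coffee or unattributed theophylline sources.

Tobacco consumption is tiered on the nicotine/cotinine mean (ND counted as
0), the two markers being too different in magnitude to use separately:
low < 200 pg/mg, medium 200-501, high 501-2500, very high > 2500.  The
medium tier is closed at 501 because one individual sits exactly on that
boundary and is classed as a medium consumer in the source assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, Individual, METHYLXANTHINES, TOBACCO_ANALYTES

__all__ = [
    "DRINKS",
    "TOBACCO_TIERS",
    "ConsumptionCall",
    "classify_drink",
    "classify_tobacco",
    "classify_cohort",
]

DRINKS = (
    "herbal_tea",
    "green_tea",
    "black_tea",
    "coffee",
    "coffee_and_theophylline",
    "theophylline_only",
    "nothing",
)

TOBACCO_TIERS = ("low", "medium", "high", "very_high")

# Detection pattern of (theobromine, caffeine, theophylline) -> drink label.
# The TB+TP pattern has no stated rule and never occurs in the builtin data;
# it maps to herbal_tea and is flagged (theobromine-led, caffeine-free).
_PATTERN_TO_DRINK: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "herbal_tea",
    (True, True, False): "green_tea",
    (True, True, True): "black_tea",
    (False, True, False): "coffee",
    (False, True, True): "coffee_and_theophylline",
    (False, False, True): "theophylline_only",
    (True, False, True): "herbal_tea",
    (False, False, False): "nothing",
}


@dataclass(frozen=True)
class ConsumptionCall:
    """Drink type and tobacco tier for one individual."""

    sample_id: int
    drink: str
    tobacco_index: float  # mean of nicotine and cotinine, pg/mg, ND -> 0
    tobacco_tier: str
    #: True for the theobromine+theophylline pattern, which has no stated
    #: rule and is conservatively labelled herbal_tea.
    unruled_pattern: bool = False


def methylxanthine_pattern(ind: Individual) -> tuple[bool, bool, bool]:
    """Detection status of (theobromine, caffeine, theophylline)."""
    return tuple(not ind.conc(a).is_nd for a in METHYLXANTHINES)  # type: ignore[return-value]


def classify_drink(ind: Individual) -> str:
    """Map the methylxanthine detection pattern to a drink label."""
    return _PATTERN_TO_DRINK[methylxanthine_pattern(ind)]


def tobacco_index(ind: Individual) -> float:
    vals = [
        0.0 if ind.conc(a).is_nd else float(ind.conc(a).value)
        for a in TOBACCO_ANALYTES
    ]
    return sum(vals) / len(vals)


def tier_of(index: float) -> str:
    """Tier from the tobacco index; medium is closed at 501 pg/mg."""
    if index < 200:
        return "low"
    if index <= 501:
        return "medium"
    if index <= 2500:
        return "high"
    return "very_high"


def classify_tobacco(ind: Individual) -> tuple[float, str]:
    idx = tobacco_index(ind)
    return idx, tier_of(idx)


def classify_individual(ind: Individual) -> ConsumptionCall:
    pattern = methylxanthine_pattern(ind)
    idx, tier = classify_tobacco(ind)
    return ConsumptionCall(
        sample_id=ind.sample_id,
        drink=_PATTERN_TO_DRINK[pattern],
        tobacco_index=idx,
        tobacco_tier=tier,
        unruled_pattern=pattern == (True, False, True),
    )


def classify_cohort(cohort: Cohort) -> pd.DataFrame:
    """One consumption call per individual, keyed by sample_id."""
    calls = [classify_individual(ind) for ind in cohort]
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "drink": [c.drink for c in calls],
            "tobacco_index": [c.tobacco_index for c in calls],
            "tobacco_tier": [c.tobacco_tier for c in calls],
            "unruled_pattern": [c.unruled_pattern for c in calls],
        }
    )
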