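"""Classification of retail establishments into food-outlet categories and health tiers.

Seven in-scope NAICS codes are recognised; everything else is NON_FOOD.
Two reclassification rules apply:

* grocery-coded stores (NAICS 445110) with fewer than five employees are
  treated as convenience stores;
* general-merchandise stores coded 452319 count as dollar stores only when
  the establishment name contains the token ``dollar`` (case-insensitive).
"""

from __future__ import annotations

import enum
from typing import Mapping

import pandas as pd

__all__ = [
    "OutletCategory",
    "HealthTier",
    "NAICS_TO_CATEGORY",
    "DEFAULT_TIER_MAP",
    "classify",
    "health_tier",
    "classify_frame",
]


class OutletCategory(str, enum.Enum):
    SUPERMARKET_GROCERY = "SUPERMARKET_GROCERY"
    FRUIT_VEG_MARKET = "FRUIT_VEG_MARKET"
    SUPERCENTRE = "SUPERCENTRE"
    CONVENIENCE = "CONVENIENCE"
    DOLLAR = "DOLLAR"
    FULL_SERVICE_RESTAURANT = "FULL_SERVICE_RESTAURANT"
    LIMITED_SERVICE_RESTAURANT = "LIMITED_SERVICE_RESTAURANT"
    NON_FOOD = "NON_FOOD"


class HealthTier(str, enum.Enum):
    HEALTHY = "HEALTHY"
    INTERMEDIATE = "INTERMEDIATE"
    UNHEALTHY = "UNHEALTHY"
    NONE = "NONE"


NAICS_TO_CATEGORY: Mapping[str, OutletCategory] = {
    "445110": OutletCategory.SUPERMARKET_GROCERY,
    "445230": OutletCategory.FRUIT_VEG_MARKET,
    "452311": OutletCategory.SUPERCENTRE,
    "445120": OutletCategory.CONVENIENCE,
    "452319": OutletCategory.DOLLAR,
    "722511": OutletCategory.FULL_SERVICE_RESTAURANT,
    "722513": OutletCategory.LIMITED_SERVICE_RESTAURANT,
}

# Dollar stores are not tier-assigned in the three-tier scheme's source text;
# they default to UNHEALTHY (overridable via ``dollar_tier``).
DEFAULT_TIER_MAP: Mapping[OutletCategory, HealthTier] = {
    OutletCategory.SUPERMARKET_GROCERY: HealthTier.HEALTHY,
    OutletCategory.FRUIT_VEG_MARKET: HealthTier.HEALTHY,
    OutletCategory.SUPERCENTRE: HealthTier.HEALTHY,
    OutletCategory.CONVENIENCE: HealthTier.UNHEALTHY,
    OutletCategory.LIMITED_SERVICE_RESTAURANT: HealthTier.UNHEALTHY,
    OutletCategory.DOLLAR: HealthTier.UNHEALTHY,
    OutletCategory.FULL_SERVICE_RESTAURANT: HealthTier.INTERMEDIATE,
    OutletCategory.NON_FOOD: HealthTier.NONE,
}

GROCERY_NAICS = "445110"
DOLLAR_NAICS = "452319"
EMPLOYEE_RECLASS_THRESHOLD = 5  # strictly fewer than five reclassifies


class ClassificationError(ValueError):
    """Raised for malformed establishment records."""


def _validate_naics(naics: object, context: str = "") -> str:
    code = str(naics).strip()
    if len(code) != 6 or not code.isdigit():
        where = f" ({context})" if context else ""
        raise ClassificationError(f"malformed NAICS code {naics!r}{where}: expected 6 digits")
    return code


def classify(naics: object, employees: int, name: str) -> OutletCategory:
    """Map one establishment record to its outlet category.

    Parameters
    ----------
    naics
        Six-digit NAICS code (string or integer).
    employees
        Year-specific employee count, ``>= 0``.
    name
        Establishment name, used only for the dollar-store token rule.
    """
    code = _validate_naics(naics)
    if employees < 0:
        raise ClassificationError(f"negative employee count {employees} for NAICS {code}")
    category = NAICS_TO_CATEGORY.get(code, OutletCategory.NON_FOOD)
    if category is OutletCategory.SUPERMARKET_GROCERY and employees < EMPLOYEE_RECLASS_THRESHOLD:
        return OutletCategory.CONVENIENCE
    if category is OutletCategory.DOLLAR and "dollar" not in str(name).strip().lower():
        return OutletCategory.NON_FOOD
    return category


def health_tier(
    category: OutletCategory,
    dollar_tier: HealthTier = HealthTier.UNHEALTHY,
) -> HealthTier:
    """Map an outlet category to its health tier.

    ``dollar_tier`` overrides the tier of dollar stores, whose placement in
    the three-tier scheme is a configurable policy choice.
    """
    category = OutletCategory(category)
    if category is OutletCategory.DOLLAR:
        return HealthTier(dollar_tier)
    return DEFAULT_TIER_MAP[category]


def classify_frame(
    establishments: pd.DataFrame,
    dollar_tier: HealthTier = HealthTier.UNHEALTHY,
) -> pd.DataFrame:
    """Append ``category`` and ``tier`` columns to an establishment table.

    Expects columns ``naics``, ``employees``, ``name``; the input frame is
    not modified. Classification is row-local so the result is independent
    of row order.
    """
    required = {"naics", "employees", "name"}
    missing = required - set(establishments.columns)
    if missing:
        raise ClassificationError(f"establishment table missing columns: {sorted(missing)}")
    out = establishments.copy()
    naics = out["naics"].astype(str).str.strip()
    bad = ~(naics.str.len().eq(6) & naics.str.isdigit())
    if bad.any():
        idx = out.index[bad][0]
        raise ClassificationError(
            f"malformed NAICS code {out.loc[idx, 'naics']!r} at row {idx}"
        )
    employees = pd.to_numeric(out["employees"])
    if (employees < 0).any():
        idx = out.index[employees < 0][0]
        raise ClassificationError(f"negative employee count at row {idx}")

    category = naics.map(lambda c: NAICS_TO_CATEGORY.get(c, OutletCategory.NON_FOOD).value)
    grocery_small = naics.eq(GROCERY_NAICS) & (employees < EMPLOYEE_RECLASS_THRESHOLD)
    category = category.mask(grocery_small, OutletCategory.CONVENIENCE.value)
    no_dollar_name = naics.eq(DOLLAR_NAICS) & ~out["name"].astype(str).str.strip().str.lower().str.contains(
        "dollar", regex=False
    )
    category = category.mask(no_dollar_name, OutletCategory.NON_FOOD.value)

    tier_map = {c.value: health_tier(c, dollar_tier).value for c in OutletCategory}
    out["category"] = category
    out["tier"] = category.map(tier_map)
    return out
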