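"""Tract-year food-environment indices.

Aggregates classified establishments into a balanced tract-year panel of
outlet counts by health tier, the modified Retail Food Environment Index
(mRFEI), the Herfindahl-Hirschman index (HHI) of sales concentration, the
HHI concentration band, and a USDA-style food-desert classifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import HealthTier

__all__ = [
    "HHIBand",
    "FoodDesertInput",
    "compute_mrfei",
    "compute_hhi",
    "hhi_band",
    "classify_food_desert",
    "build_panel",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = [
    "tract_id",
    "year",
    "n_healthy",
    "n_intermediate",
    "n_unhealthy",
    "mrfei",
    "hhi",
    "hhi_band",
    "no_outlets",
]


class HHIBand(str, enum.Enum):
    COMPETITIVE = "COMPETITIVE"
    MODERATE = "MODERATE"
    HIGH = "HIGH"
    EMPTY = "EMPTY"


class IndexInputError(ValueError):
    pass


def compute_mrfei(n_healthy: int, n_unhealthy: int) -> tuple[float, bool]:
    """Percentage of healthy outlets among healthy + unhealthy outlets.

    Returns ``(score, no_outlets)``; the score is 0 with ``no_outlets=True``
    when both counts are zero. Intermediate-tier outlets do not enter.
    """
    if n_healthy < 0 or n_unhealthy < 0:
        raise IndexInputError(f"negative outlet counts ({n_healthy}, {n_unhealthy})")
    denom = n_healthy + n_unhealthy
    if denom == 0:
        return 0.0, True
    return 100.0 * n_healthy / denom, False


def compute_hhi(sales: Sequence[float] | Iterable[float]) -> tuple[float, bool]:
    """Sum of squared percentage market shares; 10000 for a monopoly.

    Returns ``(points, no_outlets)``; 0 with ``no_outlets=True`` for an
    empty market.
    """
    s = np.asarray(list(sales), dtype=float)
    if s.size == 0:
        return 0.0, True
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise IndexInputError("all sales must be positive and finite")
    shares = 100.0 * s / s.sum()
    return float(min(np.sum(shares**2), 10000.0)), False


def hhi_band(hhi: float, no_outlets: bool = False) -> HHIBand:
    """Concentration band: <1500 competitive, 1500-2500 moderate, >=2500 high."""
    if no_outlets:
        return HHIBand.EMPTY
    if not (0 <= hhi <= 10000):
        raise IndexInputError(f"HHI {hhi} outside [0, 10000]")
    if hhi < 1500:
        return HHIBand.COMPETITIVE
    if hhi < 2500:
        return HHIBand.MODERATE
    return HHIBand.HIGH


@dataclass(frozen=True)
class FoodDesertInput:
    """Inputs to the two-criterion (low-income and low-access) definition."""

    poverty_rate: float
    income_ratio: float  # tract median family income / area median family income
    persons_low_access: int  # residents > 1 mile from a supermarket
    population: int

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise IndexInputError("population must be positive")
        if self.income_ratio <= 0:
            raise IndexInputError("income_ratio must be positive")
        if self.persons_low_access > self.population:
            raise IndexInputError("persons_low_access exceeds population")


def is_low_income(poverty_rate: float, income_ratio: float) -> bool:
    return poverty_rate >= 20.0 or income_ratio <= 0.80


def is_low_access(persons_low_access: int, population: int) -> bool:
    if population <= 0:
        raise IndexInputError("population must be positive")
    return persons_low_access >= 500 and persons_low_access / population >= 0.33


def classify_food_desert(inp: FoodDesertInput) -> bool:
    """Low-income AND low-access: poverty >= 20% or income ratio <= 0.80,
    and at least 500 persons and at least 33% of the population low-access."""
    return is_low_income(inp.poverty_rate, inp.income_ratio) and is_low_access(
        inp.persons_low_access, inp.population
    )


def build_panel(
    classified: pd.DataFrame,
    years: Sequence[int],
    tract_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate classified establishments to a balanced tract-year panel.

    Parameters
    ----------
    classified
        Establishment table with columns ``establishment_id``, ``tract_id``,
        ``year``, ``sales``, ``tier`` (and optionally ``category``).
        NON_FOOD rows (tier NONE) are excluded from counts and sales shares.
    years
        Full year grid; every tract gets one row per year, zero-filled with
        ``no_outlets`` set where no in-scope outlet is present.
    tract_ids
        Optional explicit tract universe (e.g. from the geometry file); by
        default the tracts observed in ``classified``.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise IndexInputError("empty year grid")
    df = classified.copy()
    df["year"] = df["year"].astype(int)
    df["tract_id"] = df["tract_id"].astype(str)

    dup = df.duplicated(subset=["tract_id", "year", "establishment_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise IndexInputError(
            "duplicate establishment_id "
            f"{row['establishment_id']!r} in tract {row['tract_id']} year {row['year']}"
        )

    in_scope = df[df["tier"] != HealthTier.NONE.value]
    in_scope = in_scope[in_scope["year"].isin(years)]

    if tract_ids is None:
        tracts = sorted(df["tract_id"].unique())
    else:
        tracts = sorted(str(t) for t in tract_ids)
    if not tracts:
        raise IndexInputError("no tracts to build a panel over")

    counts = (
        in_scope.groupby(["tract_id", "year", "tier"], observed=True)
        .size()
        .unstack("tier", fill_value=0)
    )
    for tier in (HealthTier.HEALTHY, HealthTier.INTERMEDIATE, HealthTier.UNHEALTHY):
        if tier.value not in counts.columns:
            counts[tier.value] = 0

    grid = pd.MultiIndex.from_product([tracts, years], names=["tract_id", "year"])
    counts = counts.reindex(grid, fill_value=0)

    def _group_hhi(s: pd.Series) -> float:
        return compute_hhi(s.to_numpy())[0]

    hhi = in_scope.groupby(["tract_id", "year"])["sales"].apply(_group_hhi)
    hhi = hhi.reindex(grid, fill_value=0.0)

    panel = pd.DataFrame(
        {
            "n_healthy": counts[HealthTier.HEALTHY.value].astype(int),
            "n_intermediate": counts[HealthTier.INTERMEDIATE.value].astype(int),
            "n_unhealthy": counts[HealthTier.UNHEALTHY.value].astype(int),
            "hhi": hhi.astype(float),
        }
    ).reset_index()

    n_scored = panel["n_healthy"] + panel["n_unhealthy"]
    panel["no_outlets"] = (
        panel[["n_healthy", "n_intermediate", "n_unhealthy"]].sum(axis=1) == 0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mrfei = 100.0 * panel["n_healthy"] / n_scored
    panel["mrfei"] = mrfei.fillna(0.0)
    panel["hhi_band"] = [
        hhi_band(h, no).value for h, no in zip(panel["hhi"], panel["no_outlets"])
    ]
    return panel[PANEL_COLUMNS].sort_values(["tract_id", "year"]).reset_index(drop=True)
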