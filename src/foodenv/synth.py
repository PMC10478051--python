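"""Synthetic establishment registries, tract attribute panels and lattice geometries.

Emulates the schema of a longitudinal establishment registry (one row per
establishment-year with NAICS code, name, employees, sales and tract id)
plus a tract-year demographic panel, with known ground-truth structure:
outlet counts follow a log-linear Poisson intensity with user-chosen
coefficients (``beta_true``), tract and year log-intensity effects, and an
optional planted cluster of elevated healthy-outlet intensity. Everything
is reproducible from one root seed via spawned child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geo import TractGeometry, write_geojson
from .taxonomy import NAICS_TO_CATEGORY, OutletCategory

__all__ = [
    "ClusterSpec",
    "SynthConfig",
    "generate_lattice",
    "generate_attributes",
    "generate_category_counts",
    "generate_establishments",
    "write_bundle",
]

CATEGORY_TO_NAICS = {cat.value: code for code, cat in NAICS_TO_CATEGORY.items()}
NON_FOOD_NAICS = "531120"  # out-of-scope filler code

HEALTHY_CATEGORIES = ("SUPERMARKET_GROCERY", "FRUIT_VEG_MARKET", "SUPERCENTRE")

DEFAULT_BASE_RATES: Mapping[str, float] = {
    "SUPERMARKET_GROCERY": 1.2,
    "FRUIT_VEG_MARKET": 0.2,
    "SUPERCENTRE": 0.15,
    "CONVENIENCE": 1.5,
    "DOLLAR": 0.4,
    "FULL_SERVICE_RESTAURANT": 1.0,
    "LIMITED_SERVICE_RESTAURANT": 1.8,
}

# lognormal sales log-means per category (sigma shared); heavy tails give
# non-degenerate HHI variation
SALES_LOG_MEAN: Mapping[str, float] = {
    "SUPERMARKET_GROCERY": 14.5,
    "FRUIT_VEG_MARKET": 12.0,
    "SUPERCENTRE": 16.5,
    "CONVENIENCE": 12.5,
    "DOLLAR": 13.0,
    "FULL_SERVICE_RESTAURANT": 13.2,
    "LIMITED_SERVICE_RESTAURANT": 13.0,
    "NON_FOOD": 12.0,
}
SALES_LOG_SD = 0.8

_NAME_STEMS: Mapping[str, tuple[str, ...]] = {
    "SUPERMARKET_GROCERY": ("Fresh Market", "Valley Grocery", "Corner Foods", "Grand Supermarket"),
    "FRUIT_VEG_MARKET": ("Green Grocers", "Farm Stand", "Produce Patch"),
    "SUPERCENTRE": ("MegaCentre", "ShopAll Supercentre"),
    "CONVENIENCE": ("QuickStop", "Night Owl Mart", "Gas N Go"),
    "FULL_SERVICE_RESTAURANT": ("Blue Plate Diner", "Trattoria Roma", "The Oak Table"),
    "LIMITED_SERVICE_RESTAURANT": ("Burger Barn", "Taco Express", "Pizza Pronto"),
    "NON_FOOD": ("Ace Hardware Annex", "Style Salon", "Prime Lessors"),
}
_DOLLAR_STEMS = ("Dollar Depot", "Family Dollar Mart", "Lucky Dollar")
_NON_DOLLAR_STEMS = ("Bargain Bin", "Value Variety", "Thrift Corner")


@dataclass(frozen=True)
class ClusterSpec:
    """Planted cluster: healthy-category intensity is multiplied inside a
    Chebyshev radius of the centre cell."""

    center_row: int
    center_col: int
    radius: int
    multiplier: float

    def contains(self, row: int, col: int) -> bool:
        return max(abs(row - self.center_row), abs(col - self.center_col)) <= self.radius


@dataclass(frozen=True)
class SynthConfig:
    n_rows: int = 5
    n_cols: int = 5
    years: tuple[int, int] = (2000, 2019)  # inclusive
    seed: int = 0
    beta_true: Mapping[str, float] = field(default_factory=dict)
    fe_sd_tract: float = 0.15
    fe_sd_year: float = 0.05
    category_base_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    metro_fraction: float = 0.7
    cluster_spec: ClusterSpec | None = None
    grocery_small_prob: float = 0.3  # P(employees < 5 | grocery-coded)
    dollar_plain_name_frac: float = 0.2  # fraction of 452319 records without "dollar"
    nonfood_rate: float = 0.8  # Poisson rate of filler establishments per tract-year

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        if not 0 <= self.metro_fraction <= 1:
            raise ValueError("metro_fraction must be in [0, 1]")
        unknown = set(self.category_base_rates) - set(DEFAULT_BASE_RATES)
        if unknown:
            raise ValueError(f"unknown outlet categories in base rates: {sorted(unknown)}")
        if any(r <= 0 for r in self.category_base_rates.values()):
            raise ValueError("all category base rates must be positive")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def child_seed(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the root seed."""
        order = ["lattice", "attributes", "counts_fe", "counts_draw", "establishments"]
        ss = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(ss[order.index(stage)])


def tract_id_for(row: int, col: int) -> str:
    return f"{row:03d}{col:03d}"


def generate_lattice(config: SynthConfig) -> list[TractGeometry]:
    """Unit-square lattice of ``n_rows x n_cols`` tracts in row-major order."""
    geoms = []
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            poly = Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)])
            geoms.append(TractGeometry(tract_id_for(r, c), poly))
    return geoms


def generate_attributes(config: SynthConfig, geoms: list[TractGeometry]) -> pd.DataFrame:
    """One row per tract-year with race/ethnicity percentages, controls and
    SVI scores.

    Race shares (White/Black/Asian/other) come from one Dirichlet draw per
    tract; the White share drifts linearly over years against the "other"
    remainder, so ``pct_white + pct_black + pct_asian <= 100`` holds for
    every row and within-tract variation exists for fixed-effects models.
    The Hispanic percentage is an independent axis with its own drift. SVI
    scores are rank-normalised transforms of poverty and minority share, so
    higher minority share implies a higher minority-language sub-theme by
    construction.
    """
    if not geoms:
        raise ValueError("no geometries supplied")
    rng = config.child_seed("attributes")
    tracts = [g.tract_id for g in geoms]
    n = len(tracts)
    years = np.array(config.year_list)
    t = years - years[0]
    ny = len(years)

    shares = rng.dirichlet([8.0, 2.0, 1.0, 2.0], size=n) * 100.0  # W, B, A, other
    white0, black0, asian0, other0 = shares.T
    # each named race share drifts linearly against the unnamed remainder;
    # slopes are capped so every share stays non-negative and the named
    # shares never exceed 100 in total
    span = max(t[-1], 1)
    caps = np.minimum(np.stack([white0, black0, asian0]), other0[None, :] / 3.0) / (2.0 * span)
    slopes = rng.uniform(-1.0, 1.0, size=(3, n)) * caps
    slope, black_slope, asian_slope = slopes

    hisp0 = rng.beta(2.0, 5.0, size=n) * 100.0
    hisp_cap = np.minimum(hisp0, 100.0 - hisp0) / (2.0 * span)
    hisp_slope = rng.uniform(-1.0, 1.0, size=n) * hisp_cap

    pov0 = rng.beta(2.0, 6.0, size=n) * 100.0
    pov_cap = np.minimum(pov0, 100.0 - pov0) / (2.0 * span)
    pov_slope = rng.uniform(-1.0, 1.0, size=n) * pov_cap

    bach0 = rng.beta(3.0, 5.0, size=n) * 100.0
    bach_cap = np.minimum(bach0, 100.0 - bach0) / (2.0 * span)
    bach_slope = rng.uniform(-1.0, 1.0, size=n) * bach_cap

    pop0 = rng.lognormal(np.log(4000.0), 0.4, size=n)
    pop_growth = rng.normal(0.0, 0.01, size=n)

    metro = rng.random(n) < config.metro_fraction

    rows = {
        "tract_id": np.repeat(tracts, ny),
        "year": np.tile(years, n),
        "pct_white": (white0[:, None] + slope[:, None] * t[None, :]).ravel(),
        "pct_black": (black0[:, None] + black_slope[:, None] * t[None, :]).ravel(),
        "pct_asian": (asian0[:, None] + asian_slope[:, None] * t[None, :]).ravel(),
        "pct_hispanic": (hisp0[:, None] + hisp_slope[:, None] * t[None, :]).ravel(),
        "population": np.rint(
            pop0[:, None] * np.exp(pop_growth[:, None] * t[None, :])
        ).astype(int).ravel(),
        "pct_bachelor": (bach0[:, None] + bach_slope[:, None] * t[None, :]).ravel(),
        "poverty_rate": (pov0[:, None] + pov_slope[:, None] * t[None, :]).ravel(),
        "metro": np.repeat(metro, ny),
    }
    df = pd.DataFrame(rows)

    def _rank01(v: pd.Series) -> pd.Series:
        return (v.rank(method="average") - 0.5) / len(v)

    minority = 100.0 - df["pct_white"]
    noise = rng.normal(0.0, 5.0, size=(4, len(df)))
    df["svi_ses"] = _rank01(df["poverty_rate"] + noise[0])
    df["svi_household"] = _rank01(df["poverty_rate"] + noise[1] * 2.0)
    df["svi_minority_language"] = _rank01(minority + df["pct_hispanic"] * 0.5 + noise[2])
    df["svi_housing_transport"] = _rank01(-df["pct_bachelor"] + noise[3] * 2.0)
    df["svi_overall"] = _rank01(
        df[["svi_ses", "svi_household", "svi_minority_language", "svi_housing_transport"]].sum(axis=1)
    )
    return df


def _log_intensity(config: SynthConfig, attrs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Log-intensity components aligned to attrs rows.

    Returns ``(fe_part, beta_part)``: tract + year log effects, and
    beta_true * attributes. The beta part is applied to healthy categories
    only, so attribute effects move both healthy counts and the
    healthy-share index rather than scaling all categories equally.
    """
    rng = config.child_seed("counts_fe")
    tracts = np.sort(attrs["tract_id"].unique())
    years = np.array(config.year_list)
    fe_tract = rng.normal(0.0, config.fe_sd_tract, size=len(tracts))
    fe_year = rng.normal(0.0, config.fe_sd_year, size=len(years))
    ti = pd.Series(np.arange(len(tracts)), index=tracts)
    yi = pd.Series(np.arange(len(years)), index=years)

    fe_part = fe_tract[ti[attrs["tract_id"]].to_numpy()] + fe_year[yi[attrs["year"]].to_numpy()]
    beta_part = np.zeros(len(attrs))
    for name, beta in config.beta_true.items():
        if name not in attrs.columns:
            raise ValueError(f"beta_true refers to unknown attribute {name!r}")
        beta_part = beta_part + beta * attrs[name].to_numpy(dtype=float)
    return fe_part, beta_part


def generate_category_counts(config: SynthConfig, attrs: pd.DataFrame) -> pd.DataFrame:
    """Tract-year-category outlet counts, Poisson with log-linear mean.

    For healthy categories,
    log E[count] = log(base rate) + beta_true . attributes + tract effect
    + year effect (+ log multiplier inside the planted cluster); other
    categories omit the beta_true term (attribute effects shift the healthy
    share, not the overall outlet volume). Returned long with columns
    tract_id, year, category, count, log_mean.
    """
    fe_part, beta_part = _log_intensity(config, attrs)
    rng = config.child_seed("counts_draw")

    in_cluster = np.zeros(len(attrs), dtype=bool)
    if config.cluster_spec is not None:
        rows = attrs["tract_id"].str[:3].astype(int)
        cols = attrs["tract_id"].str[3:6].astype(int)
        cs = config.cluster_spec
        in_cluster = (
            np.maximum(np.abs(rows - cs.center_row), np.abs(cols - cs.center_col)) <= cs.radius
        ).to_numpy()

    frames = []
    for cat in sorted(config.category_base_rates):
        log_mean = np.log(config.category_base_rates[cat]) + fe_part
        if cat in HEALTHY_CATEGORIES:
            log_mean = log_mean + beta_part
            if config.cluster_spec is not None:
                log_mean = log_mean + np.where(
                    in_cluster, np.log(config.cluster_spec.multiplier), 0.0
                )
        log_mean = np.clip(log_mean, -30.0, 10.0)
        counts = rng.poisson(np.exp(log_mean))
        frames.append(
            pd.DataFrame(
                {
                    "tract_id": attrs["tract_id"].to_numpy(),
                    "year": attrs["year"].to_numpy(),
                    "category": cat,
                    "count": counts,
                    "log_mean": log_mean,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _employees_for(rng: np.random.Generator, category: np.ndarray, small_prob: float) -> np.ndarray:
    """Category-typical employee counts; grocery-coded stores are bimodal
    (mode < 5 with probability ``small_prob``, else >= 20) so the
    convenience reclassification rule bites on a known fraction."""
    n = len(category)
    emp = np.zeros(n, dtype=int)
    is_grocery = category == "SUPERMARKET_GROCERY"
    small = rng.random(n) < small_prob
    emp[is_grocery & small] = rng.integers(0, 5, size=int((is_grocery & small).sum()))
    emp[is_grocery & ~small] = 20 + rng.poisson(15.0, size=int((is_grocery & ~small).sum()))
    typical = {
        "FRUIT_VEG_MARKET": 4.0,
        "SUPERCENTRE": 120.0,
        "CONVENIENCE": 3.0,
        "DOLLAR": 8.0,
        "FULL_SERVICE_RESTAURANT": 18.0,
        "LIMITED_SERVICE_RESTAURANT": 12.0,
        "NON_FOOD": 6.0,
    }
    for cat, lam in typical.items():
        mask = category == cat
        emp[mask] = rng.poisson(lam, size=int(mask.sum()))
    return emp


def generate_establishments(
    config: SynthConfig,
    attrs: pd.DataFrame,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand category counts into establishment-year records.

    Dollar-category records get a name containing "Dollar" except for a
    ``dollar_plain_name_frac`` fraction (exercising the name filter); a
    ``nonfood_rate`` Poisson stream of out-of-scope filler records is added.
    """
    if counts is None:
        counts = generate_category_counts(config, attrs)
    rng = config.child_seed("establishments")

    counts = counts.sort_values(["tract_id", "year", "category"], kind="stable")
    nonfood = attrs[["tract_id", "year"]].copy().sort_values(["tract_id", "year"])
    nonfood["category"] = "NON_FOOD"
    nonfood["count"] = rng.poisson(config.nonfood_rate, size=len(nonfood))
    counts = pd.concat([counts[["tract_id", "year", "category", "count"]], nonfood], ignore_index=True)
    counts = counts[counts["count"] > 0]

    reps = counts["count"].to_numpy()
    tract = np.repeat(counts["tract_id"].to_numpy(), reps)
    year = np.repeat(counts["year"].to_numpy(), reps)
    category = np.repeat(counts["category"].to_numpy(), reps)
    n = len(tract)

    naics = np.array([CATEGORY_TO_NAICS.get(c, NON_FOOD_NAICS) for c in category])
    employees = _employees_for(rng, category, config.grocery_small_prob)
    mu = np.array([SALES_LOG_MEAN[c] for c in category])
    sales = np.exp(rng.normal(mu, SALES_LOG_SD))

    names = np.empty(n, dtype=object)
    stem_pick = rng.integers(0, 1_000_000, size=n)
    plain = rng.random(n) < config.dollar_plain_name_frac
    for i in range(n):
        cat = category[i]
        if cat == "DOLLAR":
            stems = _NON_DOLLAR_STEMS if plain[i] else _DOLLAR_STEMS
        else:
            stems = _NAME_STEMS[cat]
        names[i] = f"{stems[stem_pick[i] % len(stems)]} #{i:05d}"

    return pd.DataFrame(
        {
            "establishment_id": [f"E{i:07d}" for i in range(n)],
            "tract_id": tract,
            "year": year.astype(int),
            "naics": naics,
            "name": names,
            "employees": employees,
            "sales": np.round(sales, 2),
        }
    )


def write_bundle(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write establishments.csv, tract_attributes.csv and
    tracts.geojson; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geoms = generate_lattice(config)
    attrs = generate_attributes(config, geoms)
    est = generate_establishments(config, attrs)
    paths = {
        "establishments": outdir / "establishments.csv",
        "tract_attributes": outdir / "tract_attributes.csv",
        "tracts": outdir / "tracts.geojson",
    }
    est.to_csv(paths["establishments"], index=False)
    attrs.to_csv(paths["tract_attributes"], index=False)
    write_geojson(geoms, paths["tracts"])
    return paths


def config_with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    return replace(config, seed=seed)
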