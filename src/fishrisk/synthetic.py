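"""Synthetic inputs for the whole pipeline.

Real runs of this analysis consume reconstructed-catch panels, spatially
allocated catch, port gazetteers, national slavery-prevalence estimates and
bilateral seafood trade flows. This module generates stand-ins with the
statistical structure the downstream stages assume, so everything is testable
end to end without external databases:

* a country x year industrial-landings panel with year-to-year noise around
  country-level means (years are treated as i.i.d. — the analysis only ever
  uses decade means and spreads);
* half-degree catch cells allocated from the panel totals, with EEZ
  attribution and domestic ports, built to realise per-country targets for
  "% catch outside EEZ" and catch-weighted mean distance from home;
* slavery-prevalence estimates with a planted linear dependence on the
  fisheries metrics (for parameter-recovery tests), truncated at zero, with
  95% CIs of configurable relative half-width;
* a sparse exporter→importer trade matrix of HS6 class-03 commodities.

Countries are drawn from a configurable set of cluster archetypes over the
six typology variables, so the clustering stage has separable structure to
recover. One RNG stream per generator (seeded from ``config.seed`` plus a
fixed per-generator offset) keeps the generators independent: adding one
never perturbs another. The generators make no attempt to mimic the real
global catch distribution, real port geography, or real HS6 composition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .metrics import EARTH_RADIUS_KM, HIGH_SEAS

# Fixed per-generator RNG stream offsets (spawned as (seed, offset) pairs).
_STREAM_PROFILES = 0
_STREAM_PANEL = 1
_STREAM_SPATIAL = 2
_STREAM_SLAVERY = 3
_STREAM_TRADE = 4

# Small pool of HS6 codes in class 03 (fish and seafood products).
_HS6_POOL = ("030342", "030487", "030613", "030749")


@dataclass(frozen=True)
class ClusterArchetype:
    """Mean vector over the six typology variables, plus a relative spread.

    A country assigned to an archetype draws each of its six target values
    from Normal(mean, rel_sd * mean), truncated away from zero.
    """

    name: str
    pct_unreported: float
    value_per_fisher: float
    pct_catch_outside_eez: float
    gdp_per_capita_usd: float
    pct_subsidy: float
    mean_distance_km: float
    rel_sd: float = 0.08


#: Three default archetypes: subsidised distant-water fleets with poor
#: reporting; lower-income, largely domestic fisheries; and wealthy,
#: well-monitored fisheries. They emulate the separable country groups the
#: typology stage is expected to recover.
DEFAULT_ARCHETYPES = (
    ClusterArchetype("distant_water", 40.0, 30_000.0, 60.0, 25_000.0, 35.0, 6000.0),
    ClusterArchetype("domestic_developing", 30.0, 8_000.0, 5.0, 8_000.0, 8.0, 600.0),
    ClusterArchetype("wealthy_domestic", 5.0, 120_000.0, 15.0, 55_000.0, 12.0, 1500.0),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    The planted prevalence model is
    ``prevalence_i = intercept + effect_unreported * pct_unreported_i
    + effect_value * landed_value_per_kg_i + Normal(0, noise_sd)``,
    truncated at zero, in victims per 1000 population. Default effect signs
    match the direction the analysis expects to detect: prevalence rises
    with unreported catch and falls with the unit value of the catch.
    """

    n_countries: int = 20
    years: tuple[int, int] = (2005, 2014)
    seed: int = 0
    intercept: float = 1.0
    effect_unreported: float = 0.15  # per-1000 per percentage point
    effect_value: float = -0.8  # per-1000 per USD/kg
    noise_sd: float = 1.0  # residual SD of prevalence, per 1000
    ci_halfwidth_frac: float = 0.3  # 95% CI half-width as fraction of prevalence
    cluster_spec: tuple[ClusterArchetype, ...] = DEFAULT_ARCHETYPES
    trade_density: float = 0.3  # fraction of ordered country pairs with a flow
    cells_per_country: int = 30
    ports_per_country: int = 2
    year_cv: float = 0.15  # lognormal CV of year-to-year tonnage noise

    def validate(self) -> None:
        if self.n_countries < 3:
            raise ConfigurationError("n_countries must be >= 3")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError("years range is empty")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0 < self.trade_density <= 1):
            raise ConfigurationError("trade_density must be in (0, 1]")
        if self.ports_per_country < 1:
            raise ConfigurationError("ports_per_country must be >= 1")
        if self.cells_per_country < 1:
            raise ConfigurationError("cells_per_country must be >= 1")
        if not self.cluster_spec:
            raise ConfigurationError("cluster_spec must list at least one archetype")
        if self.ci_halfwidth_frac < 0:
            raise ConfigurationError("ci_halfwidth_frac must be >= 0")
        if self.year_cv < 0:
            raise ConfigurationError("year_cv must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _rng(config: SyntheticConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset])


def _country_codes(n: int) -> list[str]:
    # Synthetic ISO3-like codes S?? — never collide with real ISO3 names
    # used in exclusion lists.
    return ["S" + chr(65 + i // 26) + chr(65 + i % 26) for i in range(n)]


def _truncated_normal(rng, mean, sd, low):
    """Normal draw redrawn (simple clip) to stay above ``low``."""
    x = rng.normal(mean, sd)
    return max(x, low)


def country_profiles(config: SyntheticConfig) -> pd.DataFrame:
    """Per-country ground truth the generators realise.

    Returns one row per country: archetype assignment (round-robin over
    ``cluster_spec``), the six typology-variable targets drawn around the
    archetype means, the landed value per kg, and the mean annual total
    catch. Deterministic given the config; shared by all generators so the
    panel, spatial and slavery outputs are mutually consistent.
    """
    config.validate()
    rng = _rng(config, _STREAM_PROFILES)
    codes = _country_codes(config.n_countries)
    arch = config.cluster_spec
    rows = []
    for i, code in enumerate(codes):
        a = arch[i % len(arch)]

        def draw(mean, lo=1e-6, hi=None):
            v = _truncated_normal(rng, mean, a.rel_sd * mean, lo)
            return min(v, hi) if hi is not None else v

        rows.append(
            {
                "country": code,
                "cluster": a.name,
                "cluster_index": i % len(arch),
                "pct_unreported": draw(a.pct_unreported, 0.2, 95.0),
                "value_per_fisher": draw(a.value_per_fisher, 100.0),
                "pct_catch_outside_eez": draw(a.pct_catch_outside_eez, 0.0, 100.0),
                "gdp_per_capita_usd": draw(a.gdp_per_capita_usd, 500.0),
                "pct_subsidy": draw(a.pct_subsidy, 0.1, 95.0),
                "mean_distance_km": draw(a.mean_distance_km, 50.0),
                # unit value of the catch, USD/kg, independent of archetype
                "landed_value_per_kg": float(np.exp(rng.normal(np.log(1.2), 0.5))),
                # mean annual total landings, tonnes
                "mean_annual_catch_t": float(np.exp(rng.normal(np.log(5e5), 0.8))),
            }
        )
    return pd.DataFrame(rows).set_index("country")


def generate_country_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Country x year panel of industrial landings and static covariates.

    Yearly total landings vary lognormally (CV ``year_cv``) around each
    country's mean annual catch; the unreported share and unit value carry
    smaller year-to-year jitter. Fishers, harmful subsidies and GDP per
    capita are constant across years. Same seed, same output.
    """
    profiles = country_profiles(config)
    rng = _rng(config, _STREAM_PANEL)
    years = config.year_list
    n_y = len(years)
    sig = config.year_cv
    rows = []
    for code, p in profiles.iterrows():
        # lognormal multipliers with mean 1
        ly = np.exp(rng.normal(-sig**2 / 2.0, sig, n_y)) if sig > 0 else np.ones(n_y)
        lv = np.exp(rng.normal(-(sig / 3) ** 2 / 2.0, sig / 3, n_y)) if sig > 0 else np.ones(n_y)
        u_frac = p["pct_unreported"] / 100.0
        mean_value = p["mean_annual_catch_t"] * 1000.0 * p["landed_value_per_kg"]
        fishers = max(1.0, round(mean_value / p["value_per_fisher"]))
        subsidy = p["pct_subsidy"] / 100.0 * mean_value
        for j, year in enumerate(years):
            total = p["mean_annual_catch_t"] * ly[j]
            rows.append(
                {
                    "country": code,
                    "year": year,
                    "reported_t": total * (1.0 - u_frac),
                    "unreported_t": total * u_frac,
                    "landed_value_usd": total * 1000.0 * p["landed_value_per_kg"] * lv[j],
                    "fishers": fishers,
                    "harmful_subsidy_usd": subsidy,
                    "gdp_per_capita_usd": p["gdp_per_capita_usd"],
                }
            )
    return pd.DataFrame(rows)


def _destination(lat, lon, bearing_deg, distance_km):
    """Great-circle destination point from (lat, lon) along a bearing."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return np.degrees(phi2), (np.degrees(lam2) + 180.0) % 360.0 - 180.0


def snap_to_half_degree(lat, lon):
    """Snap coordinates to the nearest half-degree cell centre (x.25/x.75)."""
    lat_c = np.clip(np.floor(np.asarray(lat) * 2.0) / 2.0 + 0.25, -89.75, 89.75)
    lon = (np.asarray(lon) + 180.0) % 360.0 - 180.0
    lon_c = np.floor(lon * 2.0) / 2.0 + 0.25
    return lat_c, lon_c


def generate_spatial_catch(
    config: SyntheticConfig, panel: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Half-degree catch cells plus a domestic-port gazetteer.

    Each country's decade catch total (from the panel, regenerated if not
    supplied) is allocated across ``cells_per_country`` cells via a Dirichlet
    draw, so cell tonnage sums reproduce the panel totals exactly. Cells are
    placed at great-circle distances drawn around the country's target mean
    distance from a home anchor, then snapped to half-degree cell centres;
    EEZ attribution (own / foreign / high seas) is Bernoulli with the
    country's target outside-EEZ fraction.
    """
    profiles = country_profiles(config)
    if panel is None:
        panel = generate_country_panel(config)
    rng = _rng(config, _STREAM_SPATIAL)
    totals = (
        (panel["reported_t"] + panel["unreported_t"]).groupby(panel["country"]).sum()
    )
    codes = list(profiles.index)
    cell_rows, port_rows = [], []
    for code in codes:
        p = profiles.loc[code]
        anchor_lat = rng.uniform(-55.0, 55.0)
        anchor_lon = rng.uniform(-180.0, 180.0)
        port_rows.append({"country": code, "lat": anchor_lat, "lon": anchor_lon})
        for _ in range(config.ports_per_country - 1):
            port_rows.append(
                {
                    "country": code,
                    "lat": float(np.clip(anchor_lat + rng.uniform(-2, 2), -89.9, 89.9)),
                    "lon": (anchor_lon + rng.uniform(-2, 2) + 180.0) % 360.0 - 180.0,
                }
            )
        n_cells = config.cells_per_country
        weights = rng.dirichlet(np.ones(n_cells))
        tonnes = weights * totals[code]
        bearings = rng.uniform(0.0, 360.0, n_cells)
        dists = np.maximum(rng.normal(p["mean_distance_km"], 0.15 * p["mean_distance_km"], n_cells), 25.0)
        outside = rng.random(n_cells) < p["pct_catch_outside_eez"] / 100.0
        lat, lon = _destination(anchor_lat, anchor_lon, bearings, dists)
        lat, lon = snap_to_half_degree(lat, lon)
        for j in range(n_cells):
            if outside[j]:
                # split foreign-EEZ vs high-seas attribution evenly
                if rng.random() < 0.5:
                    owner = HIGH_SEAS
                else:
                    owner = codes[(codes.index(code) + 1 + int(rng.integers(len(codes) - 1))) % len(codes)]
                    if owner == code:
                        owner = HIGH_SEAS
            else:
                owner = code
            cell_rows.append(
                {
                    "lat": float(lat[j]),
                    "lon": float(lon[j]),
                    "fishing_country": code,
                    "eez_owner": owner,
                    "tonnes": float(tonnes[j]),
                }
            )
    return pd.DataFrame(cell_rows), pd.DataFrame(port_rows)


def generate_slavery_estimates(
    config: SyntheticConfig, metrics: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Prevalence estimates with a planted linear dependence on the metrics.

    ``metrics`` must provide ``pct_unreported`` and ``landed_value_per_kg``
    for every country (indexed by country). Returns the estimates table and
    a provenance dict recording the planted coefficients, for
    parameter-recovery tests and the sidecar JSON written by the pipeline.
    """
    config.validate()
    required = ("pct_unreported", "landed_value_per_kg")
    for col in required:
        if col not in metrics.columns:
            raise InputError(f"metrics table lacks required column {col!r}")
    missing = metrics.index[metrics[list(required)].isna().any(axis=1)].tolist()
    if missing:
        raise InputError(f"metrics missing for countries: {missing}")
    rng = _rng(config, _STREAM_SLAVERY)
    mu = (
        config.intercept
        + config.effect_unreported * metrics["pct_unreported"]
        + config.effect_value * metrics["landed_value_per_kg"]
    )
    noise = rng.normal(0.0, config.noise_sd, len(metrics)) if config.noise_sd > 0 else np.zeros(len(metrics))
    prev = np.maximum(mu.to_numpy() + noise, 0.0)
    half = config.ci_halfwidth_frac * prev + 1e-3  # strictly positive half-widths
    est = pd.DataFrame(
        {
            "country": metrics.index,
            "prevalence_per_1000": prev,
            "ci95_low": np.maximum(prev - half, 0.0),
            "ci95_high": prev + half,
        }
    ).set_index("country")
    provenance = {
        "model": "prevalence = intercept + b_unreported*pct_unreported + b_value*landed_value_per_kg + N(0, noise_sd), truncated at 0",
        "intercept": config.intercept,
        "effect_unreported": config.effect_unreported,
        "effect_value": config.effect_value,
        "noise_sd": config.noise_sd,
        "ci_halfwidth_frac": config.ci_halfwidth_frac,
        "seed": config.seed,
    }
    return est, provenance


def generate_trade_matrix(config: SyntheticConfig) -> pd.DataFrame:
    """Sparse bilateral exporter→importer tonnage matrix (HS6 class 03).

    Each ordered country pair carries a flow with probability
    ``trade_density``; tonnage is lognormal. One flow record per selected
    pair; no self-flows.
    """
    config.validate()
    rng = _rng(config, _STREAM_TRADE)
    codes = _country_codes(config.n_countries)
    rows = []
    for exp in codes:
        for imp in codes:
            if exp == imp:
                continue
            if rng.random() < config.trade_density:
                rows.append(
                    {
                        "exporter": exp,
                        "importer": imp,
                        "hs6": _HS6_POOL[int(rng.integers(len(_HS6_POOL)))],
                        "year": config.years[1],
                        "tonnes": float(np.exp(rng.normal(np.log(5e4), 1.0))),
                    }
                )
    cols = ["exporter", "importer", "hs6", "year", "tonnes"]
    return pd.DataFrame(rows, columns=cols)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
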