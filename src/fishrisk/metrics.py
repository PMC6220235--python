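"""Per-country fisheries and economic performance metrics.

Aggregates a country x year panel of industrial landings, spatially allocated
catch cells and a port gazetteer into the per-country measures used by the
regression and clustering stages:

* ``pct_unreported`` — unreported landings as a share of total landings (%),
  a proxy for weak monitoring and enforcement;
* ``landed_value_per_kg`` — ex-vessel value per kilogram landed (USD/kg),
  a unit-price / profitability proxy;
* ``value_per_fisher`` and ``tonnes_per_fisher`` — mean annual landed value
  (USD) and landings (t) per industrial fisher;
* ``pct_subsidy`` — harmful (capacity-enhancing) subsidies as a percentage of
  mean annual landed value;
* ``pct_catch_outside_eez`` — tonnage share of catch taken outside the
  country's own EEZ (high-seas catch counts as outside);
* ``mean_distance_km`` — catch-weighted mean great-circle distance between
  each catch cell's centroid and the closest domestic port.

Ratio metrics are computed from decade sums rather than means of annual
ratios, which keeps them stable when individual years are small; across-year
standard deviations of the annual ratios are returned alongside for the Monte
Carlo sensitivity stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedResultError

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0088

#: Sentinel EEZ owner for cells on the high seas.
HIGH_SEAS = "HIGH_SEAS"

#: The six variables entering the country typology (PCA + k-means).
CLUSTERING_VARIABLES = (
    "pct_unreported",
    "value_per_fisher",
    "pct_catch_outside_eez",
    "gdp_per_capita_usd",
    "pct_subsidy",
    "mean_distance_km",
)

#: Metrics with an annual series behind them, for which across-year
#: variability (sd_<name>) is reported.
ANNUAL_METRICS = (
    "pct_unreported",
    "landed_value_per_kg",
    "value_per_fisher",
    "tonnes_per_fisher",
    "pct_subsidy",
)


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise InputError("coordinates must be finite")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise InputError("latitude out of range [-90, 90]")
    if np.any(lon <= -180.0) or np.any(lon > 180.0):
        raise InputError("longitude out of range (-180, 180]")


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees.

    Uses the haversine formula on a sphere of radius :data:`EARTH_RADIUS_KM`.
    Symmetric, nonnegative, and bounded by half the Earth's circumference.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    _check_coords([lat1, lat2], [lon1, lon2])
    return float(_haversine(lat1, lon1, lat2, lon2))


def _haversine(lat1, lon1, lat2, lon2):
    # Vectorised core; inputs in degrees, any broadcastable shapes.
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards tiny negative/over-one values from roundoff at antipodes
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def nearest_port_distances(cells: pd.DataFrame, ports: pd.DataFrame) -> np.ndarray:
    """Distance (km) from each cell centroid to its closest port.

    ``cells`` needs ``lat``/``lon`` columns; ``ports`` likewise. Returns one
    distance per cell row.
    """
    if len(ports) == 0:
        raise InputError("no ports supplied")
    _check_coords(cells["lat"].to_numpy(), cells["lon"].to_numpy())
    _check_coords(ports["lat"].to_numpy(), ports["lon"].to_numpy())
    d = _haversine(
        cells["lat"].to_numpy()[:, None],
        cells["lon"].to_numpy()[:, None],
        ports["lat"].to_numpy()[None, :],
        ports["lon"].to_numpy()[None, :],
    )
    return d.min(axis=1)


def catch_weighted_mean_distance(cells: pd.DataFrame, ports: pd.DataFrame) -> float:
    """Catch-weighted mean distance from home for one country's catch.

    Each cell's distance is the great-circle distance from its centroid to
    the closest domestic port; the mean is weighted by the catch tonnage in
    each cell: ``sum_i w_i d_i / sum_i w_i``.
    """
    if len(cells) == 0:
        raise InputError("no catch cells supplied")
    if len(ports) == 0:
        raise InputError("no ports supplied")
    w = cells["tonnes"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise InputError("cell tonnage must be nonnegative")
    wtot = w.sum()
    if wtot <= 0:
        raise UndefinedResultError("total cell tonnage is zero; mean distance undefined")
    d = nearest_port_distances(cells, ports)
    return float(np.dot(w, d) / wtot)


def _spatial_metrics(country, cells, ports):
    """(% catch outside own EEZ, catch-weighted mean distance) for one country."""
    cc = cells[cells["fishing_country"] == country]
    pp = ports[ports["country"] == country]
    if len(cc) == 0 or len(pp) == 0 or cc["tonnes"].sum() <= 0:
        return np.nan, np.nan
    tonnes = cc["tonnes"].to_numpy(dtype=float)
    outside = cc["eez_owner"].to_numpy() != country  # high seas counts as outside
    pct_outside = 100.0 * tonnes[outside].sum() / tonnes.sum()
    return pct_outside, catch_weighted_mean_distance(cc, pp)


def compute_country_metrics(
    panel: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    ports: pd.DataFrame | None = None,
    period: tuple[int, int] = (2005, 2014),
    variability: str = "sd",
) -> pd.DataFrame:
    """Aggregate the panel (and optional spatial data) to per-country metrics.

    Parameters
    ----------
    panel
        Country x year records with columns ``country, year, reported_t,
        unreported_t, landed_value_usd, fishers, harmful_subsidy_usd,
        gdp_per_capita_usd`` (the last three constant within country).
    cells, ports
        Spatially allocated catch and the port gazetteer. If either is
        missing for a country, its ``pct_catch_outside_eez`` and
        ``mean_distance_km`` are NaN (flagged missing).
    period
        Inclusive year range aggregated over (default the 2005–2014 decade).
    variability
        ``"sd"`` (default) or ``"se"`` — whether the across-year spread of
        the annual ratio metrics is reported as a standard deviation or a
        standard error of the mean.

    Returns
    -------
    DataFrame indexed by country with the metric columns, plus one
    ``sd_<metric>`` column per annual metric. Countries with zero total catch
    over the period are dropped with a warning.
    """
    if variability not in ("sd", "se"):
        raise InputError(f"variability must be 'sd' or 'se', got {variability!r}")
    y0, y1 = period
    if y1 < y0:
        raise InputError("empty aggregation period")
    sub = panel[(panel["year"] >= y0) & (panel["year"] <= y1)].copy()
    if len(sub) == 0:
        raise InputError("no panel rows fall inside the aggregation period")

    if (sub["fishers"] <= 0).any() or sub["fishers"].isna().any():
        bad = sorted(sub.loc[(sub["fishers"] <= 0) | sub["fishers"].isna(), "country"].unique())
        raise InputError(f"nonpositive or missing fisher counts for: {bad}")

    sub["total_t"] = sub["reported_t"] + sub["unreported_t"]
    rows = []
    for country, g in sub.groupby("country", sort=True):
        tot = g["total_t"].sum()
        if tot <= 0:
            logger.warning("country %s has zero total catch in %s–%s; excluded", country, y0, y1)
            continue
        n_years = len(g)
        fishers = float(g["fishers"].iloc[0])
        mean_annual_value = g["landed_value_usd"].mean()
        subsidy = float(g["harmful_subsidy_usd"].iloc[0])

        # Annual ratio series, for variability estimates only.
        ann = pd.DataFrame(
            {
                "pct_unreported": 100.0 * g["unreported_t"] / g["total_t"],
                "landed_value_per_kg": g["landed_value_usd"] / (1000.0 * g["total_t"]),
                "value_per_fisher": g["landed_value_usd"] / fishers,
                "tonnes_per_fisher": g["total_t"] / fishers,
                "pct_subsidy": 100.0 * subsidy / g["landed_value_usd"],
            }
        )
        spread = ann.std(ddof=1)
        if variability == "se":
            spread = spread / np.sqrt(n_years)

        row = {
            "country": country,
            "pct_unreported": 100.0 * g["unreported_t"].sum() / tot,
            "landed_value_per_kg": g["landed_value_usd"].sum() / (1000.0 * tot),
            "value_per_fisher": mean_annual_value / fishers,
            "tonnes_per_fisher": (tot / n_years) / fishers,
            "pct_subsidy": 100.0 * subsidy / mean_annual_value,
            "gdp_per_capita_usd": float(g["gdp_per_capita_usd"].iloc[0]),
        }
        if cells is not None and ports is not None:
            pct_out, dist = _spatial_metrics(country, cells, ports)
        else:
            pct_out, dist = np.nan, np.nan
        row["pct_catch_outside_eez"] = pct_out
        row["mean_distance_km"] = dist
        for m in ANNUAL_METRICS:
            row[f"sd_{m}"] = float(spread[m]) if n_years > 1 else 0.0
        rows.append(row)

    if not rows:
        raise InputError("every country had zero total catch over the period")
    out = pd.DataFrame(rows).set_index("country")
    return out
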