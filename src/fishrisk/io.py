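"""CSV readers/writers for the pipeline's table dialects.

All tables are UTF-8, comma-separated with a header row. Validation is
collective: every problem found (unknown columns, negative tonnage, CI
inversions, out-of-range coordinates) is gathered into a single
:class:`~fishrisk.errors.ValidationError` listing row numbers, so one pass
surfaces everything.

Dialects (columns, units):

========== ==================================================================
panel      country, year, reported_t, unreported_t, landed_value_usd,
           fishers, harmful_subsidy_usd, gdp_per_capita_usd
cells      lat, lon, fishing_country, eez_owner, tonnes
           (eez_owner may be the sentinel ``HIGH_SEAS``)
ports      country, lat, lon
slavery    country, prevalence, ci95_low, ci95_high, unit
           (unit per row: ``per_1000`` or ``per_10000``; values are
           normalised to per-1000 on ingest and the frame is flagged via
           ``df.attrs['normalised_from_per_10000']``)
trade      exporter, importer, hs6, year, tonnes
========== ==================================================================
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError

PANEL_COLUMNS = [
    "country", "year", "reported_t", "unreported_t", "landed_value_usd",
    "fishers", "harmful_subsidy_usd", "gdp_per_capita_usd",
]
CELL_COLUMNS = ["lat", "lon", "fishing_country", "eez_owner", "tonnes"]
PORT_COLUMNS = ["country", "lat", "lon"]
SLAVERY_COLUMNS = ["country", "prevalence", "ci95_low", "ci95_high", "unit"]
TRADE_COLUMNS = ["exporter", "importer", "hs6", "year", "tonnes"]


def _read(path, expected_cols) -> pd.DataFrame:
    path = Path(path)
    issues = []
    try:
        df = pd.read_csv(path, dtype={"hs6": str} if "hs6" in expected_cols else None)
    except pd.errors.EmptyDataError:
        raise ValidationError([f"{path}: file is empty"])
    unknown = [c for c in df.columns if c not in expected_cols]
    missing = [c for c in expected_cols if c not in df.columns]
    if unknown:
        issues.append(f"{path}: unknown columns {unknown}")
    if missing:
        issues.append(f"{path}: missing columns {missing}")
    if issues:
        raise ValidationError(issues)
    if len(df) == 0:
        raise ValidationError([f"{path}: no data rows"])
    return df[expected_cols]


def _check(df, mask, message, issues):
    for idx in df.index[mask]:
        issues.append(f"row {idx + 2}: {message}")  # +2: header + 1-based


def read_country_panel(path) -> pd.DataFrame:
    df = _read(path, PANEL_COLUMNS)
    issues: list[str] = []
    _check(df, df["reported_t"] < 0, "negative reported tonnage", issues)
    _check(df, df["unreported_t"] < 0, "negative unreported tonnage", issues)
    _check(df, df["landed_value_usd"] < 0, "negative landed value", issues)
    _check(df, df["fishers"] <= 0, "nonpositive fisher count", issues)
    _check(df, df["gdp_per_capita_usd"] <= 0, "nonpositive GDP per capita", issues)
    if issues:
        raise ValidationError(issues)
    return df


def read_spatial_cells(path) -> pd.DataFrame:
    df = _read(path, CELL_COLUMNS)
    issues: list[str] = []
    _check(df, (df["lat"] < -90) | (df["lat"] > 90), "latitude out of range", issues)
    _check(df, (df["lon"] <= -180) | (df["lon"] > 180), "longitude out of range", issues)
    _check(df, df["tonnes"] < 0, "negative cell tonnage", issues)
    if issues:
        raise ValidationError(issues)
    return df


def read_ports(path) -> pd.DataFrame:
    df = _read(path, PORT_COLUMNS)
    issues: list[str] = []
    _check(df, (df["lat"] < -90) | (df["lat"] > 90), "latitude out of range", issues)
    _check(df, (df["lon"] <= -180) | (df["lon"] > 180), "longitude out of range", issues)
    if issues:
        raise ValidationError(issues)
    return df


def read_slavery_estimates(path) -> pd.DataFrame:
    """Read prevalence estimates, normalising any per-10,000 rows to per-1000."""
    df = _read(path, SLAVERY_COLUMNS)
    issues: list[str] = []
    bad_unit = ~df["unit"].isin(["per_1000", "per_10000"])
    _check(df, bad_unit, "unknown prevalence unit", issues)
    _check(df, df["prevalence"] < 0, "negative prevalence", issues)
    _check(df, df["ci95_low"] > df["prevalence"], "CI lower bound above estimate", issues)
    _check(df, df["ci95_high"] < df["prevalence"], "CI upper bound below estimate", issues)
    _check(df, df["ci95_low"] < 0, "negative CI lower bound", issues)
    if issues:
        raise ValidationError(issues)
    scale = df["unit"].map({"per_1000": 1.0, "per_10000": 0.1})
    out = pd.DataFrame(
        {
            "country": df["country"],
            "prevalence_per_1000": df["prevalence"] * scale,
            "ci95_low": df["ci95_low"] * scale,
            "ci95_high": df["ci95_high"] * scale,
        }
    ).set_index("country")
    out.attrs["normalised_from_per_10000"] = sorted(
        df.loc[df["unit"] == "per_10000", "country"].tolist()
    )
    return out


def read_trade_flows(path) -> pd.DataFrame:
    df = _read(path, TRADE_COLUMNS)
    issues: list[str] = []
    _check(df, df["tonnes"] <= 0, "nonpositive flow tonnage", issues)
    _check(df, df["exporter"] == df["importer"], "self-flow (exporter == importer)", issues)
    if issues:
        raise ValidationError(issues)
    return df


def write_country_panel(df: pd.DataFrame, path) -> None:
    df[PANEL_COLUMNS].to_csv(path, index=False)


def write_spatial_cells(df: pd.DataFrame, path) -> None:
    df[CELL_COLUMNS].to_csv(path, index=False)


def write_ports(df: pd.DataFrame, path) -> None:
    df[PORT_COLUMNS].to_csv(path, index=False)


def write_slavery_estimates(df: pd.DataFrame, path) -> None:
    """Write estimates (indexed by country, per-1000 columns) in the dialect."""
    out = pd.DataFrame(
        {
            "country": df.index,
            "prevalence": df["prevalence_per_1000"].to_numpy(),
            "ci95_low": df["ci95_low"].to_numpy(),
            "ci95_high": df["ci95_high"].to_numpy(),
            "unit": "per_1000",
        }
    )
    out.to_csv(path, index=False)


def write_trade_flows(df: pd.DataFrame, path) -> None:
    df[TRADE_COLUMNS].to_csv(path, index=False)
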