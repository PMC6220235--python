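"""Prevalence-weighted slavery-risk propagation over bilateral seafood trade.

A country's slavery prevalence of v victims per 1000 population, applied
uniformly to every sector touching its seafood, converts directly to a risk
of v kilograms of slavery-associated seafood per tonne (1000 kg) produced or
re-exported. The model then propagates these national risks through a
bilateral trade matrix:

* the risk of a region's **imports** is the tonnage-weighted mean of the
  national risks of its external suppliers (trade among bloc members counts
  as domestic supply, not imports);
* the risk of its **domestic supply** is the mean of the import risk and the
  domestic-production risk, weighted by import tonnage and by domestic
  production net of exports.

The model deliberately assumes re-export neutrality: all seafood exported by
a country — caught domestically or processed from imports — carries that
country's national risk, because origin information is not preserved in
commodity trade data.

Risks are carried unrounded throughout; multipliers (import vs domestic,
supply vs domestic) are computed on unrounded values and a separate display
helper rounds to one decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import InputError, UndefinedResultError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionDefinition:
    """A single country or a bloc of countries treated as one market.

    ``domestic_production_t`` and ``exports_t`` are annual tonnages;
    ``exports_t`` must already exclude intra-bloc trade (bloc-internal flows
    are domestic supply, not exports).
    """

    name: str
    members: tuple[str, ...]
    domestic_production_t: float = 0.0
    exports_t: float = 0.0

    def __post_init__(self):
        if not self.members:
            raise InputError("region must have at least one member")
        if self.domestic_production_t < 0 or self.exports_t < 0:
            raise InputError("tonnages must be nonnegative")


@dataclass(frozen=True)
class SupplyRiskResult:
    """Risk of a region's imports, domestic production and mixed supply."""

    region: str
    domestic_risk_kg_per_t: float
    import_risk_kg_per_t: float
    supply_risk_kg_per_t: float
    import_vs_domestic_ratio: float | None  # None when domestic risk is 0
    supply_vs_domestic_ratio: float | None
    import_t: float
    domestic_net_t: float

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "domestic_risk_kg_per_t": self.domestic_risk_kg_per_t,
            "import_risk_kg_per_t": self.import_risk_kg_per_t,
            "supply_risk_kg_per_t": self.supply_risk_kg_per_t,
            "import_vs_domestic_ratio": self.import_vs_domestic_ratio,
            "supply_vs_domestic_ratio": self.supply_vs_domestic_ratio,
            "import_t": self.import_t,
            "domestic_net_t": self.domestic_net_t,
        }


def prevalence_to_risk(prevalence: float, unit: str = "per_1000") -> float:
    """Convert a national slavery prevalence into kg of at-risk seafood per tonne.

    A prevalence of v per 1000 people, applied to all sectors, marks the
    fraction v/1000 of each tonne — i.e. v kilograms per tonne. ``unit`` is
    ``"per_1000"`` or ``"per_10000"``; no rounding is applied (see
    :func:`display_risk`).
    """
    if prevalence < 0:
        raise InputError("prevalence must be nonnegative")
    if unit == "per_1000":
        return float(prevalence)
    if unit == "per_10000":
        return float(prevalence) / 10.0
    raise InputError(f"unknown prevalence unit {unit!r}")


def display_risk(risk_kg_per_t: float) -> float:
    """Round a risk to one decimal for display; internal values stay unrounded."""
    return round(float(risk_kg_per_t), 1)


def average_flows(
    flows: pd.DataFrame,
    years: tuple[int, int] | None = None,
    hs6_prefix: str = "03",
) -> pd.DataFrame:
    """Filter to the commodity scope and average per-year bilateral flows.

    Keeps HS6 codes with the given prefix (class 03 = fish and seafood
    products); if ``years`` is given, flows are restricted to the inclusive
    window and each exporter→importer total is divided by the window length
    (mean annual flow). Returns columns exporter, importer, tonnes.
    """
    f = flows
    if "hs6" in f.columns and hs6_prefix:
        f = f[f["hs6"].astype(str).str.startswith(hs6_prefix)]
    if years is not None and "year" in f.columns:
        y0, y1 = years
        f = f[(f["year"] >= y0) & (f["year"] <= y1)]
        denom = y1 - y0 + 1
    else:
        denom = 1
    agg = (
        f.groupby(["exporter", "importer"], as_index=False)["tonnes"].sum()
    )
    agg["tonnes"] = agg["tonnes"] / denom
    return agg


def import_risk(
    flows: pd.DataFrame,
    risks: pd.Series | dict,
    region: RegionDefinition,
) -> tuple[float, pd.DataFrame]:
    """Tonnage-weighted mean risk of a region's external seafood imports.

    Only flows from non-members into members count; intra-bloc flows are
    folded into domestic supply. Returns the risk (kg/t) and a per-source
    breakdown (tonnes, risk, tonnage share), sorted by descending tonnage.
    """
    risks = pd.Series(risks, dtype=float)
    members = set(region.members)
    ext = flows[
        flows["importer"].isin(members) & ~flows["exporter"].isin(members)
    ]
    if len(ext) == 0 or ext["tonnes"].sum() <= 0:
        raise UndefinedResultError(
            f"region {region.name!r} has no external imports; import risk undefined"
        )
    if (ext["tonnes"] <= 0).any():
        raise InputError("trade flows must have strictly positive tonnage")
    by_src = ext.groupby("exporter")["tonnes"].sum()
    missing = sorted(set(by_src.index) - set(risks.index))
    if missing:
        raise InputError(f"no risk score for exporters: {missing}")
    src_risk = risks.loc[by_src.index]
    total = by_src.sum()
    value = float((by_src * src_risk).sum() / total)
    breakdown = (
        pd.DataFrame(
            {
                "source": by_src.index,
                "tonnes": by_src.to_numpy(float),
                "risk_kg_per_t": src_risk.to_numpy(float),
            }
        )
        .assign(share=lambda d: d["tonnes"] / total)
        .sort_values("tonnes", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return value, breakdown


def supply_risk(
    region: RegionDefinition,
    import_risk_kg_per_t: float,
    import_t: float,
    domestic_risk_kg_per_t: float,
) -> SupplyRiskResult:
    """Mix import and domestic risks into the region's supply risk.

    supply = (import_risk * import_t + domestic_risk * domestic_net)
             / (import_t + domestic_net),
    with domestic_net = max(production - exports, 0). Ratios use unrounded
    values; when domestic risk is zero they are reported as undefined
    (None), never infinite.
    """
    if import_t < 0:
        raise InputError("import tonnage must be nonnegative")
    if import_risk_kg_per_t < 0 or domestic_risk_kg_per_t < 0:
        raise InputError("risks must be nonnegative")
    domestic_net = region.domestic_production_t - region.exports_t
    if domestic_net < 0:
        logger.warning(
            "region %s exports exceed production (net %.1f t); flooring at 0",
            region.name,
            domestic_net,
        )
        domestic_net = 0.0
    denom = import_t + domestic_net
    if denom <= 0:
        raise UndefinedResultError(
            "both import tonnage and net domestic production are zero"
        )
    supply = (import_risk_kg_per_t * import_t + domestic_risk_kg_per_t * domestic_net) / denom
    if domestic_risk_kg_per_t > 0:
        ratio_imp = import_risk_kg_per_t / domestic_risk_kg_per_t
        ratio_sup = supply / domestic_risk_kg_per_t
    else:
        ratio_imp = ratio_sup = None
    return SupplyRiskResult(
        region=region.name,
        domestic_risk_kg_per_t=float(domestic_risk_kg_per_t),
        import_risk_kg_per_t=float(import_risk_kg_per_t),
        supply_risk_kg_per_t=float(supply),
        import_vs_domestic_ratio=ratio_imp,
        supply_vs_domestic_ratio=ratio_sup,
        import_t=float(import_t),
        domestic_net_t=float(domestic_net),
    )


def assess_region(
    flows: pd.DataFrame,
    risks: pd.Series | dict,
    region: RegionDefinition,
    domestic_risk_kg_per_t: float,
) -> SupplyRiskResult:
    """Convenience wrapper: import risk + supply mixing in one call."""
    imp_risk, breakdown = import_risk(flows, risks, region)
    return supply_risk(region, imp_risk, float(breakdown["tonnes"].sum()), domestic_risk_kg_per_t)


def build_sankey(
    flows: pd.DataFrame,
    risks: pd.Series | dict,
    region: RegionDefinition,
    domestic_risk_kg_per_t: float,
    top_n: int | None = None,
) -> dict:
    """River-plot structure for a region's seafood supply.

    Nodes: each external source country (optionally the top ``top_n`` by
    tonnage plus an aggregated "other" node), the region's domestic
    production, and the region's supply node. Link width is tonnes, and each
    link carries the source's risk intensity (kg/t). Tonnage is conserved:
    links into the supply node sum to import_t + domestic_net.
    """
    imp_risk, breakdown = import_risk(flows, risks, region)
    import_t = float(breakdown["tonnes"].sum())
    if top_n is not None and len(breakdown) > top_n:
        head = breakdown.iloc[:top_n]
        tail = breakdown.iloc[top_n:]
        tail_t = float(tail["tonnes"].sum())
        tail_risk = float((tail["tonnes"] * tail["risk_kg_per_t"]).sum() / tail_t)
        head = pd.concat(
            [
                head,
                pd.DataFrame(
                    [{"source": "other", "tonnes": tail_t, "risk_kg_per_t": tail_risk,
                      "share": tail_t / import_t}]
                ),
            ],
            ignore_index=True,
        )
        breakdown = head
    supply_node = f"{region.name} supply"
    domestic_node = f"{region.name} domestic production"
    res = supply_risk(region, imp_risk, import_t, domestic_risk_kg_per_t)
    nodes = [
        {"id": str(s), "kind": "source"} for s in breakdown["source"]
    ] + [
        {"id": domestic_node, "kind": "domestic"},
        {"id": supply_node, "kind": "supply", "risk_kg_per_t": res.supply_risk_kg_per_t},
    ]
    links = [
        {
            "source": str(r["source"]),
            "target": supply_node,
            "tonnes": float(r["tonnes"]),
            "risk_kg_per_t": float(r["risk_kg_per_t"]),
        }
        for _, r in breakdown.iterrows()
    ]
    if res.domestic_net_t > 0:
        links.append(
            {
                "source": domestic_node,
                "target": supply_node,
                "tonnes": res.domestic_net_t,
                "risk_kg_per_t": float(domestic_risk_kg_per_t),
            }
        )
    return {"nodes": nodes, "links": links, "import_risk_kg_per_t": imp_risk,
            "supply_risk_kg_per_t": res.supply_risk_kg_per_t}


def region_trade_summary(flows: pd.DataFrame, region: RegionDefinition) -> dict:
    """External imports/exports and intra-bloc tonnage for a region."""
    members = set(region.members)
    imp = flows[flows["importer"].isin(members) & ~flows["exporter"].isin(members)]
    exp = flows[flows["exporter"].isin(members) & ~flows["importer"].isin(members)]
    intra = flows[flows["exporter"].isin(members) & flows["importer"].isin(members)]
    return {
        "import_t": float(imp["tonnes"].sum()),
        "export_t": float(exp["tonnes"].sum()),
        "intra_bloc_t": float(intra["tonnes"].sum()),
    }
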