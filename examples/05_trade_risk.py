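"""Propagate national slavery risks through seafood trade into one market.

A national prevalence of v victims per 1000 people converts to v kg of
at-risk seafood per tonne produced. The import risk of a market is the
tonnage-weighted mean of its suppliers' risks; the supply risk mixes imports
with domestic production net of exports.
"""

import pandas as pd

import fishrisk as fr

# Worked conversion: a prevalence of 1.8 victims per 10,000 people
domestic_risk = fr.prevalence_to_risk(1.8, unit="per_10000")
print(f"prevalence 1.8/10,000 -> domestic risk {domestic_risk:.2f} kg/t "
      f"(displayed as {fr.display_risk(domestic_risk)})")

# A market importing from three suppliers with higher national risks
flows = pd.DataFrame(
    {
        "exporter": ["THA", "VNM", "CHN", "MKT"],
        "importer": ["MKT", "MKT", "MKT", "THA"],
        "tonnes": [400.0, 250.0, 350.0, 100.0],
    }
)
risks = {"THA": 4.2, "VNM": 3.1, "CHN": 2.2, "MKT": domestic_risk}
region = fr.RegionDefinition(
    "MKT", ("MKT",), domestic_production_t=1200.0, exports_t=100.0
)

imp_risk, breakdown = fr.import_risk(flows, risks, region)
print(f"\nimport risk = {imp_risk:.2f} kg/t (tonnage-weighted mean of suppliers)")
print(breakdown.round(3).to_string(index=False))

res = fr.supply_risk(region, imp_risk, float(breakdown["tonnes"].sum()), domestic_risk)
print(f"\nsupply risk = {res.supply_risk_kg_per_t:.2f} kg/t over "
      f"{res.import_t:.0f} t imported + {res.domestic_net_t:.0f} t domestic (net)")
print(f"imported seafood carries {res.import_vs_domestic_ratio:.0f}x the domestic risk;")
print(f"the import mix raises the whole supply's risk {res.supply_vs_domestic_ratio:.1f}x.")

sankey = fr.build_sankey(flows, risks, region, domestic_risk, top_n=10)
print(f"\nSankey export: {len(sankey['nodes'])} nodes, {len(sankey['links'])} links "
      "(link width = tonnes, colour = source risk)")
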