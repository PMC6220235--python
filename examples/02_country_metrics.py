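"""Compute per-country fisheries performance metrics over a decade.

Shows the decade-aggregated metrics for the 20-country default world,
including the catch-weighted mean distance from home (nearest-domestic-port
great-circle distance, weighted by cell tonnage).
"""

import fishrisk as fr

cfg = fr.SyntheticConfig(seed=42)
panel = fr.generate_country_panel(cfg)
cells, ports = fr.generate_spatial_catch(cfg, panel)
metrics = fr.compute_country_metrics(panel, cells, ports, period=(2005, 2014))

cols = [
    "pct_unreported", "landed_value_per_kg", "value_per_fisher",
    "pct_catch_outside_eez", "pct_subsidy", "mean_distance_km",
]
print(metrics[cols].head(6).round(2))
print("\nEach row is one fishing country, aggregated 2005-2014:")
print("  pct_unreported        unreported share of total landings (%)")
print("  landed_value_per_kg   ex-vessel value of the catch (USD/kg)")
print("  pct_catch_outside_eez tonnage share caught outside the own EEZ (%)")
print("  mean_distance_km      catch-weighted distance to the closest home port")

# a single great-circle distance, for orientation
d = fr.haversine_km((0.25, 10.25), (0.25, 11.25))
print(f"\nhaversine check: one degree of longitude at the equator = {d:.1f} km")
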