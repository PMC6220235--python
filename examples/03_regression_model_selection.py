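"""Select the best prevalence model by AICc and probe it with Monte Carlo.

Fits every non-empty subset of three candidate fisheries predictors to the
per-country slavery prevalence, ranks the models by small-sample-corrected
AIC, and then propagates input uncertainty (across-year SDs of the metrics,
95% CIs of the prevalence estimates) into a distribution of R² values.
"""

import fishrisk as fr

cfg = fr.SyntheticConfig(seed=42)
panel = fr.generate_country_panel(cfg)
cells, ports = fr.generate_spatial_catch(cfg, panel)
metrics = fr.compute_country_metrics(panel, cells, ports)
slavery, _ = fr.generate_slavery_estimates(cfg, metrics)

best, ranking = fr.select_model(
    metrics, slavery,
    candidates=("pct_unreported", "landed_value_per_kg", "tonnes_per_fisher"),
)
print("model ranking (lower AICc is better):")
print(ranking.round(3).to_string(index=False))
print(f"\nbest model: prevalence ~ {' + '.join(best.predictors)}")
print(f"R² = {best.r2:.3f}, F-test p = {best.f_pvalue:.2e}, n = {best.n}")

mc = fr.monte_carlo_sensitivity(
    metrics, slavery, best.predictors, n_runs=10_000, scenario="all", seed=1
)
print(f"\nMonte Carlo (10,000 runs, all inputs perturbed): median R² = {mc.median_r2:.3f}")
print("The median R² under perturbation sits below the point estimate:")
print("measurement uncertainty in the inputs attenuates the apparent fit.")
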