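"""Pipeline orchestration: synth → metrics → regression → clustering → trade.

Runs the stages behind one configuration object, writes every stage's
CSV/JSON artifacts into an output directory, and records a reproducibility
manifest (config hash, seeds, package version, per-stage row counts and
status). All randomness flows from config seeds — no wall-clock seeding —
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, io, metrics, regression, synthetic, trade
from .errors import ConfigurationError, FishriskError

logger = logging.getLogger(__name__)

STAGES = ("synth", "metrics", "regress", "cluster", "trade")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synthetic`` (generate the inputs) or ``inputs`` (paths
    to CSV tables: keys panel, cells, ports, slavery, trade) must be set.
    An empty ``regions`` tuple skips the trade stage; ``mc_runs = 0`` skips
    the Monte Carlo sensitivity analysis.
    """

    synthetic: synthetic.SyntheticConfig | None = None
    inputs: dict | None = None
    period: tuple[int, int] = (2005, 2014)
    candidates: tuple[str, ...] = (
        "pct_unreported", "landed_value_per_kg", "tonnes_per_fisher",
    )
    exclusions: tuple[str, ...] = regression.DEFAULT_EXCLUSIONS
    mc_runs: int = 10_000
    mc_scenarios: tuple[str, ...] = ("all", "fisheries_only", "slavery_only")
    mc_seed: int = 0
    cluster_variables: tuple[str, ...] = metrics.CLUSTERING_VARIABLES
    k_range: tuple[int, int] = (2, 6)
    cluster_seed: int = 0
    n_restarts: int = 50
    regions: tuple[dict, ...] = ()
    trade_years: tuple[int, int] | None = None
    hs6_prefix: str = "03"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' and 'inputs' must be configured"
            )
        if self.synthetic is not None:
            self.synthetic.validate()
        if self.inputs is not None:
            missing = {"panel", "slavery"} - set(self.inputs)
            if missing:
                raise ConfigurationError(f"inputs block missing required keys: {sorted(missing)}")
        if self.mc_runs < 0:
            raise ConfigurationError("mc_runs must be >= 0")
        for s in self.mc_scenarios:
            if s not in ("all", "fisheries_only", "slavery_only"):
                raise ConfigurationError(f"unknown Monte Carlo scenario {s!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if "years" in syn:
                syn["years"] = tuple(syn["years"])
            if "cluster_spec" in syn:
                syn["cluster_spec"] = tuple(
                    synthetic.ClusterArchetype(**a) for a in syn["cluster_spec"]
                )
            d["synthetic"] = synthetic.SyntheticConfig(**syn)
        for key in ("period", "candidates", "exclusions", "mc_scenarios",
                    "cluster_variables", "k_range", "trade_years"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("regions") is not None:
            d["regions"] = tuple(dict(r) for r in d["regions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_inputs(config: PipelineConfig, outdir: Path) -> dict:
    """Read the five tables from configured paths or from a prior synth stage."""
    if config.inputs is not None:
        paths = config.inputs
    else:
        paths = {
            "panel": outdir / "panel.csv",
            "cells": outdir / "cells.csv",
            "ports": outdir / "ports.csv",
            "slavery": outdir / "slavery.csv",
            "trade": outdir / "trade.csv",
        }
    data = {
        "panel": io.read_country_panel(paths["panel"]),
        "slavery": io.read_slavery_estimates(paths["slavery"]),
    }
    for key, reader in (("cells", io.read_spatial_cells), ("ports", io.read_ports),
                        ("trade", io.read_trade_flows)):
        p = paths.get(key)
        data[key] = reader(p) if p is not None and Path(p).exists() else None
    return data


def _stage_synth(config, outdir, manifest):
    syn = config.synthetic
    panel = synthetic.generate_country_panel(syn)
    cells, ports = synthetic.generate_spatial_catch(syn, panel)
    m = metrics.compute_country_metrics(panel, cells, ports, period=config.period)
    slavery, provenance = synthetic.generate_slavery_estimates(syn, m)
    flows = synthetic.generate_trade_matrix(syn)
    io.write_country_panel(panel, outdir / "panel.csv")
    io.write_spatial_cells(cells, outdir / "cells.csv")
    io.write_ports(ports, outdir / "ports.csv")
    io.write_slavery_estimates(slavery, outdir / "slavery.csv")
    io.write_trade_flows(flows, outdir / "trade.csv")
    _write_json(provenance, outdir / "provenance.json")
    manifest["stages"]["synth"] = {
        "status": "ok",
        "rows": {
            "panel": len(panel), "cells": len(cells), "ports": len(ports),
            "slavery": len(slavery), "trade": len(flows),
        },
        "artifacts": ["panel.csv", "cells.csv", "ports.csv", "slavery.csv",
                      "trade.csv", "provenance.json"],
    }


def _stage_metrics(config, data, outdir, manifest):
    m = metrics.compute_country_metrics(
        data["panel"], data["cells"], data["ports"], period=config.period
    )
    m.to_csv(outdir / "metrics.csv")
    manifest["stages"]["metrics"] = {
        "status": "ok", "rows": {"metrics": len(m)}, "artifacts": ["metrics.csv"],
    }
    return m


def _stage_regress(config, m, slavery, outdir, manifest):
    best, ranking = regression.select_model(
        m, slavery, candidates=config.candidates, exclusions=config.exclusions
    )
    ranking.to_csv(outdir / "model_ranking.csv", index=False)
    _write_json(
        {
            "predictors": list(best.predictors),
            "coefficients": best.coefficients,
            "r2": best.r2,
            "f_pvalue": best.f_pvalue,
            "aicc": best.aicc,
            "n": best.n,
        },
        outdir / "best_model.json",
    )
    fv = regression.fitted_vs_observed(best, m, slavery, exclusions=config.exclusions)
    fv.to_csv(outdir / "fitted_vs_observed.csv")
    artifacts = ["model_ranking.csv", "best_model.json", "fitted_vs_observed.csv"]
    mc_medians = {}
    if config.mc_runs > 0:
        for scenario in config.mc_scenarios:
            mc = regression.monte_carlo_sensitivity(
                m, slavery, best.predictors, n_runs=config.mc_runs,
                scenario=scenario, seed=config.mc_seed, exclusions=config.exclusions,
            )
            pd.DataFrame({"r2": mc.r2}).to_csv(outdir / f"mc_{scenario}.csv", index=False)
            counts, edges = np.histogram(mc.r2, bins=20, range=(0.0, 1.0))
            _write_json(
                {
                    "scenario": scenario,
                    "median_r2": mc.median_r2,
                    "n_runs": mc.n_runs,
                    "n_skipped": mc.n_skipped,
                    "bin_edges": edges.tolist(),
                    "counts": counts.tolist(),
                },
                outdir / f"mc_{scenario}_hist.json",
            )
            artifacts += [f"mc_{scenario}.csv", f"mc_{scenario}_hist.json"]
            mc_medians[scenario] = mc.median_r2
    manifest["stages"]["regress"] = {
        "status": "ok",
        "rows": {"ranking": len(ranking)},
        "best_predictors": list(best.predictors),
        "r2": best.r2,
        "mc_median_r2": mc_medians,
        "artifacts": artifacts,
    }
    return best


def _stage_cluster(config, m, outdir, manifest):
    z = clustering.standardize(m[list(config.cluster_variables)])
    pc = clustering.pca(z)
    scores2 = pc.scores[["PC1", "PC2"]]
    k, diag = clustering.choose_k(
        scores2, k_range=config.k_range, seed=config.cluster_seed,
        n_restarts=config.n_restarts,
    )
    assign = clustering.kmeans_cluster(
        scores2, k, seed=config.cluster_seed, n_restarts=config.n_restarts
    )
    pc.loadings.to_csv(outdir / "loadings.csv")
    pc.scores.to_csv(outdir / "scores.csv")
    pd.DataFrame(
        {
            "component": pc.loadings.columns,
            "explained_fraction": pc.explained_fraction,
            "eigenvalue": pc.eigenvalues,
        }
    ).to_csv(outdir / "explained_variance.csv", index=False)
    diag.to_csv(outdir / "k_diagnostics.csv", index=False)
    assign.labels.to_frame().to_csv(outdir / "clusters.csv")
    _write_json(clustering.biplot_data(pc, assign), outdir / "biplot.json")
    manifest["stages"]["cluster"] = {
        "status": "ok",
        "rows": {"countries": len(assign.labels)},
        "k": k,
        "artifacts": ["loadings.csv", "scores.csv", "explained_variance.csv",
                      "k_diagnostics.csv", "clusters.csv", "biplot.json"],
    }
    return assign


def _stage_trade(config, data, outdir, manifest):
    flows = trade.average_flows(
        data["trade"], years=config.trade_years, hs6_prefix=config.hs6_prefix
    )
    risks = data["slavery"]["prevalence_per_1000"]  # per-1000 == kg/t
    panel = data["panel"]
    panel_period = panel[(panel["year"] >= config.period[0]) & (panel["year"] <= config.period[1])]
    n_years = panel_period["year"].nunique()
    artifacts, results = [], {}
    for rdict in config.regions:
        members = tuple(rdict["members"])
        summary = None
        if "domestic_production_t" in rdict:
            production = float(rdict["domestic_production_t"])
        else:
            mask = panel_period["country"].isin(members)
            production = float(
                (panel_period.loc[mask, "reported_t"] + panel_period.loc[mask, "unreported_t"]).sum()
            ) / max(n_years, 1)
        if "exports_t" in rdict:
            exports = float(rdict["exports_t"])
        else:
            summary = trade.region_trade_summary(
                flows, trade.RegionDefinition(rdict["name"], members)
            )
            exports = summary["export_t"]
        region = trade.RegionDefinition(
            name=rdict["name"], members=members,
            domestic_production_t=production, exports_t=exports,
        )
        missing = [c for c in members if c not in risks.index]
        if missing:
            raise FishriskError(f"no prevalence estimate for region members: {missing}")
        domestic_risk = float(risks.loc[list(members)].mean())
        res = trade.assess_region(flows, risks, region, domestic_risk)
        _write_json(res.as_dict(), outdir / f"supply_risk_{region.name}.json")
        _write_json(
            trade.build_sankey(flows, risks, region, domestic_risk, top_n=10),
            outdir / f"sankey_{region.name}.json",
        )
        artifacts += [f"supply_risk_{region.name}.json", f"sankey_{region.name}.json"]
        results[region.name] = res.supply_risk_kg_per_t
    manifest["stages"]["trade"] = {
        "status": "ok", "rows": {"flows": len(flows), "regions": len(config.regions)},
        "supply_risk_kg_per_t": results, "artifacts": artifacts,
    }


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES) -> dict:
    """Execute the requested stages and return (and write) the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "seeds": {
            "synthetic": config.synthetic.seed if config.synthetic else None,
            "monte_carlo": config.mc_seed,
            "clustering": config.cluster_seed,
        },
        "stages": {},
    }
    stages = tuple(stages)
    current = None
    try:
        if "synth" in stages and config.synthetic is not None:
            current = "synth"
            _stage_synth(config, outdir, manifest)
        needs_data = any(s in stages for s in ("metrics", "regress", "cluster", "trade"))
        if needs_data:
            data = _load_inputs(config, outdir)
        m = None
        if any(s in stages for s in ("metrics", "regress", "cluster")):
            current = "metrics"
            m = _stage_metrics(config, data, outdir, manifest)
        if "regress" in stages:
            current = "regress"
            _stage_regress(config, m, data["slavery"], outdir, manifest)
        if "cluster" in stages:
            current = "cluster"
            _stage_cluster(config, m, outdir, manifest)
        if "trade" in stages:
            current = "trade"
            if config.regions and data.get("trade") is not None:
                _stage_trade(config, data, outdir, manifest)
            else:
                manifest["stages"]["trade"] = {"status": "skipped"}
    except FishriskError as exc:
        manifest["stages"][current] = {"status": "error", "message": str(exc)}
        _write_json(manifest, outdir / "manifest.json")
        raise FishriskError(f"stage {current!r} failed: {exc}") from exc
    _write_json(manifest, outdir / "manifest.json")
    return manifest
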