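import numpy as np
import pandas as pd
import pytest

import fishrisk as fr


@pytest.fixture(scope="session")
def default_config():
    """The standard 20-country synthetic world (decade 2005-2014)."""
    return fr.SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def world(default_config):
    """Panel, cells, ports, metrics, slavery and trade for the default config."""
    panel = fr.generate_country_panel(default_config)
    cells, ports = fr.generate_spatial_catch(default_config, panel)
    m = fr.compute_country_metrics(panel, cells, ports)
    slavery, provenance = fr.generate_slavery_estimates(default_config, m)
    flows = fr.generate_trade_matrix(default_config)
    return {
        "config": default_config,
        "panel": panel,
        "cells": cells,
        "ports": ports,
        "metrics": m,
        "slavery": slavery,
        "provenance": provenance,
        "flows": flows,
    }


@pytest.fixture()
def tiny_panel():
    """Two countries x two years with hand-checkable numbers."""
    rows = []
    for country, rep, unrep, value in [
        ("AAA", 80.0, 20.0, 2.0e6),
        ("BBB", 500.0, 0.0, 1.0e6),
    ]:
        for year in (2005, 2006):
            rows.append(
                {
                    "country": country,
                    "year": year,
                    "reported_t": rep,
                    "unreported_t": unrep,
                    "landed_value_usd": value,
                    "fishers": 100.0,
                    "harmful_subsidy_usd": 1.0e5,
                    "gdp_per_capita_usd": 20_000.0,
                }
            )
    return pd.DataFrame(rows)


def recovery_config(seed: int) -> fr.SyntheticConfig:
    """Parameter-recovery conditions: many countries, small noise.

    The intercept is raised so the planted linear predictor stays positive
    for essentially all countries; otherwise the truncation of prevalence at
    zero would bias the recovered slopes.
    """
    return fr.SyntheticConfig(
        n_countries=200, seed=seed, intercept=4.0, noise_sd=0.3
    )


def planted_regression_data(seed: int):
    """Metrics + slavery estimates from the recovery conditions (panel only)."""
    cfg = recovery_config(seed)
    panel = fr.generate_country_panel(cfg)
    m = fr.compute_country_metrics(panel)
    slavery, provenance = fr.generate_slavery_estimates(cfg, m)
    return m, slavery, provenance
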