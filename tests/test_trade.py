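"""Prevalence→risk conversion and propagation over trade flows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fishrisk as fr
from fishrisk.errors import InputError, UndefinedResultError
from fishrisk.trade import average_flows, region_trade_summary


def flows_df(rows):
    return pd.DataFrame(rows, columns=["exporter", "importer", "tonnes"])


class TestPrevalenceToRisk:
    def test_us_prevalence_converts_to_0p2(self):
        r = fr.prevalence_to_risk(1.8, unit="per_10000")
        assert r == pytest.approx(0.18)
        assert fr.display_risk(r) == 0.2

    def test_europe_prevalence_converts_to_0p3(self):
        r = fr.prevalence_to_risk(2.8, unit="per_10000")
        assert r == pytest.approx(0.28)
        assert fr.display_risk(r) == 0.3

    def test_zero_and_identity_unit(self):
        assert fr.prevalence_to_risk(0.0) == 0.0
        assert fr.prevalence_to_risk(3.5, unit="per_1000") == 3.5

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            fr.prevalence_to_risk(-0.1)

    def test_unknown_unit_rejected(self):
        with pytest.raises(InputError):
            fr.prevalence_to_risk(1.0, unit="percent")


class TestImportRisk:
    def test_single_exporter_passthrough(self):
        region = fr.RegionDefinition("usa", ("USA",))
        flows = flows_df([("THA", "USA", 100.0)])
        risk, breakdown = fr.import_risk(flows, {"THA": 4.2}, region)
        assert risk == 4.2
        assert len(breakdown) == 1 and breakdown.loc[0, "share"] == 1.0

    def test_equal_tonnes_average(self):
        region = fr.RegionDefinition("usa", ("USA",))
        flows = flows_df([("AAA", "USA", 50.0), ("BBB", "USA", 50.0)])
        risk, _ = fr.import_risk(flows, {"AAA": 2.0, "BBB": 4.0}, region)
        assert risk == pytest.approx(3.0)

    def test_intra_bloc_flows_are_not_imports(self):
        region = fr.RegionDefinition("eu", ("FRA", "DEU"))
        flows = flows_df([("FRA", "DEU", 100.0)])
        with pytest.raises(UndefinedResultError):
            fr.import_risk(flows, {"FRA": 1.0, "DEU": 1.0}, region)

    def test_missing_risk_scores_listed(self):
        region = fr.RegionDefinition("usa", ("USA",))
        flows = flows_df([("THA", "USA", 10.0), ("VNM", "USA", 5.0)])
        with pytest.raises(InputError, match="VNM"):
            fr.import_risk(flows, {"THA": 1.0}, region)


class TestSupplyRisk:
    def test_us_multiplier_is_17(self):
        # import risk 3.1 kg/t against the unrounded domestic risk from
        # a prevalence of 1.8 per 10,000
        domestic = fr.prevalence_to_risk(1.8, unit="per_10000")
        region = fr.RegionDefinition("usa", ("USA",), 1000.0, 0.0)
        res = fr.supply_risk(region, 3.1, 500.0, domestic)
        assert round(res.import_vs_domestic_ratio) == 17

    def test_no_imports_collapses_to_domestic(self):
        region = fr.RegionDefinition("r", ("AAA",), 100.0, 0.0)
        res = fr.supply_risk(region, 5.0, 0.0, 2.0)
        assert res.supply_risk_kg_per_t == 2.0
        assert res.supply_vs_domestic_ratio == pytest.approx(1.0)

    def test_equal_tonnes_mix(self):
        region = fr.RegionDefinition("r", ("AAA",), 100.0, 0.0)
        res = fr.supply_risk(region, 3.0, 100.0, 1.0)
        assert res.supply_risk_kg_per_t == pytest.approx(2.0)

    def test_exports_floor_at_zero_net(self, caplog):
        region = fr.RegionDefinition("hub", ("AAA",), 50.0, 80.0)
        with caplog.at_level("WARNING"):
            res = fr.supply_risk(region, 2.0, 10.0, 1.0)
        assert res.domestic_net_t == 0.0
        assert res.supply_risk_kg_per_t == pytest.approx(2.0)
        assert any("exceed production" in r.message for r in caplog.records)

    def test_zero_domestic_risk_ratio_undefined_not_infinite(self):
        region = fr.RegionDefinition("r", ("AAA",), 100.0, 0.0)
        res = fr.supply_risk(region, 2.0, 50.0, 0.0)
        assert res.import_vs_domestic_ratio is None
        assert res.supply_vs_domestic_ratio is None

    def test_both_tonnages_zero_undefined(self):
        region = fr.RegionDefinition("r", ("AAA",), 0.0, 0.0)
        with pytest.raises(UndefinedResultError):
            fr.supply_risk(region, 1.0, 0.0, 1.0)

    @given(
        imp_risk=st.floats(0, 10), dom_risk=st.floats(0.01, 10),
        imp_t=st.floats(0, 1e6), dom_t=st.floats(0.1, 1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_convexity(self, imp_risk, dom_risk, imp_t, dom_t):
        region = fr.RegionDefinition("r", ("AAA",), dom_t, 0.0)
        res = fr.supply_risk(region, imp_risk, imp_t, dom_risk)
        lo, hi = sorted([imp_risk, dom_risk]) if imp_t > 0 else (dom_risk, dom_risk)
        assert lo - 1e-9 <= res.supply_risk_kg_per_t <= hi + 1e-9


class TestSankey:
    def test_one_exporter_plus_domestic(self):
        region = fr.RegionDefinition("usa", ("USA",), 200.0, 50.0)
        flows = flows_df([("THA", "USA", 100.0)])
        sk = fr.build_sankey(flows, {"THA": 4.0}, region, domestic_risk_kg_per_t=0.2)
        assert len(sk["links"]) == 2
        into_supply = sum(l["tonnes"] for l in sk["links"])
        assert into_supply == pytest.approx(100.0 + 150.0)

    def test_top_n_truncation_conserves_tonnage(self):
        rng = np.random.default_rng(0)
        srcs = [f"S{i:02d}" for i in range(10)]
        flows = flows_df([(s, "USA", float(rng.uniform(1, 100))) for s in srcs])
        risks = {s: float(rng.uniform(0, 5)) for s in srcs}
        region = fr.RegionDefinition("usa", ("USA",), 500.0, 100.0)
        sk = fr.build_sankey(flows, risks, region, 0.2, top_n=3)
        source_links = [l for l in sk["links"] if l["source"] != "usa domestic production"]
        assert len(source_links) == 4  # top 3 + "other"
        assert sum(l["tonnes"] for l in source_links) == pytest.approx(flows["tonnes"].sum())


class TestAverageFlows:
    def test_commodity_prefix_filter_and_window_mean(self):
        flows = pd.DataFrame(
            {
                "exporter": ["AAA"] * 3,
                "importer": ["BBB"] * 3,
                "hs6": ["030342", "030342", "160414"],
                "year": [2011, 2012, 2011],
                "tonnes": [10.0, 30.0, 99.0],
            }
        )
        agg = average_flows(flows, years=(2011, 2014), hs6_prefix="03")
        assert len(agg) == 1
        # (10 + 30) tonnes over a 4-year window
        assert agg.loc[0, "tonnes"] == pytest.approx(10.0)


def random_world(seed):
    rng = np.random.default_rng(seed)
    n = 8
    codes = [f"C{i}" for i in range(n)]
    rows = [
        (a, b, float(rng.uniform(1, 1000)))
        for a in codes
        for b in codes
        if a != b and rng.random() < 0.5
    ]
    risks = pd.Series({c: float(rng.uniform(0, 8)) for c in codes})
    return codes, flows_df(rows), risks


@pytest.mark.parametrize("seed", range(25))
def test_randomised_propagation_invariants(seed):
    codes, flows, risks = random_world(seed)
    region = fr.RegionDefinition(
        "r", (codes[0],), float(np.random.default_rng(seed).uniform(10, 1000)), 0.0
    )
    if not len(flows[(flows["importer"] == codes[0])]):
        pytest.skip("no imports drawn")
    dom = float(risks[codes[0]])
    imp_risk, breakdown = fr.import_risk(flows, risks, region)
    imp_t = float(breakdown["tonnes"].sum())
    res = fr.supply_risk(region, imp_risk, imp_t, dom)
    # convexity
    assert min(imp_risk, dom) - 1e-9 <= res.supply_risk_kg_per_t <= max(imp_risk, dom) + 1e-9
    # homogeneity: scaling all tonnages changes nothing
    scaled = flows.assign(tonnes=flows["tonnes"] * 3.7)
    region2 = fr.RegionDefinition("r", (codes[0],), region.domestic_production_t * 3.7, 0.0)
    imp2, bd2 = fr.import_risk(scaled, risks, region2)
    res2 = fr.supply_risk(region2, imp2, float(bd2["tonnes"].sum()), dom)
    assert imp2 == pytest.approx(imp_risk)
    assert res2.supply_risk_kg_per_t == pytest.approx(res.supply_risk_kg_per_t)
    # merging exporters with equal risk leaves import risk unchanged
    uniform = pd.Series(2.5, index=risks.index)
    u_risk, _ = fr.import_risk(flows, uniform, region)
    assert u_risk == pytest.approx(2.5)
    u_res = fr.supply_risk(region, u_risk, imp_t, 2.5)
    assert u_res.supply_risk_kg_per_t == pytest.approx(2.5)
    assert u_res.import_vs_domestic_ratio == pytest.approx(1.0)
    assert u_res.supply_vs_domestic_ratio == pytest.approx(1.0)


def test_region_trade_summary_partitions_flows():
    flows = flows_df(
        [("FRA", "DEU", 10.0), ("THA", "FRA", 20.0), ("DEU", "THA", 5.0), ("THA", "VNM", 7.0)]
    )
    s = region_trade_summary(flows, fr.RegionDefinition("eu", ("FRA", "DEU")))
    assert s == {"import_t": 20.0, "export_t": 5.0, "intra_bloc_t": 10.0}
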