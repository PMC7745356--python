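"""Item screening, anchoring rules, multigroup calibration, scoring tables."""

import json

import numpy as np
import pytest
from scipy.stats import norm

import sesindex as si
from sesindex.index import DesignError, IncompleteStatsError, ScoringError
from sesindex.irt import DegenerateItemError

from conftest import SEED


def printed_stats(cfg):
    """Per-site ItemStats from the packaged (published) tables: prevalence,
    loading, and the slope implied by the loading."""
    out = {}
    for site in cfg.sites:
        out[site] = {}
        for item in cfg.items:
            lam = cfg.loadings[site][item]
            out[site][item] = si.ItemStats(
                item, cfg.prevalences[site][item], lam, si.loading_to_slope(lam)
            )
    return out


class TestScreenItems:
    def test_low_loading_dropped(self):
        stats = {"x": si.ItemStats("x", 0.30, loading=0.39, slope=1.2)}
        d = si.screen_items(stats)["x"]
        assert not d.keep and "loading" in d.reason

    def test_floor_effect_dropped_before_other_rules(self):
        stats = {"x": si.ItemStats("x", 0.0, loading=0.8, slope=1.5)}
        d = si.screen_items(stats)["x"]
        assert not d.keep and d.reason == "floor"

    def test_boundary_passing_item_kept(self):
        stats = {"x": si.ItemStats("x", 0.50, loading=0.41, slope=1.01)}
        assert si.screen_items(stats)["x"].keep

    def test_low_slope_dropped(self):
        stats = {"x": si.ItemStats("x", 0.50, loading=0.6, slope=0.9)}
        d = si.screen_items(stats)["x"]
        assert not d.keep and "slope" in d.reason

    def test_missing_statistic_rejected(self):
        stats = {"x": si.ItemStats("x", 0.50, loading=None, slope=1.2)}
        with pytest.raises(IncompleteStatsError, match="x"):
            si.screen_items(stats)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            si.SelectionCriteria(floor=0.99, ceiling=0.01)
        with pytest.raises(ValueError):
            si.SelectionCriteria(min_loading=-0.1)


class TestAssignAnchors:
    def test_published_design_reproduced(self, default_cfg):
        design = si.assign_anchors(printed_stats(default_cfg))
        # DRC loses the two items nobody owns there, gains the pool items
        assert set(design.site_items["DRC"]) == (
            set(si.STANDARD_ITEMS) - {"lpg_electricity_fuel", "refrigerator"}
        ) | {"bicycle", "more_than_one_room"}
        removed = {s["removed"] for s in design.substitutions["DRC"]}
        assert removed == {"lpg_electricity_fuel", "refrigerator"}
        # every other site keeps the ten standard items
        for site in default_cfg.sites:
            if site != "DRC":
                assert design.site_items[site] == si.STANDARD_ITEMS
        # eight items are common to all sites
        assert len(design.common_items()) == 8

    def test_poorly_discriminating_item_site_specific(self, default_cfg):
        design = si.assign_anchors(printed_stats(default_cfg))
        assert design.status["Kenya"]["improved_water"] == "site_specific"

    def test_good_item_is_global_anchor(self, default_cfg):
        # uniformly well-behaved stats -> anchored everywhere
        stats = {
            s: {it: si.ItemStats(it, 0.5, 0.7, 1.5) for it in si.STANDARD_ITEMS}
            for s in ("A", "B", "C")
        }
        design = si.assign_anchors(stats)
        for site in ("A", "B", "C"):
            assert all(v == "anchor" for v in design.status[site].values())
        # on the published statistics, television anchors at every site where
        # it is not essentially absent (DRC: 0.4% -> site-specific there)
        printed = si.assign_anchors(printed_stats(default_cfg))
        for site in default_cfg.sites:
            expected = "site_specific" if site == "DRC" else "anchor"
            assert printed.status[site]["television"] == expected

    def test_missing_site_stats_rejected(self):
        stats = {"A": {"finished_floor": si.ItemStats("finished_floor", 0.5, 0.7, 1.5)}}
        with pytest.raises(IncompleteStatsError):
            si.assign_anchors(stats)

    def test_exhausted_pool_retains_item_with_warning(self):
        stats = {
            "A": {
                it: si.ItemStats(it, 0.5, 0.7, 1.5) for it in si.STANDARD_ITEMS
            }
        }
        stats["A"]["car"] = si.ItemStats("car", 0.0, None, None)
        design = si.assign_anchors(stats, replacement_pool=[])
        assert "car" in design.site_items["A"]
        assert any("car" in w for w in design.warnings)
        assert design.status["A"]["car"] == "anchor"  # constant: linking excluded

    def test_design_json_roundtrip(self, tmp_path, default_cfg):
        design = si.assign_anchors(printed_stats(default_cfg))
        path = tmp_path / "design.json"
        design.to_json(path)
        loaded = si.IndexDesign.from_json(path)
        assert loaded.site_items == design.site_items
        assert loaded.status == design.status


def two_site_linked_config(mu_b=-1.0, n_items=8):
    """Two sites with identical item parameters and latent means 0 / mu_b."""
    rng = np.random.default_rng(7)
    lams = rng.uniform(0.5, 0.85, n_items)
    taus = rng.uniform(-0.8, 0.8, n_items)
    names = [f"x{j}" for j in range(n_items)]

    def prev(mu):
        scale = np.sqrt(lams**2 + 1 - lams**2)  # sd = 1
        return dict(zip(names, 1 - norm.cdf((taus - lams * mu) / scale)))

    return si.calibrate_generator(
        {"ref": prev(0.0), "low": prev(mu_b)},
        {"ref": dict(zip(names, lams)), "low": dict(zip(names, lams))},
        {"ref": 0.5, "low": 0.5},
        latent={"ref": (0.0, 1.0), "low": (mu_b, 1.0)},
        seed=SEED,
    )


@pytest.fixture(scope="module")
def linked_fit(grid):
    cfg = two_site_linked_config()
    data = si.simulate_responses(cfg, 10_000, seed=SEED, covariates=False)
    items = list(cfg.items)
    design = si.IndexDesign(
        {"ref": items, "low": items},
        {s: {i: "anchor" for i in items} for s in ("ref", "low")},
    )
    result = si.multigroup_calibrate(data, design, grid, reference_site="ref")
    return data, design, result


class TestMultigroupCalibrate:
    def test_group_mean_difference_recovered(self, linked_fit):
        _, _, result = linked_fit
        assert result.latent["ref"] == (0.0, 1.0)
        assert result.latent["low"][0] == pytest.approx(-1.0, abs=0.1)

    def test_anchor_parameters_shared_across_sites(self, linked_fit):
        _, _, result = linked_fit
        for p_ref, p_low in zip(result.params["ref"], result.params["low"]):
            assert (p_ref.a, p_ref.b) == (p_low.a, p_low.b)
        payload = json.loads(result.to_json())
        assert set(payload["anchors"]) == {f"x{j}" for j in range(8)}
        assert payload["site_specific"] == {}

    def test_pooled_loglik_monotone(self, linked_fit):
        _, _, result = linked_fit
        assert np.all(np.diff(result.loglik_history) >= -1e-6)

    def test_single_group_all_free_equals_fit_2pl(self, grid):
        cfg = two_site_linked_config()
        data = si.simulate_responses(cfg, 3_000, seed=SEED, covariates=False,
                                     sites=["ref"])
        items = list(cfg.items)
        design = si.IndexDesign(
            {"ref": items}, {"ref": {i: "site_specific" for i in items}}
        )
        multi = si.multigroup_calibrate(data, design, grid, reference_site="ref")
        single = si.fit_2pl(data, grid)
        assert multi.loglik == pytest.approx(single.loglik, abs=1e-4)
        for pm, ps in zip(multi.params["ref"], single.params):
            assert pm.a == pytest.approx(ps.a, abs=1e-3)
            assert pm.b == pytest.approx(ps.b, abs=1e-3)

    def test_site_specific_constant_item_rejected(self, grid):
        cfg = two_site_linked_config()
        data = si.simulate_responses(cfg, 500, seed=SEED, covariates=False,
                                     sites=["ref"])
        data.data["x0"] = 0.0
        items = list(cfg.items)
        design = si.IndexDesign(
            {"ref": items}, {"ref": {i: "site_specific" for i in items}}
        )
        with pytest.raises(DegenerateItemError, match="x0"):
            si.multigroup_calibrate(data, design, grid, reference_site="ref")

    def test_result_json_roundtrip(self, linked_fit, tmp_path):
        _, design, result = linked_fit
        path = tmp_path / "params.json"
        result.to_json(path)
        loaded = si.MultigroupResult.from_json(path, design)
        for site in ("ref", "low"):
            for p0, p1 in zip(result.params[site], loaded.params[site]):
                assert (p0.a, p0.b, p0.group) == (p1.a, p1.b, p1.group)
        assert loaded.latent["low"][0] == pytest.approx(result.latent["low"][0])


class TestScoringTables:
    def identical_result(self, a=1.5, b=0.0, J=10):
        params = [si.ItemParameters(f"x{j}", a, b) for j in range(J)]
        return si.MultigroupResult(
            params={"A": params}, anchors={p.item: (p.a, p.b) for p in params},
            latent={"A": (0.0, 1.0)}, loglik=0.0, n_cycles=1, converged=True,
        )

    def test_endpoints_exact(self, calibrated):
        *_, tables = calibrated
        for site in tables.sites:
            assert tables.scores[site][0] == 0.0
            assert tables.scores[site][-1] == 100.0

    def test_strictly_increasing(self, calibrated):
        *_, tables = calibrated
        for site in tables.sites:
            assert np.all(np.diff(tables.scores[site]) > 0)

    def test_doubling_slopes_preserves_endpoints(self, grid):
        t1 = si.build_scoring_tables(self.identical_result(a=1.5), grid)
        t2 = si.build_scoring_tables(self.identical_result(a=3.0), grid)
        for t in (t1, t2):
            assert t.scores["A"][0] == 0.0 and t.scores["A"][-1] == 100.0

    def test_identical_items_match_fine_grid_oracle(self):
        # independent oracle: E[theta | S=s] for binomial items on a dense grid
        a, b, J = 1.5, 0.0, 10
        t = np.linspace(-9, 9, 4001)
        from scipy.stats import binom, norm

        w = norm.pdf(t)
        p = 1 / (1 + np.exp(-a * (t - b)))
        eap = np.empty(J + 1)
        for s in range(J + 1):
            like = binom.pmf(s, J, p) * w
            eap[s] = np.trapezoid(t * like, t) / np.trapezoid(like, t)
        oracle = 100 * (eap - eap[0]) / (eap[-1] - eap[0])
        grid = si.QuadratureGrid.normal()
        tables = si.build_scoring_tables(self.identical_result(a, b, J), grid)
        assert tables.scores["A"] == pytest.approx(oracle, abs=0.01)

    def test_zero_information_set_rejected(self, grid):
        result = self.identical_result(a=0.0)
        with pytest.raises(ScoringError):
            si.build_scoring_tables(result, grid)

    def test_csv_roundtrip(self, tmp_path, calibrated):
        *_, tables = calibrated
        path = tmp_path / "tables.csv"
        tables.to_csv(path)
        loaded = si.ScoringTable.from_csv(path, tables.site_items)
        for site in tables.sites:
            assert loaded.scores[site] == pytest.approx(
                np.round(tables.scores[site], 2)
            )

    def test_reference_table_matches_published_values(self):
        ref = si.reference_scoring_table()
        assert ref.lookup("DRC", 2) == 16.18
        assert ref.lookup("Guatemala", 1) == 7.12
        for site in ref.sites:
            assert ref.lookup(site, 0) == 0.0
            assert ref.lookup(site, 10) == 100.0
        assert "bicycle" in ref.site_items["DRC"]
        assert "refrigerator" not in ref.site_items["DRC"]


class TestEndToEndDesign:
    def test_empirical_pipeline_reproduces_published_design(self, calibrated):
        _, design, result, _ = calibrated
        removed = {s["removed"] for s in design.substitutions["DRC"]}
        assert removed == {"lpg_electricity_fuel", "refrigerator"}
        added = {s["added"] for s in design.substitutions["DRC"]}
        assert added == {"bicycle", "more_than_one_room"}
        assert len(design.common_items()) == 8
        # anchors store exactly one parameter pair per item
        payload = json.loads(result.to_json())
        for item, val in payload["anchors"].items():
            for site, plist in result.params.items():
                for p in plist:
                    if p.item == item and p.group == "anchor":
                        assert (p.a, p.b) == (val["a"], val["b"])
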