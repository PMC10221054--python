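"""Scenario grids, correlations, inversion scenarios and regression fits."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import greensail as gs
from greensail.experiments import (
    INVERSION_PAI_GRID,
    build_stack,
    correlation_table,
    default_scenario_config,
    fit_green_fpar_vi,
    pearson_r,
    run_inversion_scenario,
    run_scenario_grid,
    species_fpar_table,
)
from greensail.sail import SailError

from conftest import flat_optics

PAR_WL = np.arange(400.0, 1000.0 + 1e-9, 5.0)


def _components():
    leaf = gs.generate_component_optics("leaf", gs.SPECIES_PROFILES["oak"],
                                        seed=0)
    branch = gs.generate_component_optics("branch", gs.BARK_BROADLEAF, seed=0)
    soil = gs.generate_component_optics("soil", gs.SOIL_DEFAULT, seed=0)
    return leaf, branch, soil


class TestBuildStack:
    def test_pure_leaf_emits_single_layer(self):
        leaf, branch, soil = _components()
        stack = build_stack(2.0, 1.0, leaf, branch, soil)
        assert len(stack.layers) == 1
        assert stack.layers[0].component.kind is gs.ComponentKind.LEAF

    def test_interleaved_layer_arithmetic(self):
        leaf, branch, soil = _components()
        stack = build_stack(2.0, 0.5, leaf, branch, soil,
                            arrangement="interleaved", n_pairs=10)
        assert len(stack.layers) == 20
        areas = [l.area_index for l in stack.layers]
        assert all(a == pytest.approx(0.1) for a in areas)
        assert stack.green_proportion == pytest.approx(0.5)

    def test_blocks_layer_order_is_leaf_over_branch(self):
        leaf, branch, soil = _components()
        stack = build_stack(3.0, 0.7, leaf, branch, soil, arrangement="blocks")
        kinds = [l.component.kind for l in stack.layers]
        assert kinds == [gs.ComponentKind.LEAF, gs.ComponentKind.BRANCH]
        assert stack.total_pai == pytest.approx(3.0)

    def test_interleave_refinement_converges(self, geom):
        leaf, branch, soil = _components()
        results = []
        for n_pairs in (10, 40):
            stack = build_stack(3.0, 0.6, leaf, branch, soil,
                                arrangement="interleaved", n_pairs=n_pairs)
            profile = gs.solve_stack(stack, geom)
            results.append(gs.partition_canopy_fpar(profile, stack).fpar_total)
        assert abs(results[0] - results[1]) < 0.005


class TestScenarioGrid:
    def test_row_count_is_grid_product(self, dbf_grid):
        assert len(dbf_grid) == 9 * 7

    def test_deterministic(self, dbf_cfg, dbf_grid):
        again = run_scenario_grid(dbf_cfg)
        pd.testing.assert_frame_equal(again, dbf_grid)

    def test_green_fpar_maximal_at_densest_greenest_canopy(self, dbf_grid):
        top = dbf_grid.loc[dbf_grid.fpar_pav.idxmax()]
        assert top.pai == max(dbf_grid.pai)
        assert top.green_proportion == max(dbf_grid.green_proportion)

    def test_fpar_monotone_in_pai(self, dbf_grid, enf_grid):
        for grid in (dbf_grid, enf_grid):
            for p, group in grid.groupby("green_proportion"):
                g = group.sort_values("pai")
                assert np.all(np.diff(g.fpar_total) > 0)
                assert np.all(np.diff(g.fpar_pav) > 0)

    def test_npv_fpar_unimodal_with_interior_peak(self, dbf_grid):
        g = dbf_grid[dbf_grid.green_proportion == 0.5].sort_values("pai")
        vals = g.fpar_npv.to_numpy()
        peak = int(np.argmax(vals))
        assert 0 < peak < len(vals) - 1
        assert 1.0 <= g.pai.to_numpy()[peak] <= 3.0
        assert np.all(np.diff(vals[: peak + 1]) > 0)
        assert np.all(np.diff(vals[peak:]) < 0)

    def test_partition_shifts_with_green_proportion(self, dbf_grid):
        for pai, group in dbf_grid.groupby("pai"):
            g = group.sort_values("green_proportion")
            assert np.all(np.diff(g.fpar_pav) > 0)
            assert np.all(np.diff(g.fpar_npv) < 0)

    def test_npv_share_spans_wide_range(self, dbf_grid):
        share = 100.0 * dbf_grid.fpar_npv / dbf_grid.fpar_total
        assert share.min() < 5.0
        assert share.max() > 30.0


class TestPearson:
    def test_perfect_lines(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(xs, [2 * x + 1 for x in xs]) == pytest.approx(1.0)
        assert pearson_r(xs, [-x for x in xs]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(
            0.8, abs=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SailError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(SailError, match="at least 3"):
            pearson_r([1, 2], [1, 2])
        with pytest.raises(SailError, match="equal-length"):
            pearson_r([1, 2, 3], [1, 2])


class TestCorrelations:
    def test_green_fpar_strongly_linear_in_indices(self, dbf_grid):
        table = correlation_table(dbf_grid)
        assert (table.loc["fpar_pav"] > 0.9).all()

    def test_npv_fpar_weakly_related_to_indices(self, dbf_grid):
        table = correlation_table(dbf_grid)
        assert (table.loc["fpar_npv"].abs() < 0.5).all()
        assert (table.loc["fpar_npv"].abs()
                < table.loc["fpar_pav"] - 0.4).all()

    def test_stratified_table_has_group_level(self, dbf_grid):
        out = correlation_table(dbf_grid, by="green_proportion")
        assert out.index.nlevels == 2
        assert set(out.index.get_level_values(0)) == set(
            dbf_grid.green_proportion.unique()
        )

    def test_constant_column_propagates_error(self, dbf_grid):
        broken = dbf_grid.assign(ndvi=0.5)
        with pytest.raises(SailError, match="constant"):
            correlation_table(broken)


class TestInversionScenarios:
    def test_dbf_holds_woody_area_constant(self, dbf_inversion):
        woody = dbf_inversion.pai * (1 - dbf_inversion.green_proportion)
        np.testing.assert_allclose(woody, 0.5, atol=1e-12)
        assert dbf_inversion.iloc[0].green_proportion == pytest.approx(0.5)

    def test_enf_holds_green_proportion_constant(self, enf_inversion):
        np.testing.assert_allclose(enf_inversion.green_proportion, 0.9)
        row = enf_inversion[enf_inversion.pai == 4.0].iloc[0]
        assert row.pai * row.green_proportion == pytest.approx(3.6)

    def test_seven_rows_on_integer_pai(self, dbf_inversion):
        assert len(dbf_inversion) == 7
        assert tuple(dbf_inversion.pai) == INVERSION_PAI_GRID

    def test_pai_below_woody_area_rejected(self, dbf_cfg):
        with pytest.raises(SailError, match="woody area"):
            run_inversion_scenario(dbf_cfg, pai_values=[0.3])

    def test_high_linearity_of_green_fpar_with_indices(self, dbf_inversion,
                                                       enf_inversion):
        for table in (dbf_inversion, enf_inversion):
            cors = correlation_table(table, fpar_columns=("fpar_pav",))
            assert (cors.loc["fpar_pav"] > 0.9).all()


class TestRegressionFit:
    def test_exact_line_recovered(self):
        vi = np.linspace(0.1, 0.7, 10)
        table = pd.DataFrame({"evi": vi, "fpar_pav": 2.0 * vi - 0.5})
        fit = fit_green_fpar_vi(table, "evi")
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.5, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert fit.mean_error == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(17)
        vi = rng.uniform(0.1, 0.7, size=50)
        y = 2.0 * vi - 0.5 + rng.normal(0.0, 0.01, size=50)
        fit = fit_green_fpar_vi(pd.DataFrame({"evi": vi, "fpar_pav": y}), "evi")
        assert fit.slope == pytest.approx(2.0, abs=0.05)

    def test_noiseless_recovery_unbiased_across_seeds(self):
        biases = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vi = rng.uniform(0.05, 0.8, size=30)
            table = pd.DataFrame({"evi": vi, "fpar_pav": 1.7 * vi - 0.2})
            biases.append(fit_green_fpar_vi(table, "evi").slope - 1.7)
        assert abs(np.mean(biases)) < 0.01

    def test_error_rate_definition(self):
        vi = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([0.2, 0.5, 0.5, 0.8])
        fit = fit_green_fpar_vi(pd.DataFrame({"evi": vi, "fpar_pav": y}), "evi")
        pred = fit.slope * vi + fit.intercept
        assert fit.mean_error == pytest.approx(np.mean(np.abs(pred - y)))
        assert fit.error_rate_percent == pytest.approx(
            100 * fit.mean_error / y.mean()
        )

    def test_degenerate_design_rejected(self):
        table = pd.DataFrame({"evi": [0.2, 0.2, 0.2], "fpar_pav": [0.1, 0.2, 0.3]})
        with pytest.raises(SailError, match="degenerate"):
            fit_green_fpar_vi(table, "evi")


@pytest.fixture(scope="module")
def species_table():
    species = [
        gs.generate_component_optics("leaf", profile, seed=0)
        for profile in gs.SPECIES_PROFILES.values()
    ]
    branch = gs.generate_component_optics("branch", gs.BARK_BROADLEAF, seed=0)
    soil = gs.generate_component_optics("soil", gs.SOIL_DEFAULT, seed=0)
    return species_fpar_table(species, branch, soil)


class TestSpeciesTable:
    def test_layout(self, species_table):
        table = species_table
        assert table.shape == (6, 6)
        assert set(table.columns.get_level_values("proportion")) == {0.98, 0.5}
        assert set(table.columns.get_level_values("pai")) == {1.0, 4.0, 7.0}

    def test_oak_leads_every_scenario(self, species_table):
        others = species_table.drop(index="oak")
        assert (species_table.loc["oak"] >= others.max(axis=0) - 1e-12).all()

    def test_green_fpar_rises_with_pai_for_every_species(self, species_table):
        for proportion in (0.98, 0.5):
            sub = species_table[proportion]
            assert (sub[7.0] > sub[4.0]).all()
            assert (sub[4.0] > sub[1.0]).all()


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        leaf, branch, soil = _components()
        with pytest.raises(SailError, match="proportions"):
            gs.ScenarioConfig(
                forest_type="DBF", leaf_optics=leaf, branch_optics=branch,
                soil_optics=soil, green_proportions=(0.0, 0.5),
            )

    def test_default_config_uses_reference_geometry(self):
        cfg = default_scenario_config("ENF", seed=1)
        assert cfg.geometry.solar_zenith_deg == 30.0
        assert cfg.geometry.view_zenith_deg == 0.0
        assert cfg.geometry.direct_fraction == 1.0
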