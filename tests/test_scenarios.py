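"""Scenario edit algebra and the built-in scenario library."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

import dietsim as ds
from dietsim.nutrients import ADDITIVE
from dietsim.scenarios import ScenarioConfigError, ScenarioEdit, ScenarioSpec


def by_id(library, sid):
    return next(s for s in library if s.id == sid)


class TestApplyEdit:
    def test_halving_pf_reproduces_reference_pf_column(
        self, baseline_table, modelled_reference
    ):
        out = ds.apply_edit(baseline_table, ScenarioEdit.scale("PF", 0.5))
        pf = out.vector("PF")
        assert pf.protein == pytest.approx(23.3)
        assert pf.energy_incl_fibre == pytest.approx(2555.0)
        assert pf.isclose(modelled_reference.vector("PF"), atol=0.51)

    def test_scale_by_one_is_identity(self, baseline_table):
        out = ds.apply_edit(baseline_table, ScenarioEdit.scale("PF", 1.0))
        assert out.to_frame().equals(baseline_table.to_frame())

    def test_scale_unknown_group_errors(self, baseline_table):
        with pytest.raises(KeyError, match="margarine"):
            ds.apply_edit(baseline_table, ScenarioEdit.scale("margarine", 0.5))

    def test_add_food_twice_equals_double_grams(self, baseline_table, profiles):
        e150 = ScenarioEdit.add("fruits", 150.0, profiles["fruits"])
        e300 = ScenarioEdit.add("fruits", 300.0, profiles["fruits"])
        twice = ds.apply_edit(ds.apply_edit(baseline_table, e150), e150)
        once = ds.apply_edit(baseline_table, e300)
        for f in sorted(ADDITIVE):
            assert twice.vector("fruits")[f] == pytest.approx(
                once.vector("fruits")[f], abs=1e-9
            )

    def test_substitute_conserves_total_grams(self, baseline_table, profiles):
        edit = ScenarioEdit.substitution(
            20.0, profiles["sfa_oils"], profiles["healthy_oils"],
            remove_group="PF", add_group="PCI",
        )
        out = ds.apply_edit(baseline_table, edit)
        assert out.aggregate_total().gram_weight == pytest.approx(
            baseline_table.aggregate_total().gram_weight
        )

    def test_substitute_floors_at_zero_with_warning(self, baseline_table, profiles, caplog):
        # removing 60 g of SFA-oil profile strips more saturated fat (27 g)
        # than the PCI group holds (1.1 g): floored, warned
        edit = ScenarioEdit.substitution(
            60.0, profiles["sfa_oils"], profiles["healthy_oils"],
            remove_group="PCI", add_group="PCI",
        )
        with caplog.at_level(logging.WARNING, logger="dietsim.scenarios"):
            out = ds.apply_edit(baseline_table, edit)
        assert "floored" in caplog.text
        assert out.vector("PCI").saturated_fat >= 0.0

    def test_baseline_is_never_mutated(self, baseline_table):
        before = baseline_table.to_frame().copy()
        ds.apply_edit(baseline_table, ScenarioEdit.scale("PF", 0.1))
        assert baseline_table.to_frame().equals(before)


class TestRunScenario:
    def test_empty_spec_is_identity(self, baseline_table):
        out = ds.run_scenario(baseline_table, ScenarioSpec("noop"))
        assert out.to_frame().equals(baseline_table.to_frame())
        assert out.provenance == "modelled"

    def test_s2_scales_mp_grams(self, baseline_table, library):
        out = ds.run_scenario(baseline_table, by_id(library, "S2.m1"))
        assert out.vector("MP").gram_weight == pytest.approx(1898 * 1.25)
        assert out.vector("PF").gram_weight == pytest.approx(437.0)

    def test_scale_composition_law(self, baseline_table):
        one = ds.run_scenario(
            baseline_table,
            ScenarioSpec("ab", edits=(
                ScenarioEdit.scale("MP", 1.2), ScenarioEdit.scale("MP", 1.5),
            )),
        )
        both = ds.apply_edit(baseline_table, ScenarioEdit.scale("MP", 1.8))
        for f in sorted(ADDITIVE):
            assert one.vector("MP")[f] == pytest.approx(both.vector("MP")[f])

    def test_disjoint_edits_commute(self, baseline_table, profiles):
        a = ScenarioEdit.scale("PF", 0.5)
        b = ScenarioEdit.add("nuts", 30.0, profiles["nuts"])
        ab = ds.run_scenario(baseline_table, ScenarioSpec("ab", edits=(a, b)))
        ba = ds.run_scenario(baseline_table, ScenarioSpec("ba", edits=(b, a)))
        assert ab.to_frame().equals(ba.to_frame())


class TestScenarioLibrary:
    def test_s3a_has_five_fish_models(self, library):
        specs = [s for s in library if s.id.startswith("S3a.")]
        assert len(specs) == 5
        grams = [s.edits[1].grams for s in specs]
        assert grams == [40, 80, 120, 160, 200]

    def test_s3b_has_four_nut_models(self, library):
        specs = [s for s in library if s.id.startswith("S3b.")]
        assert [s.edits[1].grams for s in specs] == [10, 20, 30, 40]

    def test_s6_has_no_pf_scaling(self, library):
        s6 = [s for s in library if s.id.startswith("S6.")]
        assert len(s6) == 4
        for spec in s6:
            assert all(e.kind != "scale_group" for e in spec.edits)

    def test_all_other_scenarios_start_with_the_pf_halving(self, library):
        for spec in library:
            if spec.id.startswith("S6."):
                continue
            first = spec.edits[0]
            assert first.kind == "scale_group"
            assert first.groups == ("PF",) and first.factor == 0.5

    def test_grid_override_changes_model_count(self, profiles):
        lib = ds.scenario_library(
            {"grids": {"s3b": {"start": 5, "stop": 40, "step": 5}}},
            profiles=profiles,
        )
        assert len([s for s in lib if s.id.startswith("S3b.")]) == 8

    def test_reference_combination_is_tagged(self, library):
        tagged = [s for s in library if "reference_table" in s.tags]
        assert len(tagged) == 1
        assert tagged[0].id == "S5.n30v225f150.fish40"

    def test_every_library_result_is_finite_and_nonnegative(
        self, baseline_table, library
    ):
        import numpy as np

        for spec in library:
            total = ds.run_scenario(baseline_table, spec).aggregate_total().series
            assert np.isfinite(total.to_numpy()).all(), spec.id
            assert (total.drop("glycaemic_index") >= 0).all(), spec.id

    def test_malformed_custom_scenario_names_offender(self, profiles):
        with pytest.raises(ScenarioConfigError, match="bad_one"):
            ds.scenario_library(
                {"scenarios": [{"id": "bad_one", "edits": [{"kind": "wat"}]}]},
                profiles=profiles,
            )

    def test_custom_scenario_from_yaml_config(self, tmp_path, baseline_table, profiles):
        cfg = tmp_path / "scen.yaml"
        cfg.write_text(
            "scenarios:\n"
            "  - id: my_fish\n"
            "    description: fish only\n"
            "    edits:\n"
            "      - {kind: add_food, group: omega3_fish, grams: 50, profile: omega3_fish}\n"
        )
        lib = ds.scenario_library(cfg, profiles=profiles)
        spec = by_id(lib, "my_fish")
        out = ds.run_scenario(baseline_table, spec)
        assert out.vector("omega3_fish").gram_weight == pytest.approx(2.2 + 50)


@given(factor_a=st.floats(0.0, 2.0), factor_b=st.floats(0.0, 2.0))
def test_sequential_scaling_multiplies(baseline_table, factor_a, factor_b):
    one = ds.apply_edit(
        ds.apply_edit(baseline_table, ScenarioEdit.scale("PF", factor_a)),
        ScenarioEdit.scale("PF", factor_b),
    )
    both = ds.apply_edit(baseline_table, ScenarioEdit.scale("PF", factor_a * factor_b))
    for f in ("gram_weight", "energy_incl_fibre", "sodium"):
        assert one.vector("PF")[f] == pytest.approx(both.vector("PF")[f], abs=1e-9)
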