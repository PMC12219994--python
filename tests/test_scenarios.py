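import numpy as np
import pandas as pd
import pytest

from msusim import (
    BASE_CASE,
    PAPER_GRID_LEVELS,
    RoutingTables,
    ScenarioTimes,
    TreatmentWindows,
    benefit_histograms,
    build_grid,
    evaluate_scenario,
    grouped_parameter_effect,
    national_average,
    summarize_grid,
    sweep_grid,
)
from msusim.scenarios import ScenarioError

from conftest import make_geography, random_geography

SINGLE = {name: (v,) for name, v in BASE_CASE.as_dict().items()}


class TestBuildGrid:
    def test_national_grid_cardinality(self):
        assert len(build_grid(PAPER_GRID_LEVELS)) == 46656  # 4 * 162 * 72

    def test_single_levels_one_scenario(self):
        g = build_grid(SINGLE)
        assert len(g) == 1 and g.scenarios[0] == BASE_CASE

    def test_two_by_two_product_order(self):
        levels = dict(SINGLE, onset_to_call=(0, 60), door_to_needle=(30, 45))
        g = build_grid(levels)
        assert len(g) == 4
        # row-major over canonical field order: onset varies slowest
        assert [(s.onset_to_call, s.door_to_needle) for s in g.scenarios] == [
            (0, 30), (0, 45), (60, 30), (60, 45),
        ]

    def test_empty_level_list_rejected(self):
        with pytest.raises(ScenarioError, match="empty level list"):
            build_grid(dict(SINGLE, onset_to_call=()))

    def test_unknown_field_rejected(self):
        with pytest.raises(ScenarioError, match="unknown"):
            build_grid(dict(SINGLE, bogus=(1,)))


class TestEvaluateScenario:
    def test_toy_time_deltas_match_hand_sums(self, toy_geography, lib):
        rows = evaluate_scenario(toy_geography, BASE_CASE, lib)
        row = rows.iloc[0]
        assert row["delta_t_ivt"] == 35.0  # 165 - 130
        assert row["delta_t_mt"] == 70.0  # 290 - 220

    def test_mirrored_parameters_give_zero_deltas(self, lib):
        """MSU mirroring usual care exactly (co-located everything, matched
        durations) produces deltas of zero to machine epsilon."""
        g = make_geography(
            demand_times={f"d{i}": {"C1": 0.0} for i in range(5)},
            unit_types={"C1": "CSC"},
        )
        rng = np.random.default_rng(123)
        for _ in range(20):
            oc, ca, aos, dtn, post = rng.uniform(0, 90, size=5)
            x = rng.uniform(0, 60)
            s = ScenarioTimes(
                onset_to_call=oc,
                call_to_ambulance=ca,
                ambulance_on_scene=aos,
                door_to_needle=dtn,
                transfer_net_delay=0.0,
                door_to_puncture_usual=dtn + post + x,
                call_to_msu_dispatch=ca + aos,
                msu_arrival_to_ivt=dtn,
                msu_on_scene_post_ivt=post,
                door_to_puncture_msu=x,
            )
            rows = evaluate_scenario(g, s, lib)
            deltas = rows.drop(columns=["demand_id", "admissions"]).to_numpy(dtype=float)
            assert np.abs(deltas).max() < 1e-9

    def test_msu_disbenefit_when_msu_misses_window(self, toy_geography, lib):
        """A demand unit inside the usual-care IVT window but pushed past it
        by MSU travel shows a negative mixed-cohort delta."""
        g = make_geography(
            demand_times={"d1": {"P1": 10.0, "C1": 170.0}},
            unit_types={"P1": "PSC", "C1": "CSC"},
            unit_to_unit={("P1", "C1"): 160.0},
        )
        s = BASE_CASE
        rows = evaluate_scenario(g, s, lib)
        # usual IVT: 60+20+30+10+45 = 165 <= 270; MSU IVT: 60+15+170+30 = 275 > 270
        assert rows.iloc[0]["mixed_delta_p_independent"] < 0


class TestNationalAverage:
    def _rows(self):
        return pd.DataFrame(
            {
                "demand_id": ["a", "b"],
                "admissions": [1.0, 3.0],
                "mixed_delta_utility": [0.0, 0.04],
            }
        )

    def test_weighted_mean_hand_value(self):
        out = national_average(self._rows(), weighting="admission_weighted")
        assert out["mixed_delta_utility"] == pytest.approx(0.03)

    def test_equal_weights_agree_with_unweighted(self):
        rows = self._rows()
        rows["admissions"] = 2.0
        a = national_average(rows, weighting="unweighted")
        b = national_average(rows, weighting="admission_weighted")
        assert a["mixed_delta_utility"] == pytest.approx(b["mixed_delta_utility"])

    def test_single_row_is_identity(self):
        rows = self._rows().iloc[:1]
        assert national_average(rows)["mixed_delta_utility"] == 0.0

    def test_zero_weights_rejected(self):
        rows = self._rows()
        rows["admissions"] = 0.0
        with pytest.raises(ScenarioError, match="zero"):
            national_average(rows, weighting="admission_weighted")

    def test_empty_rejected(self):
        with pytest.raises(ScenarioError):
            national_average(self._rows().iloc[:0])


@pytest.fixture(scope="module")
def small_sweep(lib):
    rng = np.random.default_rng(21)
    geo = random_geography(rng, n_demand=12, n_units=6, n_csc=2, scale=120.0)
    levels = dict(
        SINGLE,
        onset_to_call=(0, 120),
        call_to_ambulance=(15, 45),
        door_to_needle=(30, 45),
        call_to_msu_dispatch=(0, 30),
        msu_arrival_to_ivt=(15, 45),
        transfer_net_delay=(30, 90),
    )
    grid = build_grid(levels)
    return geo, grid, sweep_grid(geo, grid, lib)


class TestSweep:
    def test_cached_sweep_equals_direct_evaluation(self, small_sweep, lib):
        geo, grid, results = small_sweep
        rt = RoutingTables(geo)
        for i in [0, 7, 31, len(grid) - 1]:
            direct = national_average(evaluate_scenario(rt, grid.scenarios[i], lib))
            for m in direct.index:
                assert results.iloc[i][m] == pytest.approx(direct[m], abs=1e-12)

    def test_scenario_order_does_not_change_summary(self, small_sweep):
        _, _, results = small_sweep
        shuffled = results.sample(frac=1.0, random_state=9)
        a = summarize_grid(results)
        b = summarize_grid(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_grouped_partition_sizes_sum_to_grid(self, small_sweep):
        _, grid, results = small_sweep
        groups = results.groupby("onset_to_call").size()
        assert groups.sum() == len(grid)

    def test_single_level_field_group_equals_overall(self, small_sweep):
        _, _, results = small_sweep
        out = grouped_parameter_effect(results, "door_to_puncture_msu")
        assert len(out) == 1
        pd.testing.assert_frame_equal(next(iter(out.values())), summarize_grid(results))

    def test_unknown_field_rejected(self, small_sweep):
        _, _, results = small_sweep
        with pytest.raises(ScenarioError):
            grouped_parameter_effect(results, "nope")

    def test_median_benefit_monotone_in_msu_dispatch(self, small_sweep):
        _, _, results = small_sweep
        eff = grouped_parameter_effect(results, "call_to_msu_dispatch")
        medians = [eff[lv].loc["mixed_delta_utility", "median"] for lv in sorted(eff)]
        assert medians == sorted(medians, reverse=True)

    def test_median_benefit_monotone_in_door_to_needle(self, small_sweep):
        _, _, results = small_sweep
        eff = grouped_parameter_effect(results, "door_to_needle")
        medians = [eff[lv].loc["mixed_delta_utility", "median"] for lv in sorted(eff)]
        assert medians == sorted(medians)


class TestSummaries:
    def test_constant_series(self):
        df = pd.DataFrame({"mixed_delta_utility": [0.02] * 5})
        s = summarize_grid(df).loc["mixed_delta_utility"]
        assert s["min"] == s["median"] == s["max"] == 0.02

    def test_threshold_fraction_counting(self):
        df = pd.DataFrame({"mixed_delta_utility": [0.0, 0.01, 0.02, 0.03]})
        s = summarize_grid(df).loc["mixed_delta_utility"]
        assert s["frac_ge_0.02"] == 0.5
        fracs = [s[f"frac_ge_{t:g}"] for t in (0.0, 0.01, 0.02, 0.03, 0.04)]
        assert fracs == sorted(fracs, reverse=True)

    def test_quartiles_ordered(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"mixed_delta_utility": rng.normal(0.01, 0.02, 200)})
        s = summarize_grid(df).loc["mixed_delta_utility"]
        assert s["min"] <= s["q25"] <= s["median"] <= s["q75"] <= s["max"]


class TestHistograms:
    def test_mass_conservation(self, toy_geography, lib):
        rng = np.random.default_rng(8)
        geo = random_geography(rng, n_demand=30, n_units=5, n_csc=2)
        rows = evaluate_scenario(geo, BASE_CASE, lib)
        h = benefit_histograms(rows, weighting="unweighted")
        edges, counts = h["mixed_delta_utility"]
        assert counts.sum() == len(rows)
        hw = benefit_histograms(rows, weighting="admission_weighted")
        _, mass = hw["mixed_delta_utility"]
        assert mass.sum() == pytest.approx(rows["admissions"].sum())

    def test_identical_rows_single_bin(self):
        rows = pd.DataFrame({"admissions": np.ones(10), "mixed_delta_utility": np.full(10, 0.0125)})
        _, counts = benefit_histograms(rows, metrics=("mixed_delta_utility",))[
            "mixed_delta_utility"
        ]
        assert (counts > 0).sum() == 1

    def test_unit_admissions_equivalence(self):
        rng = np.random.default_rng(1)
        rows = pd.DataFrame(
            {"admissions": np.ones(50), "mixed_delta_utility": rng.normal(0.01, 0.01, 50)}
        )
        a = benefit_histograms(rows, weighting="unweighted", metrics=("mixed_delta_utility",))
        b = benefit_histograms(rows, weighting="admission_weighted", metrics=("mixed_delta_utility",))
        assert np.array_equal(a["mixed_delta_utility"][1], b["mixed_delta_utility"][1])

    def test_bad_bin_width(self):
        rows = pd.DataFrame({"admissions": [1.0], "mixed_delta_utility": [0.0]})
        with pytest.raises(ScenarioError):
            benefit_histograms(rows, bin_width=0.0)
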