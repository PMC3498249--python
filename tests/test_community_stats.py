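import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestrec import (
    CensusCollection,
    InvaderConfig,
    PlotMeta,
    SimConfig,
    Treatment,
    change_tests,
    importance_values,
    rarefy,
    simulate,
)
from forestrec.errors import ConfigError, DesignError, InsufficientDataError
from tests.conftest import make_census, single_plot_collection


class TestImportanceValues:
    def test_single_species_stand(self):
        col = single_plot_collection({"A": [("oak", 7, 0.7)]})
        table = importance_values(col, [("A", "survey")])
        assert list(table["species"]) == ["oak"]
        assert table["iv"].iloc[0] == pytest.approx(100.0)

    def test_two_equal_species(self):
        col = single_plot_collection({"A": [("oak", 5, 0.3), ("fir", 5, 0.3)]})
        table = importance_values(col, [("A", "survey")])
        assert list(table["iv"]) == pytest.approx([50.0, 50.0])

    def test_hand_arithmetic_three_species(self):
        col = single_plot_collection(
            {"A": [("x", 6, 0.5), ("y", 3, 0.3), ("z", 1, 0.2)]}
        )
        table = importance_values(col, [("A", "survey")]).set_index("species")
        assert table.loc["x", "relative_density"] == pytest.approx(60.0)
        assert table.loc["x", "relative_ba"] == pytest.approx(50.0)
        assert table.loc["x", "iv"] == pytest.approx(55.0)
        assert table.loc["y", "iv"] == pytest.approx((30.0 + 30.0) / 2)
        assert table.loc["z", "iv"] == pytest.approx((10.0 + 20.0) / 2)

    def test_sorted_by_descending_iv_ties_by_name(self):
        col = single_plot_collection(
            {"A": [("b", 2, 0.2), ("a", 2, 0.2), ("c", 6, 0.6)]}
        )
        table = importance_values(col, [("A", "survey")])
        assert list(table["species"]) == ["c", "a", "b"]

    def test_pooling_over_plots(self):
        col = single_plot_collection(
            {"A": [("oak", 2, 0.1)], "B": [("oak", 2, 0.1), ("fir", 4, 0.2)]}
        )
        table = importance_values(
            col, [("A", "survey"), ("B", "survey")]
        ).set_index("species")
        assert table.loc["oak", "relative_density"] == pytest.approx(50.0)

    def test_empty_scope_is_design_error(self, toy_collection):
        with pytest.raises(DesignError):
            importance_values(toy_collection, [])

    @given(
        st.lists(
            st.tuples(st.integers(1, 30), st.floats(0.01, 2.0)),
            min_size=1, max_size=10,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_columns_sum_to_100(self, rows):
        triples = [(f"s{i}", n, b) for i, (n, b) in enumerate(rows)]
        col = single_plot_collection({"A": triples})
        table = importance_values(col, [("A", "survey")])
        assert table["relative_density"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table["relative_ba"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table["iv"].sum() == pytest.approx(100.0, abs=1e-9)


def paired_collection(gap_specs, control_specs, area=100.0):
    """specs: list (per pair) of (pre_triples, post_triples)."""
    censuses, meta = [], []
    for i, ((gpre, gpost), (cpre, cpost)) in enumerate(
        zip(gap_specs, control_specs), start=1
    ):
        censuses += [
            make_census(f"G{i}", "pre", gpre), make_census(f"G{i}", "post", gpost),
            make_census(f"C{i}", "pre", cpre), make_census(f"C{i}", "post", cpost),
        ]
        meta += [
            PlotMeta(f"G{i}", f"P{i}", Treatment.GAP, area, "t"),
            PlotMeta(f"C{i}", f"P{i}", Treatment.CONTROL, area, "t"),
        ]
    return CensusCollection(censuses, meta)


class TestChangeTests:
    def test_identical_changes_give_t0_p1(self):
        spec = ([("oak", 5, 0.5)], [("oak", 7, 0.6)])
        col = paired_collection([spec, spec], [spec, spec])
        for res in change_tests(col):
            if res.variable == "endemic_density":
                continue
            assert res.t == pytest.approx(0.0)
            assert res.p_two_tailed == pytest.approx(1.0)
            assert res.df == 1

    def test_basal_area_per_ha_conversion(self):
        # 0.6 m² in a 100 m² plot = 60 m² ha⁻¹
        col = paired_collection(
            [([("oak", 5, 0.0)], [("oak", 5, 0.6)])] * 2,
            [([("oak", 5, 0.3)], [("oak", 5, 0.3)])] * 2,
        )
        res = next(r for r in change_tests(col, variables=["basal_area"]))
        assert res.gap_mean_change == pytest.approx(60.0)
        assert res.control_mean_change == pytest.approx(0.0)

    def test_endemic_density_requires_list(self):
        spec = ([("oak", 5, 0.5)], [("oak", 7, 0.6)])
        col = paired_collection([spec, spec], [spec, spec])
        with pytest.raises(ConfigError):
            change_tests(col, variables=["endemic_density"])
        res = change_tests(
            col, variables=["endemic_density"], endemic_species=["oak"]
        )[0]
        assert res.gap_mean_change == pytest.approx(0.0)

    def test_exclude_species_variant(self):
        col = paired_collection(
            [([("oak", 5, 0.5)], [("oak", 5, 0.5), ("weed", 10, 0.2)])] * 2,
            [([("oak", 5, 0.5)], [("oak", 5, 0.5)])] * 2,
        )
        with_weed = change_tests(col, variables=["stem_density"])[0]
        without = change_tests(
            col, variables=["stem_density"], exclude_species="weed"
        )[0]
        assert with_weed.gap_mean_change == pytest.approx(10.0)
        assert without.gap_mean_change == pytest.approx(0.0)
        assert without.excluded_species == "weed"

    def test_fewer_than_two_pairs_is_error(self):
        spec = ([("oak", 5, 0.5)], [("oak", 7, 0.6)])
        col = paired_collection([spec], [spec])
        with pytest.raises(InsufficientDataError):
            change_tests(col)

    def test_t_statistic_matches_independent_formula(self):
        cfg = SimConfig(seed=11, n_pairs=5)
        col = simulate(cfg)
        res = next(
            r for r in change_tests(col, variables=["stem_density"])
        )
        # independent recomputation: paired differences of (post-pre) changes
        diffs = []
        for pair_id, gap, control in col.complete_pairs():
            gch = (col.get_census(gap.plot_id, "post").total_stems
                   - col.get_census(gap.plot_id, "pre").total_stems)
            cch = (col.get_census(control.plot_id, "post").total_stems
                   - col.get_census(control.plot_id, "pre").total_stems)
            diffs.append(gch - cch)
        d = np.array(diffs, dtype=float)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert res.t == pytest.approx(t_expected, abs=1e-12)
        assert res.df == d.size - 1

    def test_detects_imposed_basal_area_loss(self):
        # gap-only basal-area loss at the magnitude the generator targets
        cfg = SimConfig(seed=5, n_pairs=5, disturbance_mortality=0.45,
                        ba_recovery_fraction=0.55)
        col = simulate(cfg)
        res = next(r for r in change_tests(col, variables=["basal_area"]))
        assert res.gap_mean_change < 0 < res.control_mean_change + 50  # sanity
        assert res.p_two_tailed < 0.05


class TestRarefy:
    def test_full_sample_gives_observed_richness(self):
        res = rarefy([5, 3, 2], 10)
        assert res.expected_species == pytest.approx(3.0)
        assert res.variance == pytest.approx(0.0, abs=1e-12)

    def test_single_individual(self):
        assert rarefy([5, 3, 2], 1).expected_species == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        # all C(10,4) subsamples of stems labelled by species
        pool = [0] * 5 + [1] * 3 + [2] * 2
        richness = [
            len(set(combo)) for combo in itertools.combinations(pool, 4)
        ]
        expected = np.mean(richness)
        variance = np.var(richness)  # population variance over subsamples
        res = rarefy([5, 3, 2], 4)
        assert res.expected_species == pytest.approx(expected, abs=1e-12)
        assert res.variance == pytest.approx(variance, abs=1e-12)

    def test_monotone_in_n(self):
        counts = [12, 7, 3, 1, 1]
        values = [rarefy(counts, n).expected_species for n in range(1, 25)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(5.0)

    def test_resample_mode_close_to_analytic(self):
        analytic = rarefy([5, 3, 2], 4).expected_species
        mc = rarefy([5, 3, 2], 4, mode="resample", seed=1, n_resamples=4000)
        assert mc.expected_species == pytest.approx(analytic, abs=0.05)

    def test_resample_deterministic_given_seed(self):
        a = rarefy([8, 4, 2, 1], 6, mode="resample", seed=3)
        b = rarefy([8, 4, 2, 1], 6, mode="resample", seed=3)
        assert a == b

    def test_census_input(self):
        census = make_census("A", "s", [("oak", 5, 0.5), ("fir", 3, 0.3)])
        assert rarefy(census, 8).expected_species == pytest.approx(2.0)

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            rarefy([5, 3, 2], 0)
        with pytest.raises(ValueError):
            rarefy([5, 3, 2], 11)

    @given(
        st.lists(st.integers(1, 12), min_size=1, max_size=6),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_properties_on_random_stands(self, counts, data):
        N = sum(counts)
        n = data.draw(st.integers(1, N))
        res = rarefy(counts, n)
        assert 1.0 - 1e-12 <= res.expected_species <= len(counts) + 1e-12
        if n < N:
            assert res.expected_species <= rarefy(counts, n + 1).expected_species + 1e-12
        assert rarefy(counts, N).expected_species == pytest.approx(len(counts))
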