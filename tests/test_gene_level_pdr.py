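"""PDRs, marker aggregation, LD weights and re-orientation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metagsa.gene_level_pdr import (
    GeneDirectedStat,
    LdTable,
    MarkerStat,
    MissingLdError,
    averaged_gene_stat,
    best_marker_stat,
    build_pdr_profiles,
    ld_blocks,
    marker_weights,
    pdr,
    reorient_directions,
)


class TestPdr:
    @pytest.mark.parametrize(
        "p,d,expected",
        [(0.05, 1.0, 0.95), (1.0, -1.0, 0.0), (0.2, -0.5, -0.4)],
    )
    def test_direct_evaluation(self, p, d, expected):
        assert pdr(p, d) == pytest.approx(expected)

    @given(p=st.floats(0.0, 1.0), d=st.floats(-1.0, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_and_range(self, p, d):
        value = pdr(p, d)
        assert abs(value) <= 1.0
        assert pdr(p, -d) == pytest.approx(-value)
        if d == 0.0:
            assert value == 0.0

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            pdr(1.2, 1.0)
        with pytest.raises(ValueError):
            pdr(0.5, 1.5)


class TestMarkerWeights:
    def test_fully_redundant_block_counts_once(self):
        ld = LdTable.from_pairs([("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0)])
        v = marker_weights(["a", "b", "c"], ld)
        np.testing.assert_allclose(list(v.values()), [1 / 3] * 3)
        assert sum(v.values()) == pytest.approx(1.0)

    def test_independent_markers_count_separately(self):
        ld = LdTable.from_pairs([("a", "b", 0.0)])
        v = marker_weights(["a", "b"], ld)
        assert v == {"a": 1.0, "b": 1.0}

    def test_half_correlated_block(self):
        ld = LdTable.from_pairs([("a", "b", np.sqrt(0.5))])
        v = marker_weights(["a", "b"], ld)
        assert v["a"] == pytest.approx(1 / 1.5)
        assert sum(v.values()) == pytest.approx(4 / 3)

    def test_sum_equals_block_count_in_block_diagonal_ld(self):
        # two blocks of perfectly correlated markers, no LD across
        ld = LdTable.from_pairs(
            [
                ("m1", "m2", 1.0),
                ("m1", "m3", 0.0),
                ("m1", "m4", 0.0),
                ("m2", "m3", 0.0),
                ("m2", "m4", 0.0),
                ("m3", "m4", -1.0),
            ]
        )
        v = marker_weights(["m1", "m2", "m3", "m4"], ld)
        assert sum(v.values()) == pytest.approx(2.0)
        blocks = ld_blocks(["m1", "m2", "m3", "m4"], ld)
        assert len(set(blocks.values())) == 2

    def test_no_ld_table_every_marker_independent(self):
        assert marker_weights(["x", "y"]) == {"x": 1.0, "y": 1.0}


class TestBestMarkerStat:
    def test_shared_representative_marker(self):
        per_study = {
            "s1": [MarkerStat("m1", 0.01, 0.4), MarkerStat("m2", 0.5, -0.1)],
            "s2": [MarkerStat("m1", 0.03, 0.2), MarkerStat("m2", 0.9, 0.1)],
        }
        out = best_marker_stat(per_study)
        assert out["s1"].p == 0.01 and out["s1"].d == 1.0
        assert out["s2"].marker == "m1"

    def test_linkage_equilibrium_annihilates_pdr(self):
        # selected markers uncorrelated between studies: d = 0 hence PDR = 0
        ld = LdTable.from_pairs([("m1", "m2", 0.0)])
        per_study = {
            "s1": [MarkerStat("m1", 1e-6, 2.0)],
            "s2": [MarkerStat("m2", 1e-6, 2.0)],
        }
        out = best_marker_stat(per_study, ld)
        assert out["s1"].d == 0.0
        assert out["s1"].pdr == 0.0

    def test_cross_study_mean_correlation(self):
        ld = LdTable.from_pairs(
            [("a", "b", 0.8), ("a", "c", 0.4), ("b", "c", 0.9)]
        )
        per_study = {
            "s1": [MarkerStat("a", 0.01, 1.0)],
            "s2": [MarkerStat("b", 0.02, 1.0)],
            "s3": [MarkerStat("c", 0.03, 1.0)],
        }
        out = best_marker_stat(per_study, ld)
        assert out["s1"].d == pytest.approx((0.8 + 0.4) / 2)

    def test_missing_ld_entry_names_pair(self):
        ld = LdTable.from_pairs([("a", "b", 0.8)])
        per_study = {
            "s1": [MarkerStat("a", 0.01, 1.0)],
            "s2": [MarkerStat("b", 0.02, 1.0)],
            "s3": [MarkerStat("c", 0.03, 1.0)],
        }
        with pytest.raises(MissingLdError, match="c"):
            best_marker_stat(per_study, ld)

    def test_p_tie_broken_lexicographically(self):
        per_study = {
            "s1": [MarkerStat("mB", 0.01, 1.0), MarkerStat("mA", 0.01, -1.0)]
        }
        out = best_marker_stat(per_study)
        assert out["s1"].marker == "mA"
        assert out["s1"].d == -1.0


class TestAveragedGeneStat:
    def test_single_marker_reduces_to_marker(self):
        out = averaged_gene_stat([MarkerStat("m", 0.037, -0.2)])
        assert out.p == pytest.approx(0.037, rel=1e-10)
        assert out.d == -1.0

    def test_two_independent_markers_chi2_tail(self):
        # closed-form chi2(4 df) upper tail: exp(-x/2) * (1 + x/2)
        ld = LdTable.from_pairs([("m1", "m2", 0.0)])
        out = averaged_gene_stat(
            [MarkerStat("m1", 0.05, 1.0), MarkerStat("m2", 0.05, 0.5)], ld
        )
        stat = -2 * (np.log(0.05) + np.log(0.05))
        expected = np.exp(-stat / 2) * (1 + stat / 2)
        assert out.p == pytest.approx(expected, rel=1e-10)
        assert out.d == 1.0

    def test_opposite_signs_cancel_direction(self):
        ld = LdTable.from_pairs([("m1", "m2", 0.0)])
        out = averaged_gene_stat(
            [MarkerStat("m1", 0.05, 1.0), MarkerStat("m2", 0.05, -0.5)], ld
        )
        assert out.d == 0.0
        assert out.pdr == 0.0

    def test_promising_filter_empty_is_flagged_null(self):
        out = averaged_gene_stat(
            [MarkerStat("m1", 0.3, 1.0), MarkerStat("m2", 0.6, 1.0)],
            promising_only=True,
        )
        assert out.p == 1.0 and out.d == 0.0 and out.flagged

    def test_promising_filter_keeps_significant_markers(self):
        out = averaged_gene_stat(
            [MarkerStat("m1", 0.01, 1.0), MarkerStat("m2", 0.6, -1.0)],
            promising_only=True,
        )
        assert out.p == pytest.approx(0.01, rel=1e-10)
        assert out.d == 1.0

    def test_strict_df_mode_differs(self):
        markers = [MarkerStat("m1", 0.05, 1.0), MarkerStat("m2", 0.05, 1.0)]
        ld = LdTable.from_pairs([("m1", "m2", 0.0)])
        loose = averaged_gene_stat(markers, ld, df_mode="2sumv")
        strict = averaged_gene_stat(markers, ld, df_mode="sumv")
        assert strict.p < loose.p  # fewer df, same statistic

    def test_agrees_with_best_marker_for_single_marker_genes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            stat = MarkerStat("m", float(rng.uniform()), float(rng.normal()))
            avg = averaged_gene_stat([stat])
            best = best_marker_stat({"s": [stat]})["s"]
            assert avg.p == pytest.approx(best.p, rel=1e-10)
            assert avg.d == best.d


class TestReorientDirections:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1.0, 1.0, -1.0], [1.0, 1.0, -1.0]),  # positive mean: unchanged
            ([-1.0, -1.0, 1.0], [1.0, 1.0, -1.0]),  # negative mean: negated
            ([1.0, -1.0], [1.0, -1.0]),  # zero mean: tie, unchanged
        ],
    )
    def test_negation_rule(self, row, expected):
        out = reorient_directions(np.array([row]))
        np.testing.assert_allclose(out[0], expected)

    @given(
        st.lists(
            st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_idempotent_and_nonnegative_mean(self, rows):
        d = np.array(rows)
        once = reorient_directions(d)
        twice = reorient_directions(once)
        np.testing.assert_array_equal(once, twice)
        assert (once.mean(axis=1) >= 0.0).all() or np.allclose(
            once.mean(axis=1)[once.mean(axis=1) < 0], 0.0, atol=1e-15
        )

    def test_dataframe_round_trip(self):
        df = pd.DataFrame([[-0.5, -0.9], [0.2, 0.3]], index=["g1", "g2"], columns=["s1", "s2"])
        out = reorient_directions(df)
        assert isinstance(out, pd.DataFrame)
        np.testing.assert_allclose(out.loc["g1"], [0.5, 0.9])


class TestBuildPdrProfiles:
    @pytest.fixture
    def universe(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:02d}" for i in range(20)]
        return pd.DataFrame(
            rng.uniform(-1, 1, size=(20, 4)),
            index=genes,
            columns=["s1", "s2", "s3", "s4"],
        )

    def test_shape_and_order(self, universe):
        gs = [f"g{i:02d}" for i in range(10)]
        profile = build_pdr_profiles(universe, list(reversed(gs)))
        assert profile.shape == (10, 4)
        assert list(profile.index) == sorted(gs)

    def test_input_order_invariance(self, universe):
        gs = ["g03", "g07", "g11"]
        a = build_pdr_profiles(universe, gs)
        b = build_pdr_profiles(universe.sample(frac=1, random_state=0), gs)
        pd.testing.assert_frame_equal(a, b)

    def test_absent_gene_dropped_with_warning(self, universe):
        with pytest.warns(UserWarning, match="absent"):
            profile = build_pdr_profiles(universe, ["g01", "g02", "nope"])
        assert list(profile.index) == ["g01", "g02"]

    def test_partial_gene_is_error(self, universe):
        universe.loc["g05", "s2"] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            build_pdr_profiles(universe, ["g04", "g05"])

    def test_all_genes_absent_is_error(self, universe):
        with pytest.raises(ValueError):
            build_pdr_profiles(universe, ["zz1", "zz2"])


class TestGeneDirectedStat:
    def test_pdr_property(self):
        stat = GeneDirectedStat(p=0.1, d=-1.0)
        assert stat.pdr == pytest.approx(-0.9)

    def test_validation(self):
        with pytest.raises(ValueError):
            GeneDirectedStat(p=-0.1, d=0.0)
        with pytest.raises(ValueError):
            GeneDirectedStat(p=0.5, d=2.0)
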