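"""Matrix construction, allelic-state calls, filters and per-SNV profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cellsnv as c
from cellsnv.matrix import AllelicState, FilterSpec, all_profiles, apply_filters

from _oracles import brute_filter, brute_profile
from conftest import matrix_from_columns, random_matrix


class TestBuildMatrix:
    def test_dimensions_and_observed_entries(self):
        k1, k2 = c.SNVKey("1", 10, "A", "G"), c.SNVKey("2", 20, "C", "T")
        table = c.SNVTable([
            c.CellSNVRecord(k1, "BC1", 2, 3),
            c.CellSNVRecord(k1, "BC2", 0, 5),
            c.CellSNVRecord(k2, "BC1", 1, 0),
        ])
        m = c.build_matrix(table, ["BC1", "BC2", "BC3", "BC4"])
        assert m.shape == (4, 2)
        assert m.observed.sum() == 3

    def test_record_outside_universe_dropped(self):
        k = c.SNVKey("1", 10, "A", "G")
        table = c.SNVTable([c.CellSNVRecord(k, "IN", 1, 1), c.CellSNVRecord(k, "OUT", 2, 2)])
        m = c.build_matrix(table, ["IN"])
        assert m.shape == (1, 1) and m.var_counts[0, 0] == 1

    def test_empty_after_restriction_errors(self):
        k = c.SNVKey("1", 10, "A", "G")
        table = c.SNVTable([c.CellSNVRecord(k, "OUT", 1, 1)])
        with pytest.raises(ValueError, match="no records"):
            c.build_matrix(table, ["IN"])


class TestVafAndState:
    @pytest.mark.parametrize("nv,nr,expect", [(5, 5, 0.5), (0, 7, 0.0), (1, 9, 0.1), (4, 0, 1.0)])
    def test_vaf_values(self, nv, nr, expect):
        assert c.vaf(nv, nr) == pytest.approx(expect)

    def test_no_coverage_vaf_undefined_not_zero(self):
        assert math.isnan(c.vaf(0, 0))

    @pytest.mark.parametrize("nv,nr,state", [
        (0, 0, AllelicState.NO_COVERAGE), (0, 4, AllelicState.REF_ONLY),
        (3, 0, AllelicState.VAR_ONLY), (2, 8, AllelicState.BIALLELIC),
    ])
    def test_states(self, nv, nr, state):
        assert c.classify_allelic_state(nv, nr) is state

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            c.vaf(-1, 2)
        with pytest.raises(ValueError):
            c.classify_allelic_state(1, -2)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_vaf_state_law(self, nv, nr):
        """VAF defined iff covered; var_only <=> VAF 1; ref_only <=> VAF 0."""
        v = c.vaf(nv, nr)
        state = c.classify_allelic_state(nv, nr)
        assert math.isnan(v) == (state is AllelicState.NO_COVERAGE)
        if not math.isnan(v):
            assert 0.0 <= v <= 1.0
            assert (state is AllelicState.VAR_ONLY) == (v == 1.0 and nv >= 1)
            assert (state is AllelicState.REF_ONLY) == (v == 0.0 and nr >= 1)


class TestFilters:
    def support_matrix(self):
        # five SNVs observed in {25, 19, 3, 40, 20} of 45 cells
        supports = [25, 19, 3, 40, 20]
        cols = [[(1, 1) if i < s else (0, 0) for i in range(45)] for s in supports]
        return matrix_from_columns(cols), supports

    def test_min_cells_threshold_excludes_fewer_than(self):
        m, supports = self.support_matrix()
        out, report = apply_filters(m, FilterSpec(min_cells_per_snv=20))
        kept_supports = sorted(out.observed.sum(axis=0).tolist())
        assert kept_supports == [20, 25, 40]  # "fewer than 20 cells" excluded, 20 kept
        assert report.n_snvs_removed_by_cell_count == 2

    def test_depth_filter_unobserves_shallow_entries(self):
        m = matrix_from_columns([[(1, 1), (2, 2), (0, 0)]])
        out, report = apply_filters(m, FilterSpec(min_depth=3))
        assert not out.observed[0, 0]  # depth 2 < 3
        assert out.var_counts[0, 0] == 0 and out.ref_counts[0, 0] == 0
        assert out.observed[1, 0]
        assert report.n_entries_removed_by_depth == 1

    def test_identity_filter(self):
        m, _ = self.support_matrix()
        out, _ = apply_filters(m, FilterSpec(0, 0))
        assert out.snvs == m.snvs
        np.testing.assert_array_equal(out.var_counts, m.var_counts)

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = random_matrix(rng)
            spec = FilterSpec(min_cells_per_snv=int(rng.integers(0, 5)), min_depth=int(rng.integers(0, 4)))
            once, _ = apply_filters(m, spec)
            twice, report2 = apply_filters(once, spec)
            assert once.snvs == twice.snvs
            np.testing.assert_array_equal(once.observed, twice.observed)
            assert report2.n_entries_removed_by_depth == 0
            assert once.observed.sum() <= m.observed.sum()  # monotone

    def test_filter_everything_yields_empty_matrix(self):
        m = matrix_from_columns([[(1, 1), (0, 0)]])
        out, report = apply_filters(m, FilterSpec(min_cells_per_snv=10))
        assert out.shape == (2, 0)
        assert report.n_snvs_removed_by_cell_count == 1


class TestProfiles:
    def test_hand_tally(self):
        m = matrix_from_columns([[(0, 2), (3, 0), (1, 1), (0, 0), (0, 0)]])
        p = c.per_snv_profile(m, m.snvs[0])
        assert (p.n_cells_covered, p.n_ref_only, p.n_var_only, p.n_biallelic) == (3, 1, 1, 1)
        assert sorted(p.vaf_values.tolist()) == [0.0, 0.5, 1.0]
        assert p.median_vaf_covered == 0.5
        assert p.n_cells_covered == p.n_ref_only + p.n_var_only + p.n_biallelic

    def test_fully_unobserved_column(self):
        m = matrix_from_columns([[(1, 1)], [(0, 0)]])
        p = c.per_snv_profile(m, m.snvs[1])
        assert p.n_cells_covered == 0
        assert math.isnan(p.median_vaf_covered) and math.isnan(p.median_nvar_expressing)

    def test_single_var_only_entry(self):
        m = matrix_from_columns([[(4, 0), (0, 0)]])
        p = c.per_snv_profile(m, m.snvs[0])
        assert p.n_var_only == 1 and p.median_vaf_covered == 1.0

    def test_unknown_snv_lookup_error(self):
        m = matrix_from_columns([[(1, 1)]])
        with pytest.raises(KeyError):
            c.per_snv_profile(m, c.SNVKey("9", 9, "A", "C"))

    def test_state_tallies_sum_to_observed_entries(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = random_matrix(rng)
            total = sum(p.n_cells_covered for p in all_profiles(m))
            assert total == int(m.observed.sum())


class TestOracleEquivalence:
    def test_profiles_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_matrix(rng)
            for snv in m.snvs:
                got = c.per_snv_profile(m, snv)
                exp = brute_profile(m, snv)
                assert got.n_cells_covered == exp["n_cells_covered"]
                assert got.n_ref_only == exp["n_ref_only"]
                assert got.n_var_only == exp["n_var_only"]
                assert got.n_biallelic == exp["n_biallelic"]
                np.testing.assert_allclose(got.vaf_values, exp["vaf_values"], atol=1e-12)

    def test_filters_match_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = random_matrix(rng)
            depth, cells = int(rng.integers(0, 5)), int(rng.integers(0, 6))
            out, _ = apply_filters(m, FilterSpec(min_cells_per_snv=cells, min_depth=depth))
            kept, observed = brute_filter(m, depth, cells)
            assert out.snvs == [m.snvs[j] for j in kept]
            exp_obs = np.array(observed)[:, kept]
            np.testing.assert_array_equal(out.observed, exp_obs)
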