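"""Coding, filtering, partitioning and risk-index design construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bvsri import (
    GenotypeMatrix,
    PhenotypeVector,
    build_risk_design,
    compute_maf,
    filter_data,
    log_transform,
    partition_by_maf,
)
from bvsri.variant_data import DataError


class TestComputeMaf:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 1, 2, 0], 0.375),
            ([2, 2, 2, 2], 0.0),  # monomorphic in the coded allele -> folded
            ([0, 0, 0, 0], 0.0),
            ([1, 1, 1, 1], 0.5),
        ],
    )
    def test_direct_counts(self, column, expected):
        assert compute_maf(np.array(column, dtype=float)) == pytest.approx(expected)

    def test_missing_entries_excluded(self):
        col = np.array([0.0, 1.0, 2.0, 0.0])
        miss = np.array([False, False, False, True])
        assert compute_maf(col, miss) == pytest.approx(0.5)

    def test_all_missing_is_an_error(self):
        with pytest.raises(DataError):
            compute_maf(np.array([0.0, 1.0]), np.array([True, True]))

    @given(st.permutations(list(range(8))))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_individual_order(self, perm):
        col = np.array([0, 0, 1, 2, 0, 1, 0, 2], dtype=float)
        assert compute_maf(col[perm]) == compute_maf(col)


class TestMinorOrientation:
    def test_major_coded_column_is_recoded(self):
        gm = GenotypeMatrix(
            values=np.array([[2, 0], [2, 1], [1, 0], [2, 0]], dtype=float),
            variant_ids=["1_1", "1_2"],
            positions=np.array([1, 2]),
        )
        # column 0 had coded-allele frequency 7/8 -> recoded to 2 - x
        np.testing.assert_array_equal(gm.values[:, 0], [0, 0, 1, 0])
        assert gm.maf[0] == pytest.approx(1 / 8)


class TestFilterData:
    def test_singleton_variant_dropped(self):
        gm = GenotypeMatrix(
            values=np.array([[0, 1, 0], [1, 0, 0], [1, 1, 0], [0, 0, 1]], dtype=float),
            variant_ids=["1_1", "1_2", "1_3"],
            positions=np.arange(3),
        )
        ph = PhenotypeVector(values=np.arange(4.0), sample_ids=gm.sample_ids)
        out, _, report = filter_data(gm, ph, min_minor_allele_count=1)
        assert report.removed_variants == ["1_3"]
        assert out.p == 2

    def test_individual_with_missing_genotype_dropped_before_mac_recount(self):
        # variant 2 has MAC 2 only because of the to-be-dropped individual
        miss = np.zeros((4, 2), dtype=bool)
        miss[1, 0] = True
        gm = GenotypeMatrix(
            values=np.array([[0, 1], [0, 1], [1, 0], [1, 0]], dtype=float),
            variant_ids=["1_1", "1_2"],
            positions=np.arange(2),
            missing_mask=miss,
        )
        ph = PhenotypeVector(values=np.arange(4.0), sample_ids=gm.sample_ids)
        out, out_ph, report = filter_data(gm, ph)
        assert report.removed_individuals == [gm.sample_ids[1]]
        assert report.removed_variants == ["1_2"]  # singleton after row removal
        assert out.n == out_ph.n == 3

    def test_clean_data_passes_through_and_is_idempotent(self, tiny_genotypes):
        ph = PhenotypeVector(
            values=np.arange(4.0), sample_ids=tiny_genotypes.sample_ids
        )
        g1, p1, rep = filter_data(tiny_genotypes, ph)
        assert rep.n_individuals_removed == rep.n_variants_removed == 0
        np.testing.assert_array_equal(g1.values, tiny_genotypes.values)
        g2, p2, rep2 = filter_data(g1, p1)
        np.testing.assert_array_equal(g2.values, g1.values)
        np.testing.assert_array_equal(p2.values, p1.values)
        assert rep2.n_individuals_removed == rep2.n_variants_removed == 0

    def test_missing_phenotype_drops_individual(self, tiny_genotypes):
        ph = PhenotypeVector(
            values=np.array([1.0, np.nan, 3.0, 4.0]),
            sample_ids=tiny_genotypes.sample_ids,
        )
        out, out_ph, report = filter_data(tiny_genotypes, ph)
        assert report.removed_individuals == [tiny_genotypes.sample_ids[1]]
        assert np.isfinite(out_ph.values).all()

    def test_everything_filtered_is_an_error(self):
        gm = GenotypeMatrix(
            values=np.array([[0.0], [1.0]]),
            variant_ids=["1_1"],
            positions=np.array([1]),
        )
        ph = PhenotypeVector(values=np.array([1.0, 2.0]))
        with pytest.raises(DataError):
            filter_data(gm, ph)  # lone variant is a singleton


class TestLogTransform:
    def test_known_values(self):
        ph = PhenotypeVector(values=np.array([1.0, np.e, np.e**2]))
        out = log_transform(ph)
        np.testing.assert_allclose(out.values, [0.0, 1.0, 2.0])
        assert out.transform_applied

    def test_blood_pressure_style_values(self):
        out = log_transform(PhenotypeVector(values=np.array([120.0, 80.0])))
        np.testing.assert_allclose(out.values, [np.log(120), np.log(80)])

    def test_nonpositive_value_errors_naming_individual(self):
        ph = PhenotypeVector(values=np.array([0.0, 1.0]), sample_ids=["A", "B"])
        with pytest.raises(DataError, match="A"):
            log_transform(ph)


def _matrix_with_mafs():
    """40 individuals; observed MAFs 0.35, 0.025, 0.025 (common, rare, rare)."""
    vals = np.zeros((40, 3))
    vals[:28, 0] = 1  # 28/80 = 0.35
    vals[0, 1] = 2  # 2/80 = 0.025
    vals[5:7, 2] = 1
    return GenotypeMatrix(
        values=vals, variant_ids=["3_10", "3_20", "3_30"], positions=np.array([10, 20, 30])
    )


class TestPartitionByMaf:
    def test_common_singleton_and_pooled_rare_group(self):
        gm = _matrix_with_mafs()
        grouping = partition_by_maf(gm, 0.05)
        assert grouping.n_groups == 2
        # the common variant sits alone; the two rare variants share a group
        assert grouping.group_of[0] != grouping.group_of[1]
        assert grouping.group_of[1] == grouping.group_of[2]
        assert sorted(grouping.group_sizes.tolist()) == [1, 2]

    def test_threshold_half_pools_everything(self):
        gm = _matrix_with_mafs()
        grouping = partition_by_maf(gm, 0.5)
        assert grouping.n_groups == 1
        assert grouping.group_sizes.tolist() == [3]

    def test_tiny_threshold_gives_all_singletons(self):
        gm = _matrix_with_mafs()
        grouping = partition_by_maf(gm, 1e-6)
        assert grouping.n_groups == 3
        assert (grouping.group_sizes == 1).all()

    def test_sizes_always_sum_to_p(self):
        gm = _matrix_with_mafs()
        for t in (0.01, 0.03, 0.05, 0.2, 0.5):
            assert partition_by_maf(gm, t).group_sizes.sum() == gm.p

    @given(st.tuples(st.floats(0.005, 0.5), st.floats(0.005, 0.5)))
    @settings(deadline=None, max_examples=30)
    def test_raising_threshold_only_moves_common_to_rare(self, pair):
        t_low, t_high = sorted(pair)
        gm = _matrix_with_mafs()

        def common_set(t):
            grouping = partition_by_maf(gm, t)
            out = {j for j in range(gm.p) if gm.maf[j] >= t}
            for j in out:  # every common variant must sit in its own group
                assert grouping.group_sizes[grouping.group_of[j]] == 1
            return out

        assert common_set(t_high) <= common_set(t_low)

    def test_bad_threshold_rejected(self):
        gm = _matrix_with_mafs()
        with pytest.raises(DataError):
            partition_by_maf(gm, 0.0)


class TestBuildRiskDesign:
    @pytest.fixture
    def rare_pair(self):
        from bvsri import VariantGrouping

        gm = GenotypeMatrix(
            values=np.array([[1, 0], [0, 2], [1, 1]], dtype=float),
            variant_ids=["1_1", "1_2"],
            positions=np.array([1, 2]),
        )
        grouping = VariantGrouping(  # both variants pooled in one rare group
            threshold=0.5,
            group_of=np.array([0, 0]),
            group_sizes=np.array([2]),
            members=[np.array([0, 1])],
        )
        return gm, grouping

    def test_group_burden_is_row_sum_of_included_columns(self, rare_pair):
        gm, grouping = rare_pair
        design, active = build_risk_design(gm, grouping, np.array([1, 1]))
        np.testing.assert_array_equal(design[:, 0], [1, 2, 2])
        assert active == [0]

    def test_single_inclusion_copies_the_column(self, rare_pair):
        gm, grouping = rare_pair
        design, _ = build_risk_design(gm, grouping, np.array([1, 0]))
        np.testing.assert_array_equal(design[:, 0], [1, 0, 1])

    def test_empty_model_has_zero_columns(self, rare_pair):
        gm, grouping = rare_pair
        design, active = build_risk_design(gm, grouping, np.zeros(2, dtype=int))
        assert design.shape == (3, 0)
        assert active == []

    def test_additive_in_gamma_for_disjoint_supports(self, small_study):
        gm, _, grouping = small_study
        rng = np.random.default_rng(0)
        g_a = np.zeros(gm.p, dtype=int)
        g_b = np.zeros(gm.p, dtype=int)
        idx = rng.permutation(gm.p)
        g_a[idx[:3]] = 1
        g_b[idx[3:6]] = 1
        d_ab, _ = build_risk_design(gm, grouping, g_a + g_b)
        d_a, act_a = build_risk_design(gm, grouping, g_a)
        d_b, act_b = build_risk_design(gm, grouping, g_b)
        # compare group-wise sums via full per-group expansion
        full = np.zeros((gm.n, grouping.n_groups))
        for d, act in ((d_a, act_a), (d_b, act_b)):
            for col, g in enumerate(act):
                full[:, g] += d[:, col]
        d_ab_full = np.zeros_like(full)
        _, act_ab = build_risk_design(gm, grouping, g_a + g_b)
        for col, g in enumerate(act_ab):
            d_ab_full[:, g] = d_ab[:, col]
        np.testing.assert_allclose(d_ab_full, full)

    def test_wrong_gamma_length_rejected(self, rare_pair):
        gm, grouping = rare_pair
        with pytest.raises(DataError):
            build_risk_design(gm, grouping, np.array([1, 0, 1]))
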