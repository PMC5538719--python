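"""Correlation coefficients, partial correlation, and matrix builders."""

import numpy as np
import pytest

from braingraph.cohort import Cohort, Subject
from braingraph.connectivity import (
    AssociationSpec,
    association_matrix,
    build_group_matrix,
    build_subject_matrix,
    correlate,
    load_matrix,
    partial_correlate,
    save_matrix,
)
from braingraph.exceptions import ConfigError, UndefinedCorrelationError, ValidationError
from braingraph.synthetic import synthetic_atlas

from oracles import pairwise_corr_matrix


class TestCorrelate:
    def test_perfect_linearity_pearson(self):
        assert correlate([1, 2, 3], [2, 4, 6], "pearson") == pytest.approx(1.0)

    def test_monotone_map_spearman(self):
        assert correlate([1, 2, 3], [1, 4, 9], "spearman") == pytest.approx(1.0)

    def test_kendall_matches_pair_enumeration(self):
        # all 3 pairs of (1,2,3) vs (3,1,2): concordant 1, discordant 2 -> -1/3
        assert correlate([1, 2, 3], [3, 1, 2], "kendall") == pytest.approx(-1 / 3)

    def test_kendall_is_tie_corrected_tau_b(self):
        # with ties, tau-b denominator shrinks; compare against direct formula
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        con = dis = 0
        for i in range(4):
            for j in range(i + 1, 4):
                s = (x[i] - x[j]) * (y[i] - y[j])
                con += s > 0
                dis += s < 0
        n0 = 6
        n1 = 1  # one tied x pair
        expected = (con - dis) / np.sqrt((n0 - n1) * n0)
        assert correlate(x, y, "kendall") == pytest.approx(expected)

    def test_zero_variance_is_error(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelate:
    def test_copies_of_control_are_undefined(self, rng):
        z = rng.standard_normal(20)
        with pytest.raises(UndefinedCorrelationError):
            partial_correlate(z, z, z[:, None])

    def test_shared_component_removed(self, rng):
        n = 2000
        z = rng.standard_normal(n)
        x = z + 0.5 * rng.standard_normal(n)
        y = z + 0.5 * rng.standard_normal(n)
        raw = correlate(x, y)
        partial = partial_correlate(x, y, z[:, None])
        assert abs(partial) < 0.1 < raw
        # oracle: correlate the explicit OLS residuals
        X = np.column_stack([np.ones(n), z])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert partial == pytest.approx(correlate(rx, ry), abs=1e-10)

    def test_empty_controls_reduce_to_plain_correlation(self, rng):
        x, y = rng.standard_normal((2, 30))
        assert partial_correlate(x, y, None) == pytest.approx(correlate(x, y))


class TestMatrixBuilders:
    def _structural(self, X, atlas):
        subs = [Subject(id=f"s{i}", data=X[i]) for i in range(X.shape[0])]
        return Cohort(atlas=atlas, mode="structural", groups={"G": subs})

    def test_perfectly_related_regions_give_all_ones(self):
        atlas = synthetic_atlas(3)
        base = np.array([1.0, 2.0, 3.0, 5.0])
        X = np.column_stack([base, 2 * base, base - 7])
        m = build_group_matrix(self._structural(X, atlas), "G", AssociationSpec("pearson", "keep"))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(m.values[off], 1.0)
        assert np.all(np.diag(m.values) == 0)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_group_matrix_matches_pairwise_loop_oracle(self, rng, method):
        atlas = synthetic_atlas(5)
        X = rng.standard_normal((12, 5))
        m = build_group_matrix(self._structural(X, atlas), "G", AssociationSpec(method, "keep"))
        expected = pairwise_corr_matrix(X, lambda a, b: correlate(a, b, method))
        np.testing.assert_allclose(m.values, expected, atol=1e-12)

    def test_partial_matrix_matches_residual_oracle(self, rng):
        atlas = synthetic_atlas(4)
        X = rng.standard_normal((30, 4))
        m = build_group_matrix(
            self._structural(X, atlas), "G", AssociationSpec("partial_pearson", "keep")
        )
        # oracle: for each pair, partial correlation controlling the other regions
        def partial_jk(a, b):
            ja = [i for i in range(4) if not np.array_equal(X[:, i], a) and not np.array_equal(X[:, i], b)]
            return partial_correlate(a, b, X[:, ja])

        expected = pairwise_corr_matrix(X, partial_jk)
        np.testing.assert_allclose(m.values, expected, atol=1e-9)

    def test_negative_rule_zero(self, rng):
        atlas = synthetic_atlas(4)
        X = rng.standard_normal((15, 4))
        keep = build_group_matrix(self._structural(X, atlas), "G", AssociationSpec("pearson", "keep"))
        zero = build_group_matrix(self._structural(X, atlas), "G", AssociationSpec("pearson", "zero"))
        assert np.any(keep.values < 0), "fixture should produce some negative correlation"
        np.testing.assert_array_equal(zero.values, np.where(keep.values < 0, 0.0, keep.values))

    def test_constant_region_error_names_region(self):
        atlas = synthetic_atlas(3)
        X = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(UndefinedCorrelationError, match="r1"):
            build_group_matrix(self._structural(X, atlas), "G", AssociationSpec())

    def test_subject_matrix_identical_series_and_abs_rule(self, rng):
        atlas = synthetic_atlas(3)
        base = rng.standard_normal(20)
        ts = np.column_stack([base, base, base])
        subj = Subject(id="s1", data=ts)
        m = build_subject_matrix(subj, atlas, AssociationSpec("pearson", "keep"))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(m.values[off], 1.0)
        # abs rule turns negatives positive
        ts2 = np.column_stack([base, -base + 0.1 * rng.standard_normal(20), base * 0.5 + rng.standard_normal(20)])
        keep = build_subject_matrix(Subject(id="s2", data=ts2), atlas, AssociationSpec("pearson", "keep"))
        ab = build_subject_matrix(Subject(id="s2", data=ts2), atlas, AssociationSpec("pearson", "abs"))
        np.testing.assert_allclose(ab.values, np.abs(keep.values), atol=1e-12)

    def test_subject_matrix_matches_pairwise_oracle(self, rng):
        atlas = synthetic_atlas(5)
        ts = rng.standard_normal((20, 5))
        m = build_subject_matrix(Subject(id="s", data=ts), atlas, AssociationSpec("pearson", "keep"))
        expected = pairwise_corr_matrix(ts, lambda a, b: correlate(a, b, "pearson"))
        np.testing.assert_allclose(m.values, expected, atol=1e-12)

    def test_output_symmetric_zero_diagonal_bounded(self, rng):
        atlas = synthetic_atlas(6)
        X = rng.standard_normal((10, 6))
        for rule, lo in (("keep", -1.0), ("abs", 0.0), ("zero", 0.0)):
            m = build_group_matrix(self._structural(X, atlas), "G", AssociationSpec("pearson", rule))
            np.testing.assert_array_equal(m.values, m.values.T)
            assert np.all(np.diag(m.values) == 0)
            assert m.values.min() >= lo and m.values.max() <= 1.0

    def test_subject_permutation_invariance(self, rng):
        atlas = synthetic_atlas(4)
        X = rng.standard_normal((9, 4))
        perm = rng.permutation(9)
        a = association_matrix(X, AssociationSpec("pearson", "keep"))
        b = association_matrix(X[perm], AssociationSpec("pearson", "keep"))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_stransform_rejected(self):
        with pytest.raises(ConfigError, match="s-transform"):
            AssociationSpec("pearson", "stransform")

    def test_matrix_csv_round_trip(self, rng, tmp_path):
        atlas = synthetic_atlas(4)
        X = rng.standard_normal((10, 4))
        m = build_group_matrix(self._structural(X, atlas), "G", AssociationSpec())
        back = load_matrix(save_matrix(m, tmp_path / "m.csv"), atlas)
        np.testing.assert_allclose(back.values, m.values, atol=1e-15)
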