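"""Correlation construction, cone geometry, and the two proximity measures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fcgeo as fg
from fcgeo.core import NotPositiveDefiniteError

from conftest import make_correlation, make_spd


def _ts(data, pid="p0"):
    return fg.ROITimeSeries(np.asarray(data, dtype=float), participant_id=pid)


# ------------------------------------------------------------- correlation


class TestCorrelationFromTimeseries:
    def test_perfectly_correlated_columns(self, rng):
        x = rng.standard_normal(40)
        q = fg.correlation_from_timeseries(_ts(np.column_stack([x, x])))
        assert q.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_columns(self, rng):
        x = rng.standard_normal(40)
        q = fg.correlation_from_timeseries(_ts(np.column_stack([x, -x])))
        assert q.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_diagonal_is_exactly_one(self, rng):
        q = fg.correlation_from_timeseries(_ts(rng.standard_normal((30, 6))))
        assert np.all(q.values.diagonal() == 1.0)
        assert q.regularization_tau == 0.0

    def test_zero_variance_column_names_roi(self, rng):
        data = rng.standard_normal((20, 4))
        data[:, 2] = 3.14
        with pytest.raises(ValueError, match="ROI column 2"):
            fg.correlation_from_timeseries(_ts(data))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            _ts(np.ones((1, 3)))

    def test_quadratic_form_nonnegative(self, rng):
        # y'Qy >= 0 for sample correlations: the defining PSD property
        q = fg.correlation_from_timeseries(_ts(rng.standard_normal((25, 10)))).values
        y = rng.standard_normal((100, 10))
        assert np.all(np.einsum("ij,jk,ik->i", y, q, y) >= -1e-10)

    def test_cone_closure_positive_combinations(self, rng):
        q1 = fg.correlation_from_timeseries(_ts(rng.standard_normal((30, 5)))).values
        q2 = fg.correlation_from_timeseries(_ts(rng.standard_normal((30, 5)))).values
        for alpha, beta in [(0.5, 2.0), (3.0, 0.1), (1.0, 1.0)]:
            fg.FCMatrix(values=alpha * q1 + beta * q2)  # validation enforces PSD


# ------------------------------------------------------------- geodesic distance


class TestGeodesicDistance:
    def test_self_distance_zero(self, rng):
        q = make_correlation(rng, 8)
        assert fg.geodesic_distance(q, q) <= 1e-8

    def test_diagonal_closed_form_2x2(self):
        # identity vs diag(e^2, 1): sqrt(log^2 e^2 + log^2 1) = 2
        d = fg.geodesic_distance(np.eye(2), np.diag([np.e**2, 1.0]))
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_diagonal_closed_form_general(self, rng):
        d1 = np.diag(rng.uniform(0.2, 3.0, size=6))
        d2 = np.diag(rng.uniform(0.2, 3.0, size=6))
        expected = np.sqrt(np.sum(np.log(np.diag(d2) / np.diag(d1)) ** 2))
        assert fg.geodesic_distance(d1, d2) == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance_under_congruence(self, rng):
        q1, q2 = make_spd(rng, 7), make_spd(rng, 7)
        a = rng.standard_normal((7, 7))
        assert abs(np.linalg.det(a)) > 1e-6
        d_orig = fg.geodesic_distance(q1, q2)
        d_cong = fg.geodesic_distance(a @ q1 @ a.T, a @ q2 @ a.T)
        assert d_cong == pytest.approx(d_orig, abs=1e-6)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 21))
            qa, qb, qc = (make_spd(rng, n) for _ in range(3))
            dab = fg.geodesic_distance(qa, qb)
            dba = fg.geodesic_distance(qb, qa)
            dbc = fg.geodesic_distance(qb, qc)
            dac = fg.geodesic_distance(qa, qc)
            assert dab >= 0
            assert fg.geodesic_distance(qa, qa) <= 1e-8
            assert abs(dab - dba) <= 1e-8
            assert dac <= dab + dbc + 1e-8

    def test_rank_deficient_input_instructs_to_regularize(self, rng):
        # T < R sample correlation is singular
        q = fg.correlation_from_timeseries(_ts(rng.standard_normal((4, 8)))).values
        with pytest.raises(NotPositiveDefiniteError, match="regularize"):
            fg.geodesic_distance(q, np.eye(8))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fg.geodesic_distance(np.eye(3), np.eye(4))


# ------------------------------------------------------------- Pearson dissimilarity


def _corr_oracle(x, y):
    """Scalar Pearson correlation written out as explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = (
        sum((xi - mx) ** 2 for xi in x) ** 0.5
        * sum((yi - my) ** 2 for yi in y) ** 0.5
    )
    return num / den


def _corr2x2(r):
    return np.array([[1.0, r], [r, 1.0]])


def _corr3x3(r01, r02, r12):
    return np.array([[1.0, r01, r02], [r01, 1.0, r12], [r02, r12, 1.0]])


class TestPearsonDissimilarity:
    def test_self_dissimilarity_zero(self, rng):
        q = make_correlation(rng, 5)
        assert fg.pearson_dissimilarity(q, q) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("r1,r2", [(0.9, -0.5), (0.1, 0.8), (-0.7, 0.3)])
    def test_two_by_two_degeneracy(self, r1, r2):
        # both centered stacked 4-vectors are positive multiples of
        # (1,-1,-1,1), so any two distinct 2x2 correlation matrices have
        # dissimilarity 0 while their geodesic distance is positive
        q1, q2 = _corr2x2(r1), _corr2x2(r2)
        assert fg.pearson_dissimilarity(q1, q2) == pytest.approx(0.0, abs=1e-12)
        assert fg.geodesic_distance(q1, q2) > 1e-3

    def test_three_by_three_against_scalar_oracle(self):
        q1 = _corr3x3(0.5, 0.2, 0.1)
        q2 = _corr3x3(0.1, 0.4, 0.3)
        v1 = [q1[i, j] for j in range(3) for i in range(3)]  # stacked columns
        v2 = [q2[i, j] for j in range(3) for i in range(3)]
        expected = (1.0 - _corr_oracle(v1, v2)) / 2.0
        assert fg.pearson_dissimilarity(q1, q2) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        d = fg.pearson_dissimilarity(make_correlation(r, 4), make_correlation(r, 4))
        assert 0.0 <= d <= 1.0

    def test_invariant_to_common_additive_shift(self, rng):
        # mean removal inside the correlation makes a constant offset of
        # both matrices (with re-correlation) a no-op
        q1, q2 = make_spd(rng, 5), make_spd(rng, 5)
        base = fg.pearson_dissimilarity(q1, q2)
        shifted = fg.pearson_dissimilarity(q1 + 3.7, q2 + 3.7)
        assert shifted == pytest.approx(base, abs=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fg.pearson_dissimilarity(np.ones((3, 3)), np.eye(3))

    def test_offdiagonal_only_variant_differs(self, rng):
        q1, q2 = make_correlation(rng, 4), make_correlation(rng, 4)
        full = fg.pearson_dissimilarity(q1, q2, include_diagonal=True)
        off = fg.pearson_dissimilarity(q1, q2, include_diagonal=False)
        assert full != pytest.approx(off, abs=1e-12)


# ------------------------------------------------------------- regularization


def _db_from_runs(rng, n_mats, t, r):
    series = [
        fg.ROITimeSeries(rng.standard_normal((t, r)), participant_id=f"s{i}")
        for i in range(n_mats)
    ]
    return fg.FCDatabase.from_timeseries(series)


class TestRegularizeDatabase:
    def test_full_rank_database_unchanged(self, rng):
        db = _db_from_runs(rng, 4, 100, 6)
        (out,) = fg.regularize_database([db], tau=1.0)
        assert out is db
        assert all(m.regularization_tau == 0.0 for m in out.matrices)

    def test_eigenvalue_shift_is_exactly_tau(self, rng):
        db = _db_from_runs(rng, 3, 5, 10)  # T < R: rank deficient
        before = [np.linalg.eigvalsh(m.values) for m in db.matrices]
        (out,) = fg.regularize_database([db], tau=1.0)
        for m, w0 in zip(out.matrices, before):
            assert m.regularization_tau == 1.0
            np.testing.assert_allclose(np.linalg.eigvalsh(m.values), w0 + 1.0, atol=1e-10)

    def test_one_bad_matrix_regularizes_all_databases(self, rng):
        good = _db_from_runs(rng, 3, 100, 6)
        bad = _db_from_runs(rng, 3, 4, 6)
        out_good, out_bad = fg.regularize_database([good, bad], tau=0.5)
        assert all(m.regularization_tau == 0.5 for m in out_good.matrices)
        assert all(m.regularization_tau == 0.5 for m in out_bad.matrices)

    def test_regularized_geodesic_is_a_metric(self, rng):
        # 10 rank-deficient matrices; exhaustive triple check after tau*I
        db = _db_from_runs(rng, 10, 8, 12)
        (db,) = fg.regularize_database([db], tau=1.0)
        d = fg.pairwise_distances(train=db, test=db, measure="geodesic").values
        np.testing.assert_allclose(d, d.T, atol=1e-8)
        assert np.all(np.abs(np.diag(d)) <= 1e-8)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-8

    def test_invalid_tau_rejected(self, rng):
        db = _db_from_runs(rng, 2, 50, 4)
        with pytest.raises(ValueError):
            fg.regularize_database([db], tau=0.0)


# ------------------------------------------------------------- pairwise distances


class TestPairwiseDistances:
    @pytest.mark.parametrize("measure", ["geodesic", "pearson"])
    def test_entries_match_looped_single_pair_calls(self, rng, measure):
        train = _db_from_runs(rng, 5, 60, 6)
        test = _db_from_runs(rng, 5, 60, 6)
        dm = fg.pairwise_distances(train=train, test=test, measure=measure)
        single = fg.geodesic_distance if measure == "geodesic" else fg.pearson_dissimilarity
        for i, mt in enumerate(test.matrices):
            for j, mr in enumerate(train.matrices):
                assert dm.values[i, j] == pytest.approx(single(mt, mr), abs=1e-10)

    def test_self_comparison_symmetric_zero_diagonal(self, rng):
        db = _db_from_runs(rng, 6, 80, 5)
        dm = fg.pairwise_distances(train=db, test=db, measure="geodesic")
        np.testing.assert_array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_single_item_databases(self, rng):
        a = _db_from_runs(rng, 1, 60, 4)
        b = _db_from_runs(rng, 1, 60, 4)
        dm = fg.pairwise_distances(train=a, test=b, measure="pearson")
        assert dm.shape == (1, 1)
        assert dm.values[0, 0] == pytest.approx(
            fg.pearson_dissimilarity(b.matrices[0], a.matrices[0]), abs=1e-12
        )

    def test_pearson_entries_within_unit_interval(self, rng):
        train = _db_from_runs(rng, 4, 50, 5)
        test = _db_from_runs(rng, 3, 50, 5)
        dm = fg.pairwise_distances(train=train, test=test, measure="pearson")
        assert dm.values.min() >= 0.0 and dm.values.max() <= 1.0

    def test_singular_input_raises_with_guidance(self, rng):
        db = _db_from_runs(rng, 3, 4, 6)
        with pytest.raises(NotPositiveDefiniteError, match="regularize"):
            fg.pairwise_distances(train=db, test=db, measure="geodesic")
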