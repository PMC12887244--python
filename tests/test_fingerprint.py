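"""Identifiability matrix and fingerprint statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spineprint as sp
from spineprint.connectivity import FCVector, edge_index_for
from spineprint.fingerprint import FingerprintError, format_percent


def _vec(values, subject="s", run=1, n=3):
    parc = sp.build_brain_parcellation(n_cortical=n, n_subcortical=0)
    return FCVector(np.asarray(values, float), edge_index_for(n), parc, subject, run)


def random_I(rng, ns):
    return rng.uniform(-1, 1, size=(ns, ns))


class TestIdentifiabilityMatrix:
    def test_identical_runs_give_unit_diagonal(self, rng):
        vecs = [_vec(rng.normal(size=3), subject=f"s{i}") for i in range(4)]
        I = sp.identifiability_matrix(vecs, vecs)
        assert np.allclose(np.diag(I), 1.0)

    def test_hand_computed_two_subject_case(self):
        a1, b1 = _vec([1.0, 2.0, 3.0]), _vec([1.0, 0.0, 1.0])
        a2, b2 = _vec([2.0, 4.0, 6.0]), _vec([3.0, 1.0, 2.0])
        I = sp.identifiability_matrix([a1, b1], [a2, b2])
        def pearson(x, y):
            x, y = np.asarray(x, float), np.asarray(y, float)
            x, y = x - x.mean(), y - y.mean()
            return (x @ y) / np.sqrt((x @ x) * (y @ y))
        expected = [[pearson([1, 2, 3], [2, 4, 6]), pearson([1, 2, 3], [3, 1, 2])],
                    [pearson([1, 0, 1], [2, 4, 6]), pearson([1, 0, 1], [3, 1, 2])]]
        assert np.allclose(I, expected, atol=1e-12)

    def test_subject_permutation_equivariance(self, rng):
        v1 = [_vec(rng.normal(size=6), n=4) for _ in range(5)]
        v2 = [_vec(rng.normal(size=6), n=4) for _ in range(5)]
        I = sp.identifiability_matrix(v1, v2)
        perm = [3, 1, 4, 0, 2]
        I_perm = sp.identifiability_matrix([v1[p] for p in perm],
                                           [v2[p] for p in perm])
        assert np.allclose(I_perm, I[np.ix_(perm, perm)])

    def test_mismatched_edges_rejected(self, rng):
        v3 = [_vec(rng.normal(size=3)) for _ in range(2)]
        v4 = [_vec(rng.normal(size=6), n=4) for _ in range(2)]
        with pytest.raises(FingerprintError, match="edge"):
            sp.identifiability_matrix(v3, v4)


class TestIdiffAndCohensD:
    def test_identity_and_constant_matrices(self):
        assert sp.idiff(np.eye(4)) == (1.0, 0.0, 1.0)
        assert sp.idiff(np.full((3, 3), 0.5))[2] == pytest.approx(0.0)

    def test_hand_arithmetic_2x2(self):
        I = np.array([[0.9, 0.5], [0.3, 0.7]])
        iself, iothers, diff = sp.idiff(I)
        assert (iself, iothers, diff) == (0.8, 0.4, pytest.approx(0.4))
        assert sp.cohens_d(I) == pytest.approx(0.4 / np.sqrt(0.02), abs=1e-12)

    def test_cohens_d_matches_pooled_sd_oracle(self, rng):
        for _ in range(100):
            I = random_I(rng, int(rng.integers(2, 9)))
            diag = np.diag(I)
            off = I[~np.eye(I.shape[0], dtype=bool)]
            pooled = np.sqrt((np.var(diag, ddof=1) + np.var(off, ddof=1)) / 2)
            expected = (diag.mean() - off.mean()) / pooled
            assert sp.cohens_d(I) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variances_warn_and_return_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(sp.cohens_d(np.full((2, 2), 0.3)))

    def test_statistics_invariant_under_joint_permutation(self, rng):
        I = random_I(rng, 7)
        perm = rng.permutation(7)
        J = I[np.ix_(perm, perm)]
        assert sp.idiff(J)[2] == pytest.approx(sp.idiff(I)[2], abs=1e-14)
        assert sp.cohens_d(J) == pytest.approx(sp.cohens_d(I), abs=1e-12)
        assert sp.success_rate(J)[0] == sp.success_rate(I)[0]
        assert sp.topk_accuracy(J, 3) == sp.topk_accuracy(I, 3)


class TestSuccessAndTopK:
    def test_diagonally_dominant_is_perfect(self):
        I = np.eye(5) + 0.01
        count, acc = sp.success_rate(I)
        assert (count, acc) == (5, 100.0)

    def test_one_failed_row(self):
        I = np.eye(3)
        I[1, 2] = 2.0  # row 1's max off the diagonal
        count, acc = sp.success_rate(I)
        assert count == 2
        assert acc == pytest.approx(200.0 / 3)
        topk = sp.topk_accuracy(I, 2)
        assert topk[1] == pytest.approx(200.0 / 3)
        assert topk[2] == 100.0

    def test_diagonal_tie_counts_as_failure(self):
        I = np.array([[0.5, 0.5], [0.1, 0.9]])
        with pytest.warns(UserWarning, match="tie"):
            count, _ = sp.success_rate(I)
        assert count == 1

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=10))
    @settings(max_examples=40, deadline=None)
    def test_topk_monotone_and_exhaustive(self, seed, ns):
        I = random_I(np.random.default_rng(seed), ns)
        topk = sp.topk_accuracy(I, ns)
        vals = [topk[k] for k in range(1, ns + 1)]
        assert vals == sorted(vals)
        assert topk[ns] == 100.0
        assert topk[1] == pytest.approx(sp.success_rate(I)[1])


class TestSortAndReport:
    def test_sort_by_diagonal_descending_and_invariant(self, rng):
        v1 = [_vec(rng.normal(size=6), subject=f"s{i}", n=4) for i in range(5)]
        v2 = [_vec(rng.normal(size=6), subject=f"s{i}", n=4, run=2)
              for i in range(5)]
        res = sp.fingerprint(v1, v2)
        sorted_res = sp.sort_by_diagonal(res)
        d = np.diag(sorted_res.I)
        assert np.all(np.diff(d) <= 0)
        assert sorted(sorted_res.subject_order) == sorted(res.subject_order)
        assert sorted_res.idiff == pytest.approx(res.idiff, abs=1e-15)
        assert sorted_res.accuracy == res.accuracy
        # sorting twice is a no-op
        again = sp.sort_by_diagonal(sorted_res)
        assert np.array_equal(again.I, sorted_res.I)

    @pytest.mark.parametrize("ns, display",
                             [(18, "5.6%"), (43, "2.3%"), (15, "6.7%"), (12, "8.3%")])
    def test_chance_level_display(self, ns, display):
        assert format_percent(sp.chance_level(ns)) == display

    def test_report_fields_round(self, rng):
        v1 = [_vec(rng.normal(size=6), subject=f"s{i}", n=4) for i in range(3)]
        v2 = [_vec(rng.normal(size=6), subject=f"s{i}", n=4) for i in range(3)]
        rep = sp.fingerprint(v1, v2).to_report()
        assert rep["chance_display"] == "33.3%"
        assert set(rep) >= {"idiff", "cohens_d", "accuracy_percent",
                            "topk_percent", "success_count"}
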