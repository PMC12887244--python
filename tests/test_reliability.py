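"""Edge-wise ICC(1,1), level-block averaging, thresholding, nodal strength."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spineprint as sp
from spineprint.pipeline import cohort_vectors
from spineprint.reliability import ReliabilityError


def icc_anova_oracle(x):
    """Brute-force one-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    ns, k = x.shape
    grand = x.mean()
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(ns))
    ssw = sum((x[i, j] - x[i].mean()) ** 2 for i in range(ns) for j in range(k))
    msr = ssr / (ns - 1)
    msw = ssw / (ns * (k - 1))
    return (msr - msw) / (msr + (k - 1) * msw)


class TestICC:
    def test_perfect_agreement(self):
        assert sp.icc_1_1([[1, 1], [2, 2], [3, 3]]) == pytest.approx(1.0)

    def test_pure_disagreement_hand_anova(self):
        # MSR = 0, MSW = 0.5 -> ICC = -1
        assert sp.icc_1_1([[1, 2], [2, 1]]) == pytest.approx(-1.0)

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(100):
            x = rng.normal(size=(6, 2))
            assert sp.icc_1_1(x) == pytest.approx(icc_anova_oracle(x), abs=1e-12)

    def test_matches_pingouin_icc1(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        for seed in range(3):
            r = np.random.default_rng(seed)
            x = r.normal(size=(8, 2))
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(8), 2),
                "rater": np.tile([0, 1], 8),
                "score": x.ravel(),
            })
            ref = pingouin.intraclass_corr(
                df, targets="subject", raters="rater", ratings="score")
            # first row of the pingouin table is the one-way random ICC1
            assert "1" in str(ref["Type"].iloc[0])
            icc1 = float(ref["ICC"].iloc[0])
            assert sp.icc_1_1(x) == pytest.approx(icc1, abs=1e-10)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_affine_invariant(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=(int(r.integers(2, 10)), 2))
        val = sp.icc_1_1(x)
        assert -1.0 - 1e-12 <= val <= 1.0 + 1e-12
        scale, shift = float(r.uniform(0.1, 10)), float(r.normal(scale=5))
        assert sp.icc_1_1(x * scale + shift) == pytest.approx(val, abs=1e-9)

    def test_too_few_subjects(self):
        with pytest.raises(ReliabilityError):
            sp.icc_1_1([[1.0, 2.0]])


class TestICCMatrix:
    def test_identical_runs_give_unit_icc(self, tiny_spine):
        spec = sp.CohortSpec(n_subjects=5, parcellation=tiny_spine, T=60, seed=2)
        v1, _ = cohort_vectors(sp.generate_cohort(spec).runs)
        m = sp.icc_matrix(v1, v1)
        off = ~np.eye(m.N, dtype=bool)
        assert np.allclose(m.values[off], 1.0)
        assert np.all(np.isnan(np.diag(m.values)))

    def test_symmetric_and_matches_per_edge_icc(self, tiny_spine):
        spec = sp.CohortSpec(n_subjects=6, parcellation=tiny_spine, T=80, seed=5)
        v1, v2 = cohort_vectors(sp.generate_cohort(spec).runs)
        m = sp.icc_matrix(v1, v2)
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        x1 = np.array([v.values for v in v1])
        x2 = np.array([v.values for v in v2])
        for e, (i, j) in enumerate(v1[0].edge_index[:25]):
            table = np.column_stack([x1[:, e], x2[:, e]])
            assert m.values[i, j] == pytest.approx(sp.icc_1_1(table), abs=1e-12)

    def test_null_edges_have_near_zero_mean_icc(self, rng):
        """Subject-exchangeable noise: mean edge ICC ~ 0 over replicates."""
        from spineprint.connectivity import FCVector, edge_index_for
        parc = sp.build_brain_parcellation(n_cortical=4, n_subcortical=0)
        vals = []
        for _ in range(200):
            v1 = [FCVector(rng.normal(size=6), edge_index_for(4), parc, f"s{i}", 1)
                  for i in range(6)]
            v2 = [FCVector(rng.normal(size=6), edge_index_for(4), parc, f"s{i}", 2)
                  for i in range(6)]
            m = sp.icc_matrix(v1, v2)
            vals.append(np.nanmean(m.values))
        assert abs(np.mean(vals)) < 0.03

    def test_between_subject_variance_drives_icc(self, tiny_spine):
        """Stronger subject effect -> larger mean edge ICC (rank order)."""
        def mean_icc(lam, seed):
            spec = sp.CohortSpec(n_subjects=8, parcellation=tiny_spine, T=120,
                                 lambda_subject=lam, sigma_run=1.0, seed=seed)
            v1, v2 = cohort_vectors(sp.generate_cohort(spec).runs)
            return np.nanmean(sp.icc_matrix(v1, v2).values)

        grid = [np.mean([mean_icc(l, s) for s in range(3)])
                for l in (0.0, 0.5, 2.0)]
        assert grid == sorted(grid)


class TestLevelAverageAndThreshold:
    def _map_from(self, values, parc):
        v1, v2 = None, None
        m = sp.ICCMap(values=values, msr_map=np.zeros_like(values),
                      msw_map=np.zeros_like(values), labels=parc)
        return m

    def test_identical_blocks_average_to_block(self, rng):
        parc = sp.build_spinal_parcellation(["C4", "C5"])
        block = rng.normal(size=(14, 14))
        block = (block + block.T) / 2
        np.fill_diagonal(block, np.nan)
        values = np.full((28, 28), np.nan)
        values[:14, :14] = block
        values[14:, 14:] = block
        avg = sp.average_level_blocks([self._map_from(values, parc)])
        assert np.allclose(avg, block, equal_nan=True)

    def test_opposite_blocks_cancel(self):
        parc = sp.build_spinal_parcellation(["C4", "C5"])
        block = np.ones((14, 14))
        values = np.zeros((28, 28))
        values[:14, :14] = block
        values[14:, 14:] = -block
        avg = sp.average_level_blocks([self._map_from(values, parc)])
        assert np.allclose(avg, 0.0)

    def test_three_hand_blocks_elementwise_mean(self, rng):
        parc = sp.build_spinal_parcellation(["C4"])
        blocks = [rng.normal(size=(14, 14)) for _ in range(3)]
        maps = [self._map_from(b, parc) for b in blocks]
        avg = sp.average_level_blocks(maps)
        assert np.allclose(avg, np.mean(blocks, axis=0), atol=1e-14)

    def test_non_spinal_map_rejected(self, rng):
        parc = sp.build_brain_parcellation(n_cortical=4, n_subcortical=0)
        with pytest.raises(ReliabilityError):
            sp.average_level_blocks([self._map_from(np.zeros((4, 4)), parc)])

    def test_threshold_enumeration_oracle(self, rng):
        n = 8  # 28 edges
        m = rng.normal(size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, np.nan)
        thr, filtered = sp.threshold_percentile(m, pct=95)
        rows, cols = np.triu_indices(n, k=1)
        edges = m[rows, cols]
        assert thr == pytest.approx(np.percentile(edges, 95))
        kept = filtered[rows, cols]
        assert np.array_equal(kept > 0, edges >= thr) or np.array_equal(
            kept != 0, edges >= thr)
        assert np.allclose(filtered, filtered.T)

    def test_constant_matrix_fully_retained(self):
        m = np.full((5, 5), 0.4)
        thr, filtered = sp.threshold_percentile(m, pct=95)
        off = ~np.eye(5, dtype=bool)
        assert thr == pytest.approx(0.4)
        assert np.allclose(filtered[off], 0.4)

    def test_zero_matrix_passes_through(self):
        _, filtered = sp.threshold_percentile(np.zeros((4, 4)), pct=50)
        assert np.allclose(filtered, 0.0)


class TestNodalStrength:
    def test_single_edge(self):
        m = np.zeros((4, 4))
        m[1, 3] = m[3, 1] = 0.7
        s = sp.nodal_strength(m)
        assert np.allclose(s, [0, 0.7, 0, 0.7])

    def test_sum_matches_row_sum_oracle_and_mean_mode(self, rng):
        m = rng.uniform(size=(6, 6))
        m = (m + m.T) / 2
        expected = m.sum(axis=1) - np.diag(m)
        assert np.allclose(sp.nodal_strength(m), expected)
        assert np.allclose(sp.nodal_strength(m, mode="mean"), expected / 5)
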