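"""ICC/COV/bootstrap statistics vs independent oracles and invariances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegnetrel import (MeasurementTable, bootstrap_ci, classify_icc, cov,
                       global_connectivity, icc, icc_bootstrap_ci, icc_table,
                       icc_unitwise, matrix_correlation, reliability_report,
                       top_percentile_edges)
from eegnetrel.connectivity import ConnectivityMatrix
from eegnetrel.reliability import pair_by_subject
from conftest import random_symmetric_matrix


def icc3_oracle(x: np.ndarray) -> float:
    """Explicit two-way sum-of-squares decomposition, ICC(3,1)."""
    n, k = x.shape
    grand = x.mean()
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_sess = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_sess
    msr = ss_subj / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def icc1_oracle(x: np.ndarray) -> float:
    """One-way variant: MSe is the within-subject mean square."""
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msw = sum((x[i] - x[i].mean()) @ (x[i] - x[i].mean())
              for i in range(n)) / (n * (k - 1))
    return (msr - msw) / (msr + (k - 1) * msw)


def make_matrix(values, subject="s0", session=1, band="beta", method="pli"):
    n = values.shape[0]
    return ConnectivityMatrix(subject_id=subject, session_id=session,
                              band_name=band, method=method, values=values,
                              channel_labels=[f"c{i}" for i in range(n)],
                              n_epochs=20)


def random_cohort_matrices(rng, n_subjects=6, n_channels=5, rho=0.8):
    """Synthetic 'PLI' matrices with correlated sessions, no signal model."""
    mats = []
    iu = np.triu_indices(n_channels, k=1)
    for s in range(n_subjects):
        base = rng.uniform(0.1, 0.8, size=len(iu[0]))
        for sess in (1, 2):
            w = np.clip(base + (0.0 if sess == 1 else
                                np.sqrt(1 - rho ** 2) *
                                rng.normal(0, 0.1, len(iu[0]))), 0.01, 1)
            m = np.zeros((n_channels, n_channels))
            m[iu] = w
            mats.append(make_matrix(m + m.T, subject=f"s{s}", session=sess))
    return mats


class TestIccOracle:
    def test_matches_two_way_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(5, 13))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=(n, k))
            assert icc_table(x) == pytest.approx(icc3_oracle(x), abs=1e-9)

    def test_one_way_variant_matches_its_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=(8, 2))
            assert icc_table(x, model="one_way") == pytest.approx(
                icc1_oracle(x), abs=1e-9)

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "session": np.tile([1, 2], 10),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject",
                                       raters="session", ratings="score")
        # single-rater consistency form: labelled ICC3 or ICC(C,1)
        sel = ref.Type.isin(["ICC3", "ICC(C,1)"])
        icc3 = ref.loc[sel, "ICC"].iloc[0]
        assert icc_table(x) == pytest.approx(icc3, abs=1e-9)

    def test_identical_sessions_give_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_table(x) == 1.0

    def test_constant_session_shift_gives_one(self):
        # consistency ICC ignores additive session effects
        x = np.array([[1.0, 1.5], [2.0, 2.5], [3.0, 3.5]])
        assert icc_table(x) == pytest.approx(1.0)

    def test_all_identical_values_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="identical"):
            assert icc_table(np.ones((4, 2))) == 1.0

    def test_no_between_subject_variance_is_undefined(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="undefined"):
            icc_table(x)

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_table(np.array([[1.0, 2.0], [2.0, 1.0]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10), seed=st.integers(0, 50))
    def test_affine_invariance(self, shift, scale, seed):
        x = np.random.default_rng(seed).normal(size=(6, 2))
        base = icc_table(x)
        assert icc_table(scale * x + shift) == pytest.approx(base, abs=1e-7)
        # per-session constant offsets are absorbed by the session effect
        assert icc_table(x + np.array([0.0, shift])) == pytest.approx(
            base, abs=1e-7)

    def test_negative_icc_reported_unclamped(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0], [1.5, 1.6], [1.2, 1.9]])
        val = icc_table(x)
        assert val < 0
        assert val == pytest.approx(icc3_oracle(x), abs=1e-12)


class TestCov:
    def test_constant_vector_zero(self):
        assert cov(np.full(5, 3.0)) == 0.0

    def test_two_point_formula(self):
        assert cov(np.array([1.0, 3.0])) == pytest.approx(np.sqrt(2) / 2)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1, 2, 20)
        assert cov(v) == pytest.approx(v.std(ddof=1) / v.mean(), abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cov(np.array([-1.0, 1.0]))


class TestMatrixLevel:
    def test_self_correlation_is_one(self):
        W = random_symmetric_matrix(np.random.default_rng(4), 6)
        m1 = make_matrix(W, session=1)
        m2 = make_matrix(W, session=2)
        assert matrix_correlation(m1, m2) == pytest.approx(1.0)

    def test_affine_invariance(self):
        W = random_symmetric_matrix(np.random.default_rng(5), 6)
        W2 = 0.5 * W + 0.1
        np.fill_diagonal(W2, 0.0)
        assert matrix_correlation(make_matrix(W), make_matrix(W2, session=2)
                                  ) == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        A = random_symmetric_matrix(rng, 7)
        B = random_symmetric_matrix(rng, 7)
        iu = np.triu_indices(7, k=1)
        a, b = A[iu], B[iu]
        ref = (((a - a.mean()) * (b - b.mean())).mean()
               / (a.std() * b.std()))
        assert matrix_correlation(make_matrix(A), make_matrix(B, session=2)
                                  ) == pytest.approx(ref, abs=1e-12)

    def test_global_connectivity_examples(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = 0.4
        W[1, 2] = W[2, 1] = 0.6
        assert global_connectivity(make_matrix(W)) == pytest.approx(0.4)
        U = np.full((8, 8), 0.5)
        np.fill_diagonal(U, 0.0)
        assert global_connectivity(make_matrix(U)) == pytest.approx(0.5)


class TestUnitwise:
    def test_per_edge_matches_anova_oracle(self):
        rng = np.random.default_rng(7)
        mats = random_cohort_matrices(rng, n_subjects=6, n_channels=5)
        per_edge, edges, med = icc_unitwise(mats)
        pairs = pair_by_subject(mats)
        iu = np.triu_indices(5, k=1)
        for e_idx in range(len(edges)):
            tab = np.array([[pairs[s][0].values[iu][e_idx],
                             pairs[s][1].values[iu][e_idx]]
                            for s in sorted(pairs)])
            assert per_edge[e_idx] == pytest.approx(icc3_oracle(tab),
                                                    abs=1e-9)
        assert med == pytest.approx(np.median(per_edge))

    def test_perfectly_stable_cohort_all_edges_one(self):
        rng = np.random.default_rng(8)
        mats = random_cohort_matrices(rng, rho=1.0)
        per_edge, _, med = icc_unitwise(mats)
        assert np.allclose(per_edge, 1.0)
        assert med == pytest.approx(1.0)

    def test_mixed_stability_median_between_subpopulations(self):
        # half the edges perfectly stable, half re-randomized per session
        rng = np.random.default_rng(9)
        n_ch, n_sub = 5, 12
        iu = np.triu_indices(n_ch, k=1)
        n_edges = len(iu[0])
        stable = np.arange(n_edges) < n_edges // 2
        mats = []
        for s in range(n_sub):
            base = rng.uniform(0.2, 0.8, n_edges)
            for sess in (1, 2):
                w = base.copy()
                if sess == 2:
                    w[~stable] = rng.uniform(0.2, 0.8, (~stable).sum())
                m = np.zeros((n_ch, n_ch))
                m[iu] = w
                mats.append(make_matrix(m + m.T, subject=f"s{s}",
                                        session=sess))
        per_edge, _, med = icc_unitwise(mats)
        med_stable = np.median(per_edge[stable])
        med_unstable = np.median(per_edge[~stable])
        assert med_unstable <= med <= med_stable
        assert med_stable == pytest.approx(1.0)


class TestTopPercentile:
    def test_quartile_of_496_edges_is_124(self):
        rng = np.random.default_rng(10)
        mats = [make_matrix(random_symmetric_matrix(rng, 32),
                            subject=f"s{s}", session=sess)
                for s in range(3) for sess in (1, 2)]
        mask = top_percentile_edges(mats, 25)
        assert mask.size == 496
        assert mask.sum() == 124

    def test_all_equal_strength_returns_full_set_with_warning(self):
        U = np.full((6, 6), 0.5)
        np.fill_diagonal(U, 0.0)
        mats = [make_matrix(U.copy(), subject=f"s{s}", session=sess)
                for s in range(3) for sess in (1, 2)]
        with pytest.warns(UserWarning, match="tied"):
            mask = top_percentile_edges(mats, 25)
        assert mask.all()

    def test_percentile_out_of_range_rejected(self):
        rng = np.random.default_rng(11)
        mats = random_cohort_matrices(rng)
        with pytest.raises(ValueError):
            top_percentile_edges(mats, 0)


class TestBootstrap:
    def test_degenerate_statistic_collapses_interval(self):
        lo, hi = bootstrap_ci(lambda subs: 7.5, list(range(10)), n_boot=50,
                              seed=0)
        assert (lo, hi) == (7.5, 7.5)

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(12)
        data = list(rng.normal(size=20))
        stat = lambda subs: float(np.mean(subs))
        assert bootstrap_ci(stat, data, 200, seed=3) == bootstrap_ci(
            stat, data, 200, seed=3)

    def test_mostly_undefined_statistic_rejected(self):
        def bad(subs):
            raise ValueError("nope")
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_ci(bad, list(range(5)), n_boot=20, seed=0)

    def test_vectorized_icc_bootstrap_deterministic_and_ordered(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(15, 2)) + np.repeat(
            rng.normal(size=(15, 1)), 2, axis=1)
        ci_a = icc_bootstrap_ci(x, n_boot=500, seed=1)
        ci_b = icc_bootstrap_ci(x, n_boot=500, seed=1)
        assert ci_a == ci_b
        assert ci_a[0] < ci_a[1] <= 1.0

    def test_vectorized_agrees_with_generic_bootstrap(self):
        # identical resampling cannot be forced (different RNG streams),
        # so agreement is statistical: wide overlap of interval endpoints
        rng = np.random.default_rng(14)
        x = rng.normal(size=(25, 2)) + np.repeat(
            rng.normal(size=(25, 1)) * 2, 2, axis=1)
        fast = icc_bootstrap_ci(x, n_boot=2000, seed=2)
        subjects = list(range(25))
        slow = bootstrap_ci(
            lambda subs: icc_table(x[list(subs)]), subjects, n_boot=2000,
            seed=99)
        assert fast[0] == pytest.approx(slow[0], abs=0.1)
        assert fast[1] == pytest.approx(slow[1], abs=0.1)


class TestReportAssembly:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(15)
        mats = random_cohort_matrices(rng, n_subjects=8, n_channels=6)
        rep = reliability_report(mats, n_boot=200, seed=0)
        assert rep.n_subjects == 8
        assert len(rep.matrix_correlations) == 8
        assert rep.unitwise_icc.shape == (15,)
        assert rep.top_mask.sum() >= int(np.ceil(0.25 * 15))
        assert rep.icc_global <= 1.0
        assert classify_icc(0.9) == "excellent"
        assert classify_icc(0.5) == "mediocre"
        assert classify_icc(0.7) == "good"
        assert classify_icc(0.1) == "low"

    def test_subject_missing_session_dropped_with_warning(self):
        rng = np.random.default_rng(16)
        mats = random_cohort_matrices(rng, n_subjects=5)
        orphan = make_matrix(random_symmetric_matrix(rng, 5), subject="s9",
                             session=1)
        with pytest.warns(UserWarning, match="missing a session"):
            pairs = pair_by_subject(mats + [orphan])
        assert "s9" not in pairs
        assert len(pairs) == 5

    def test_table_validation(self):
        with pytest.raises(ValueError):
            MeasurementTable(np.ones((3, 1)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            MeasurementTable(np.array([[1.0, np.nan]]), ["a"])
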