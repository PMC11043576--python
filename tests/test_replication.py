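"""Replication-phase preprocessing, multiple-testing correction, PCA
separation, and correlation-based feature selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirdiscover.replication import (
    FeatureTable,
    best_first_search,
    cfs_merit,
    cfs_select,
    exhaustive_search,
    holm_sidak_adjust,
    pca_separation,
    preprocess_mfi,
    univariate_tests,
)
from mirdiscover.simulate import MfiMatrix, simulate_cohort
from conftest import make_cohort, make_feature_table


def tiny_mfi(cohort, study, qc=None, blanks=None):
    cols = {sid: study[:, i] for i, sid in enumerate(cohort.sample_ids)}
    role = {sid: "study" for sid in cohort.sample_ids}
    if qc is not None:
        for i in range(qc.shape[1]):
            cols[f"QC{i}"] = qc[:, i]
            role[f"QC{i}"] = "qc_pool"
    if blanks is not None:
        for i in range(blanks.shape[1]):
            cols[f"B{i}"] = blanks[:, i]
            role[f"B{i}"] = "blank"
    values = pd.DataFrame(cols, index=[f"p{i}" for i in range(study.shape[0])])
    return MfiMatrix(values, well_role=role)


class TestPreprocess:
    def test_negative_shift_and_log10(self):
        cohort = make_cohort(1, 1)
        mfi = tiny_mfi(cohort, np.array([[-5.0, 1000.0]]))
        ft = preprocess_mfi(mfi, cohort)
        vals = ft.frame["p0"]
        assert vals.iloc[0] == pytest.approx(-3.0)   # -5 -> 0.001 -> log10
        assert vals.iloc[1] == pytest.approx(3.0)
        assert ft.n_negative_shifted == 1

    def test_zero_variance_qc_gives_zero_cv(self):
        cohort = make_cohort(1, 1)
        mfi = tiny_mfi(cohort, np.array([[10.0, 20.0]]),
                       qc=np.array([[7.0, 7.0, 7.0]]))
        ft = preprocess_mfi(mfi, cohort)
        assert ft.qc_cv["p0"] == 0.0

    def test_background_subtraction_is_config_gated(self):
        cohort = make_cohort(1, 1)
        mfi = tiny_mfi(cohort, np.array([[100.0, 100.0]]),
                       blanks=np.array([[40.0, 60.0]]))
        off = preprocess_mfi(mfi, cohort, subtract_background=False)
        on = preprocess_mfi(mfi, cohort, subtract_background=True)
        assert off.frame["p0"].iloc[0] == pytest.approx(2.0)
        assert on.frame["p0"].iloc[0] == pytest.approx(np.log10(50.0))


class TestHolmSidak:
    def test_hand_example(self):
        adj = holm_sidak_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.029701, 0.039592, 0.039592], abs=1e-5)

    def test_single_p_identity(self):
        assert holm_sidak_adjust([0.2]) == pytest.approx([0.2])

    def test_zeros_stay_zero(self):
        assert holm_sidak_adjust([0.0, 0.0]) == pytest.approx([0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.integers(0, 1000))
    def test_permutation_invariance_and_dominance(self, p, seed):
        p = np.asarray(p)
        adj = holm_sidak_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        perm = np.random.default_rng(seed).permutation(len(p))
        assert np.allclose(holm_sidak_adjust(p[perm]), adj[perm])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        _, adj_sm, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(holm_sidak_adjust(p), adj_sm)


class TestUnivariate:
    def test_shared_kernel_example(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        ft = make_feature_table(X, [1, 1, 1, 0, 0, 0])
        res = univariate_tests(ft, training_only=False)
        assert res.loc["p000", "p_raw"] == pytest.approx(0.0213, abs=5e-4)
        assert res.loc["p000", "mean_diff"] == pytest.approx(-3.0)
        assert res.loc["p000", "fold_change"] == pytest.approx(-1000.0)

    def test_degenerate_probe_flagged(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        ft = make_feature_table(X, [1, 1, 1, 1, 0, 0, 0, 0])
        res = univariate_tests(ft, training_only=False)
        assert res.loc["p000", "degenerate"]
        assert res.loc["p000", "p_raw"] == 1.0

    def test_null_pvalues_uniform(self, rng):
        X = rng.normal(size=(40, 1000))
        ft = make_feature_table(X, [1] * 20 + [0] * 20)
        res = univariate_tests(ft, training_only=False)
        ks = stats.kstest(res["p_raw"], "uniform")
        assert ks.pvalue > 1e-3

    def test_null_family_rarely_significant_after_adjustment(self, rng):
        # FWER control across replicated null panels
        hits = 0
        for i in range(100):
            X = rng.normal(size=(60, 63))
            ft = make_feature_table(X, [1] * 20 + [0] * 40)
            res = univariate_tests(ft, training_only=False)
            hits += (res["p_adjusted"] < 0.05).any()
        assert hits <= 10


class TestPcaSeparation:
    def test_planted_separation_detected(self, rng):
        y = np.array([1] * 30 + [0] * 30)
        X = rng.normal(size=(60, 10)) + 4.0 * y[:, None]
        ft = make_feature_table(X, y)
        report = pca_separation(ft, split=None)
        assert report.pc1_auc > 0.95
        assert report.cluster_agreement > 0.9

    def test_null_labels_no_separation(self, rng):
        y = np.array([1] * 30 + [0] * 30)
        X = rng.normal(size=(60, 10))
        report = pca_separation(make_feature_table(X, y), split=None)
        assert report.pc1_auc < 0.70

    def test_variance_ratios_sum_to_at_most_one(self, rng):
        X = rng.normal(size=(20, 6))
        report = pca_separation(make_feature_table(X, [1] * 10 + [0] * 10),
                                split=None, n_components=6)
        assert report.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_columns_dropped_with_warning(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        with pytest.warns(UserWarning, match="constant"):
            report = pca_separation(make_feature_table(X, [1] * 10 + [0] * 10),
                                    split=None)
        assert report.dropped == ("p000",)


def brute_best_subset(class_corr, feature_corr, candidates, forced=()):
    best, best_merit = (), -np.inf
    for k in range(0, len(candidates) + 1):
        for combo in itertools.combinations(sorted(candidates), k):
            subset = list(forced) + list(combo)
            merit = cfs_merit(class_corr, feature_corr, subset) if subset else 0.0
            if merit > best_merit + 1e-12:
                best, best_merit = combo, merit
    return best, best_merit


def random_instance(rng, n):
    names = [f"f{i}" for i in range(n)]
    rcf = {f: float(rng.uniform(0, 1)) for f in names}
    A = rng.uniform(0, 1, size=(n, n))
    M = np.abs((A + A.T) / 2)
    np.fill_diagonal(M, 1.0)
    return rcf, pd.DataFrame(M, index=names, columns=names), names


class TestCfsMerit:
    def test_singleton_reduces_to_class_correlation(self):
        rcf = {"a": 0.37}
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        assert cfs_merit(rcf, corr, ["a"]) == pytest.approx(0.37)

    def test_two_uncorrelated_features(self):
        rcf = {"a": 0.5, "b": 0.5}
        corr = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]],
                            index=["a", "b"], columns=["a", "b"])
        assert cfs_merit(rcf, corr, ["a", "b"]) == pytest.approx(1 / np.sqrt(2))

    def test_perfectly_redundant_feature_never_helps(self, rng):
        for _ in range(20):
            r = float(rng.uniform(0.1, 0.9))
            rcf = {"a": r, "b": r}
            corr = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]],
                                index=["a", "b"], columns=["a", "b"])
            assert cfs_merit(rcf, corr, ["a", "b"]) <= cfs_merit(rcf, corr, ["a"]) + 1e-12

    def test_search_matches_brute_force(self, rng):
        for n in (3, 5, 7):
            for _ in range(5):
                rcf, corr, names = random_instance(rng, n)
                expected = brute_best_subset(rcf, corr, names)
                got_ex = exhaustive_search(rcf, corr, names)
                # generous stall budget: on enumerable instances the search
                # should reach the global optimum
                got_bf = best_first_search(rcf, corr, names, stall_limit=30)
                assert got_ex[1] == pytest.approx(expected[1])
                assert set(got_ex[0]) == set(expected[0])
                assert got_bf[1] == pytest.approx(expected[1])


class TestCfsSelect:
    def test_single_informative_candidate_selected_every_fold(self, rng):
        y = np.array([1] * 30 + [0] * 30)
        X = np.column_stack([y + rng.normal(0, 0.5, 60)])
        ft = make_feature_table(X, y, hormone=rng.integers(0, 2, 60))
        fs = cfs_select(ft, folds=5, seed=0)
        assert fs.selected == ("p000",)
        assert fs.frequencies["p000"] == 1.0
        assert "hormone_use" in fs.features

    def test_planted_uncorrelated_probes_recovered(self, rng):
        # 5 informative, mutually uncorrelated probes among 45 noise probes
        y = np.tile([1, 0], 60)
        X = rng.normal(size=(120, 50))
        X[:, :5] += 1.0 * y[:, None]
        ft = make_feature_table(X, y, hormone=rng.integers(0, 2, 120))
        fs = cfs_select(ft, folds=10, seed=1)
        planted = {f"p{i:03d}" for i in range(5)}
        assert planted <= set(fs.selected)
        assert len(set(fs.selected) - planted) <= 1

    def test_pure_noise_selects_only_forced(self, rng):
        y = np.tile([1, 0], 30)
        X = rng.normal(size=(60, 30))
        ft = make_feature_table(X, y, hormone=rng.integers(0, 2, 60))
        fs = cfs_select(ft, folds=5, seed=2, min_fold_fraction=0.8)
        assert fs.features[-1] == "hormone_use"
        assert len(fs.selected) <= 2

    def test_no_gate_survivors_warns(self, rng):
        y = np.tile([1, 0], 20)
        X = rng.normal(size=(40, 5))
        ft = make_feature_table(X, y)
        with pytest.warns(UserWarning, match="p-gate"):
            fs = cfs_select(ft, folds=5, seed=0, p_gate=1e-9)
        assert fs.selected == ()
        assert fs.features == ("hormone_use",)

    def test_deterministic_given_seed(self, rng):
        y = np.tile([1, 0], 30)
        X = rng.normal(size=(60, 20))
        X[:, 0] += y
        ft = make_feature_table(X, y, hormone=rng.integers(0, 2, 60))
        a = cfs_select(ft, folds=5, seed=9)
        b = cfs_select(ft, folds=5, seed=9)
        assert a == b
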