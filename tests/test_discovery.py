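"""Discovery-phase statistics: duplicate collapsing, QC, imputation, global
normalization, Normfinder, 2^-ddCt, stratified tests and the selection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirdiscover.discovery import (
    REASON_BOTH,
    REASON_EITHER,
    REASON_NONE,
    NormalizedExpr,
    assemble_panel,
    collapse_duplicates,
    ddct_fold_change,
    discovery_selection_rule,
    global_normalize,
    impute_missing,
    normfinder_stability,
    pooled_ttest,
    qc_filter,
    select_references,
    signed_fold_change,
    stratified_ttests,
)
from mirdiscover.simulate import (
    CtMatrix,
    SimulationTruth,
    simulate_cohort,
    simulate_ct_matrix,
)
from conftest import make_cohort


def ct_matrix(data, samples, duplicates=False):
    if duplicates:
        cols, rep = [], {}
        for s in samples:
            cols += [f"{s}_A", f"{s}_B"]
            rep[f"{s}_A"] = rep[f"{s}_B"] = s
        return CtMatrix(pd.DataFrame(data, columns=cols,
                                     index=[f"m{i}" for i in range(len(data))]),
                        replicate_of=rep)
    return CtMatrix(pd.DataFrame(data, columns=samples,
                                 index=[f"m{i}" for i in range(len(data))]))


class TestCollapseDuplicates:
    def test_mean_discordance_and_identity(self):
        ct = ct_matrix([[24.0, 24.4, 24.0, 26.0, 30.0, 30.0]], ["s1", "s2", "s3"],
                       duplicates=True)
        out = collapse_duplicates(ct, max_discordance=1.0)
        row = out.values.loc["m0"]
        assert row["s1"] == pytest.approx(24.2)
        assert np.isnan(row["s2"])          # |24 - 26| > 1 cycle
        assert row["s3"] == pytest.approx(30.0)

    def test_single_observed_replicate_passes_through(self):
        ct = ct_matrix([[25.0, np.nan]], ["s1"], duplicates=True)
        out = collapse_duplicates(ct)
        assert out.values.loc["m0", "s1"] == pytest.approx(25.0)

    def test_unpaired_matrix_rejected(self):
        ct = ct_matrix([[25.0]], ["s1"])
        with pytest.raises(ValueError, match="pairing"):
            collapse_duplicates(ct)


class TestQcFilter:
    def test_greater_than_34_censored_exactly(self):
        ct = ct_matrix([[34.5, 34.0, 20.0, 21.0]], ["a", "b", "c", "d"])
        out, report = qc_filter(ct, ct_max=34.0, max_missing_fraction=0.5)
        row = out.values.loc["m0"]
        assert np.isnan(row["a"])            # strictly greater than 34
        assert row["b"] == pytest.approx(34.0)  # boundary value retained
        assert report.n_values_censored == 1

    def test_mostly_missing_mirna_dropped(self):
        ct = ct_matrix(
            [[35.0, 35.0, 35.0, 20.0, 20.0],
             [20.0, 21.0, 22.0, 23.0, 24.0]],
            list("abcde"))
        out, report = qc_filter(ct, 34.0, max_missing_fraction=0.5)
        assert report.dropped_mirnas == ("m0",)
        assert list(out.values.index) == ["m1"]

    def test_everything_dropped_is_fatal(self):
        ct = ct_matrix([[35.0, 36.0]], ["a", "b"])
        with pytest.raises(ValueError, match="nothing to analyze"):
            qc_filter(ct, 34.0, 0.5)


class TestImpute:
    def test_cell_mean(self):
        cohort = make_cohort(3, 3, hormone_pattern=[1, 1, 1])
        cols = list(cohort.sample_ids)
        data = [[20.0, 22.0, np.nan, 25.0, 26.0, 27.0]]
        ct = ct_matrix(data, cols)
        out = impute_missing(ct, cohort)
        assert out.values.loc["m0", cols[2]] == pytest.approx(21.0)

    def test_no_missing_is_identity(self):
        cohort = make_cohort(2, 2)
        ct = ct_matrix([[20.0, 21.0, 22.0, 23.0]], list(cohort.sample_ids))
        out = impute_missing(ct, cohort)
        pd.testing.assert_frame_equal(out.values, ct.values)

    def test_all_missing_mirna_rejected(self):
        cohort = make_cohort(2, 2)
        ct = ct_matrix([[np.nan] * 4], list(cohort.sample_ids))
        with pytest.raises(ValueError, match="no observed values"):
            impute_missing(ct, cohort)


class TestGlobalNormalize:
    def test_mean_subtraction(self):
        ct = ct_matrix([[20.0], [22.0], [24.0]], ["s1"])
        out = global_normalize(ct)
        assert out.values["s1"].tolist() == [-2.0, 0.0, 2.0]

    def test_constant_column_to_zero(self):
        ct = ct_matrix([[5.0], [5.0], [5.0]], ["s1"])
        assert (global_normalize(ct).values["s1"] == 0).all()

    @given(shift=st.floats(-3, 3), col=st.integers(0, 3))
    def test_shift_invariance(self, shift, col):
        rng = np.random.default_rng(42)
        base = rng.uniform(18, 30, size=(6, 4))
        shifted = base.copy()
        shifted[:, col] += shift
        a = global_normalize(ct_matrix(base, list("wxyz"))).values
        b = global_normalize(ct_matrix(shifted, list("wxyz"))).values
        assert np.allclose(a.to_numpy(), b.to_numpy())


def brute_normfinder(values, groups):
    """Independent loop-based evaluation of the stability formula."""
    genes = list(values.index)
    levels = sorted(set(groups.values()))
    a = {(i, g): np.mean([values.loc[i, s] for s in values.columns
                          if groups[s] == g]) for i in genes for g in levels}
    v = {(i, g): np.var([values.loc[i, s] for s in values.columns
                         if groups[s] == g], ddof=1) for i in genes for g in levels}
    n = {g: sum(1 for s in values.columns if groups[s] == g) for g in levels}
    abar_i = {i: np.mean([a[i, g] for g in levels]) for i in genes}
    abar_g = {g: np.mean([a[i, g] for i in genes]) for g in levels}
    abar = np.mean([a[i, g] for i in genes for g in levels])
    rho = {}
    for i in genes:
        total = 0.0
        for g in levels:
            d = a[i, g] - abar_i[i] - abar_g[g] + abar
            total += abs(d) + np.sqrt(v[i, g] / n[g])
        rho[i] = total / len(levels)
    return rho


class TestNormfinder:
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
         [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
         [0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0]],
        index=["g1", "g2", "g3"], columns=[f"s{i}" for i in range(8)],
    )
    groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}

    def test_matches_brute_force_oracle(self):
        ranking = normfinder_stability(NormalizedExpr(self.values), self.groups)
        expected = brute_normfinder(self.values, self.groups)
        for gene, rho in expected.items():
            assert ranking.rho[gene] == pytest.approx(rho, rel=1e-12)

    def test_constant_gene_most_stable(self):
        ranking = normfinder_stability(NormalizedExpr(self.values), self.groups)
        assert ranking.rho.idxmin() == "g2"

    def test_single_group_reduces_to_standard_error(self, rng):
        values = pd.DataFrame(rng.normal(size=(5, 8)),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(8)])
        groups = {c: "only" for c in values.columns}
        ranking = normfinder_stability(NormalizedExpr(values), groups)
        se = values.var(axis=1, ddof=1).pipe(lambda v: np.sqrt(v / 8))
        assert np.allclose(ranking.rho.to_numpy(), se.to_numpy())

    def test_small_group_rejected(self):
        groups = dict(self.groups, s7="C")
        with pytest.raises(ValueError, match="at least 2"):
            normfinder_stability(NormalizedExpr(self.values), groups)


class TestSelectReferences:
    def test_k_bounds_and_ordering(self):
        ranking = normfinder_stability(
            NormalizedExpr(TestNormfinder.values), TestNormfinder.groups)
        assert select_references(ranking, 1) == ("g2",)
        assert set(select_references(ranking, 3)) == {"g1", "g2", "g3"}
        with pytest.raises(ValueError):
            select_references(ranking, 0)
        with pytest.raises(ValueError):
            select_references(ranking, 4)

    def test_planted_zero_variance_references_recovered(self):
        truth = SimulationTruth(
            reference_mirnas=("r1", "r2", "r3"),
            noise_sd_ct=0.4, duplicate_sd=0.0, missing_rate=0.0,
        )
        cohort = simulate_cohort(8, 1, 0.5, seed=1)
        ct = collapse_duplicates(simulate_ct_matrix(cohort, truth, 60, seed=2))
        expr = global_normalize(ct)
        groups = {s: cohort.record(s).group for s in ct.values.columns}
        ranking = normfinder_stability(expr, groups)
        assert set(select_references(ranking, 3)) == {"r1", "r2", "r3"}


class TestFoldChange:
    def test_signed_convention(self):
        assert signed_fold_change(1.0) == 1.0
        assert signed_fold_change(4.0) == 4.0
        assert signed_fold_change(0.5) == -2.0
        assert signed_fold_change(0.25) == -4.0

    def test_ddct_hand_example(self):
        values = pd.DataFrame([[4.0, 5.0, 6.0, 7.0]], index=["m0"],
                              columns=["c1", "c2", "k1", "k2"])
        fc = ddct_fold_change(NormalizedExpr(values), ["c1", "c2"], ["k1", "k2"])
        assert fc.loc["m0", "ddct"] == pytest.approx(-2.0)
        assert fc.loc["m0", "fold_change"] == pytest.approx(4.0)

    def test_closed_form_and_group_swap(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["m0"],
                              columns=list("abcd"))
        expr = NormalizedExpr(values)
        fwd = ddct_fold_change(expr, ["a", "b"], ["c", "d"])
        rev = ddct_fold_change(expr, ["c", "d"], ["a", "b"])
        assert fwd.loc["m0", "fold_change"] == -rev.loc["m0", "fold_change"]
        assert abs(fwd.loc["m0", "fold_change"]) >= 1.0

    def test_empty_group_rejected(self):
        expr = NormalizedExpr(pd.DataFrame([[1.0]], columns=["a"]))
        with pytest.raises(ValueError):
            ddct_fold_change(expr, [], ["a"])


class TestPooledTTest:
    def test_textbook_example_against_permutation_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = pooled_ttest(x, y)
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert p == pytest.approx(0.0213, abs=5e-4)
        # exact permutation over all 20 assignments of 6 values to two triples
        pooled = np.concatenate([x, y])
        ts = []
        for idx in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            ts.append(pooled_ttest(pooled[mask], pooled[~mask])[0])
        p_perm = np.mean(np.abs(ts) >= abs(t) - 1e-12)
        assert p_perm == pytest.approx(2 / 20)  # observed split is the extreme

    def test_null_identity_and_symmetry(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])
        t, p = pooled_ttest(x, y)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        t2, p2 = pooled_ttest(y, x)
        assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)


class TestSelectionRule:
    @pytest.mark.parametrize(
        "ph,pn,included,reason",
        [
            (0.007, 0.04, True, REASON_BOTH),     # nominal in both strata
            (0.02, 0.004, True, REASON_EITHER),   # strict in one stratum
            (0.2, 0.2, False, REASON_NONE),
            (0.004, 0.9, True, REASON_EITHER),
            (0.005, 0.05, True, REASON_BOTH),     # strict bound is exclusive
            (0.05, 0.05, True, REASON_BOTH),      # nominal bound is inclusive
            (0.051, 0.001, True, REASON_EITHER),
            (np.nan, 0.004, True, REASON_EITHER),
            (np.nan, np.nan, False, REASON_NONE),
        ],
    )
    def test_truth_table(self, ph, pn, included, reason):
        got_inc, got_reason = discovery_selection_rule(ph, pn)
        assert (got_inc, got_reason) == (included, reason)

    def test_null_rate_matches_analytic(self, rng):
        # P(include) for independent uniforms:
        # 2*0.005 + 0.05^2 - inclusion-exclusion overlaps = 0.012
        ph, pn = rng.random(200_000), rng.random(200_000)
        inc = np.array([discovery_selection_rule(a, b)[0]
                        for a, b in zip(ph[:20_000], pn[:20_000])])
        # vectorized equivalent on the full draw
        full = (ph < 0.005) | (pn < 0.005) | ((ph <= 0.05) & (pn <= 0.05))
        assert np.mean(full) == pytest.approx(0.012, abs=0.0012)
        assert np.mean(inc) == pytest.approx(np.mean(full[:20_000]))


class TestStratifiedTTests:
    def test_planted_stratum_detected_and_other_null(self):
        from mirdiscover.simulate import EffectSpec, HORMONE

        truth = SimulationTruth(
            effects=(EffectSpec("syn-miR-x", HORMONE, 2.0),),
            noise_sd_ct=0.1, duplicate_sd=0.0, missing_rate=0.0,
        )
        cohort = simulate_cohort(10, 1, 0.5, seed=3)
        ct = collapse_duplicates(simulate_ct_matrix(cohort, truth, 30, seed=4))
        result = stratified_ttests(global_normalize(ct), cohort)
        row = result.table.loc["syn-miR-x"]
        assert row["p_hormone"] < 0.005
        assert row["p_nonhormone"] > 0.05
        assert row["included"] and row["inclusion_reason"] == REASON_EITHER
        assert row["fold_change_hormone"] == pytest.approx(4.0, rel=0.15)

    def test_degenerate_stratum_flagged(self):
        cohort = make_cohort(4, 4, hormone_pattern=[0, 0, 0, 0])
        values = pd.DataFrame(np.arange(8.0)[None, :].repeat(2, axis=0),
                              index=["m0", "m1"], columns=list(cohort.sample_ids))
        with pytest.warns(UserWarning, match="degenerate"):
            result = stratified_ttests(NormalizedExpr(values), cohort)
        assert result.table["p_hormone"].isna().all()
        assert result.table["p_nonhormone"].notna().all()


class TestPanel:
    def test_paper_shape_63(self):
        panel = assemble_panel(
            [f"d{i}" for i in range(49)], [f"l{i}" for i in range(8)],
            ["pc1", "pc2", "pc3"], ["nc1", "nc2", "nc3"],
        )
        assert len(panel) == 63
        assert panel["category"].value_counts().to_dict() == {
            "discovery": 49, "literature": 8,
            "positive_control": 3, "negative_control": 3,
        }

    def test_empty_additions_identity(self):
        panel = assemble_panel(["a", "b"])
        assert panel["probe_id"].tolist() == ["a", "b"]

    def test_cross_category_duplicate_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            assemble_panel(["dup"], ["dup"])
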