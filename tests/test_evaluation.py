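import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msdrift import (
    EvaluationError,
    ParameterError,
    manova_f,
    pca_manova,
    pca_scores,
    qc_rsd,
    replicate_rsd,
)
from tests.conftest import make_matrix


def replicate_matrix(values, sets, groups=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    groups = groups or ["C" if s else None for s in sets]
    roles = ["experimental"] * n
    return make_matrix(values, [1] * n, roles, groups=groups, rep_sets=sets)


class TestReplicateRsd:
    def test_identical_triplet_rsd_zero(self):
        m = replicate_matrix([[4], [4], [4]], ["r1"] * 3)
        rep = replicate_rsd(m)
        assert rep.mean_rsd == 0.0
        assert rep.entries["grand_mean"].iloc[0] == 4

    def test_pair_excluded_as_too_small(self):
        m = replicate_matrix(
            [[1], [2], [5], [6], [7]], ["r1", "r1", "r2", "r2", "r2"]
        )
        rep = replicate_rsd(m)
        reasons = rep.entries.set_index("replicate_set")["excluded"]
        assert reasons["r1"] == "set_too_small"
        assert reasons["r2"] is None

    def test_zero_in_original_rule_uses_pre_correction_values(self):
        orig = replicate_matrix([[0], [2], [3]], ["r1"] * 3)
        corr = replicate_matrix([[1], [2], [3]], ["r1"] * 3)
        with pytest.raises(EvaluationError):
            # the only entry is excluded -> nothing to average
            replicate_rsd(corr, original=orig)

    def test_all_zero_corrected_excluded(self):
        orig = replicate_matrix([[1, 5], [2, 6], [3, 7]], ["r1"] * 3)
        corr = replicate_matrix([[0, 5], [0, 6], [0, 7]], ["r1"] * 3)
        rep = replicate_rsd(corr, original=orig)
        reasons = rep.entries.set_index("feature_id")["excluded"]
        assert reasons["F1"] == "all_zero_corrected"
        assert rep.n_included == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(1, 100, size=(12, 8))
        sets = ["r1"] * 3 + ["r2"] * 3 + ["r3"] * 4 + [None, None]
        m = replicate_matrix(vals, sets)
        rep = replicate_rsd(m)
        # naive loop-and-accumulate recomputation
        acc, cnt = 0.0, 0
        for j in range(8):
            grand = vals[:, j].mean()  # all observations are experimental
            for s in ("r1", "r2", "r3"):
                rows = [i for i, lab in enumerate(sets) if lab == s]
                sd = np.std([vals[i, j] for i in rows], ddof=1)
                acc += sd / grand
                cnt += 1
        assert rep.mean_rsd == pytest.approx(acc / cnt, abs=1e-12)

    def test_invariant_to_feature_order_and_scale(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(1, 10, size=(6, 5))
        sets = ["r1"] * 3 + ["r2"] * 3
        m = replicate_matrix(vals, sets)
        base = replicate_rsd(m).mean_rsd
        perm = rng.permutation(5)
        m2 = replicate_matrix(vals[:, perm], sets)
        assert replicate_rsd(m2).mean_rsd == pytest.approx(base, rel=1e-12)
        vals3 = vals.copy()
        vals3[:, 2] *= 41.0
        m3 = replicate_matrix(vals3, sets)
        assert replicate_rsd(m3).mean_rsd == pytest.approx(base, rel=1e-12)

    def test_set_grand_mean_switch(self):
        vals = np.array([[2.0], [4.0], [6.0], [100.0]])
        m = replicate_matrix(vals, ["r1"] * 3 + [None])
        by_exp = replicate_rsd(m, grand_mean="experimental")
        by_set = replicate_rsd(m, grand_mean="set")
        sd = np.std([2, 4, 6], ddof=1)
        assert by_exp.mean_rsd == pytest.approx(sd / 28.0)
        assert by_set.mean_rsd == pytest.approx(sd / 4.0)

    def test_no_replicate_sets_is_error(self):
        m = make_matrix(np.ones((3, 1)), [1] * 3, ["experimental"] * 3)
        with pytest.raises(EvaluationError):
            replicate_rsd(m)

    def test_qc_rsd_diagnostic(self):
        vals = np.array([[10.0], [12.0], [14.0], [99.0]])
        m = make_matrix(vals, [1] * 4, ["QC", "QC", "QC", "experimental"])
        out = qc_rsd(m)
        assert out.iloc[0] == pytest.approx(np.std([10, 12, 14], ddof=1) / 12)


class TestPca:
    def test_duplicated_rows_have_identical_scores(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(6, 4))
        X = np.vstack([X, X[2]])
        X = np.abs(X)
        m = make_matrix(X, [1] * 7, ["experimental"] * 7)
        scores, _ = pca_scores(m, n_components=2)
        np.testing.assert_allclose(scores[2], scores[6], atol=1e-10)

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(15)
        X = np.abs(rng.normal(5, 1, size=(10, 6)))
        m = make_matrix(X, [1] * 10, ["experimental"] * 10)
        _, explained = pca_scores(m, n_components=6)
        assert explained.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_scores_match_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(16)
        X = np.abs(rng.normal(10, 2, size=(12, 5)))
        m = make_matrix(X, [1] * 12, ["experimental"] * 12)
        scores, _ = pca_scores(m, n_components=2)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        oracle = (U * S)[:, :2]
        for c in range(2):
            match = min(
                np.max(np.abs(scores[:, c] - oracle[:, c])),
                np.max(np.abs(scores[:, c] + oracle[:, c])),
            )
            assert match < 1e-8

    def test_too_many_components_rejected(self):
        m = make_matrix(np.abs(np.random.default_rng(0).normal(5, 1, (4, 3))),
                        [1] * 4, ["experimental"] * 4)
        with pytest.raises(ParameterError):
            pca_scores(m, n_components=4)


class TestManova:
    def test_single_column_reduces_to_anova_f(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        F, p = manova_f(y[:, None], labels)
        F_ref, p_ref = stats.f_oneway(y[:10], y[10:20], y[20:])
        assert F == pytest.approx(F_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_two_groups_matches_hotelling_t2_transform(self):
        rng = np.random.default_rng(18)
        Y = rng.normal(size=(24, 2))
        Y[12:] += 0.8
        labels = np.repeat(["a", "b"], 12)
        F, p = manova_f(Y, labels)
        # Hotelling T^2 oracle
        n1 = n2 = 12
        d = Y[:12].mean(axis=0) - Y[12:].mean(axis=0)
        S_pooled = (
            np.cov(Y[:12].T, ddof=1) * (n1 - 1) + np.cov(Y[12:].T, ddof=1) * (n2 - 1)
        ) / (n1 + n2 - 2)
        t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(S_pooled, d)
        F_ref = t2 * (n1 + n2 - 3) / (2 * (n1 + n2 - 2))
        p_ref = stats.f.sf(F_ref, 2, n1 + n2 - 3)
        assert F == pytest.approx(F_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_matches_statsmodels_wilks_for_many_groups(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(19)
        Y = rng.normal(size=(70, 2))
        labels = np.repeat([f"g{i}" for i in range(7)], 10)
        F, p = manova_f(Y, labels)
        df = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1], "g": labels})
        res = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
        tab = res.results["g"]["stat"]
        assert F == pytest.approx(float(tab.loc["Wilks' lambda", "F Value"]), rel=1e-8)
        assert p == pytest.approx(float(tab.loc["Wilks' lambda", "Pr > F"]), abs=1e-10)

    def test_permuted_labels_give_uniform_p(self):
        rng = np.random.default_rng(20)
        Y = rng.normal(size=(60, 2))
        labels = np.repeat(["a", "b"], 30)
        pvals = []
        for _ in range(500):
            perm = rng.permutation(labels)
            pvals.append(manova_f(Y, perm)[1])
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.05

    def test_one_group_is_error(self):
        with pytest.raises(EvaluationError):
            manova_f(np.random.default_rng(0).normal(size=(6, 2)), ["a"] * 6)


class TestPcaManova:
    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(21)
        exceed = 0
        n_sim = 200
        for _ in range(n_sim):
            X = np.abs(rng.normal(10, 2, size=(24, 12)))
            groups = list(np.repeat(["C", "D"], 12))
            m = make_matrix(X, [1] * 24, ["experimental"] * 24, groups=groups)
            rep = pca_manova(m, grouping="group", groups_to_compare=["C", "D"])
            crit = stats.f.ppf(0.95, *rep.df)
            exceed += rep.f_stat > crit
        assert exceed / n_sim < 0.12  # ~5 % nominal

    def test_power_on_large_shift(self):
        rng = np.random.default_rng(22)
        X = np.abs(rng.normal(10, 1, size=(30, 20)))
        X[15:, :12] *= 2.0
        groups = list(np.repeat(["C", "D"], 15))
        m = make_matrix(X, [1] * 30, ["experimental"] * 30, groups=groups)
        rep = pca_manova(m, grouping="group", groups_to_compare=["C", "D"])
        assert rep.p_value < 0.01

    def test_identical_labels_error(self):
        X = np.abs(np.random.default_rng(1).normal(5, 1, (10, 4)))
        m = make_matrix(X, [1] * 10, ["experimental"] * 10, groups=["C"] * 10)
        with pytest.raises(EvaluationError):
            pca_manova(m, grouping="group")

    def test_batch_grouping_excludes_qcs(self, small_run):
        ws, _ = small_run
        rep = pca_manova(ws, grouping="batch")
        assert sum(rep.group_sizes.values()) == int(ws.experimental_mask.sum())
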