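import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurograd.gradients import GradientSet
from neurograd.stats import (
    CANONICAL_NETWORKS,
    NetworkPartition,
    SubjectRecord,
    classify,
    delta_clinical,
    delta_features,
    fdr_bh,
    network_scores,
    partial_correlation,
    roiwise_compare,
)
from oracles import bh_stepup


def _gs(scores, roi_ids):
    scores = np.atleast_2d(np.asarray(scores, float)).T
    k = scores.shape[1]
    lam = np.linspace(0.9, 0.5, k)
    return GradientSet(scores, lam, lam / lam.sum(), roi_ids=tuple(roi_ids))


def _partition(mapping):
    labels = tuple(dict.fromkeys(mapping.values()))
    return NetworkPartition(mapping, labels)


class TestNetworkScores:
    def test_constant_scores(self):
        part = _partition({"a": "VIS", "b": "VIS", "c": "DMN"})
        s = network_scores(_gs([2.0, 2.0, 2.0], ["a", "b", "c"]), part)
        assert (s == 2.0).all()

    def test_two_network_example(self):
        part = _partition({"a": "VIS", "b": "VIS", "c": "DMN"})
        s = network_scores(_gs([1.0, 3.0, 5.0], ["a", "b", "c"]), part)
        assert s["VIS"] == 2.0 and s["DMN"] == 5.0

    def test_groupby_oracle(self, rng):
        n = 60
        roi_ids = [f"R{i}" for i in range(n)]
        nets = rng.choice(list(CANONICAL_NETWORKS), n)
        while len(set(nets)) < 7:
            nets = rng.choice(list(CANONICAL_NETWORKS), n)
        part = NetworkPartition(dict(zip(roi_ids, nets)))
        vals = rng.standard_normal(n)
        s = network_scores(_gs(vals, roi_ids), part)
        expected = pd.Series(vals).groupby(pd.Series(list(nets))).mean()
        for net in part.labels:
            assert s[net] == pytest.approx(expected[net])


class TestRoiwiseCompare:
    def test_identical_paired_groups(self, rng):
        A = rng.standard_normal((10, 5))
        res = roiwise_compare(A, A.copy(), paired=True)
        assert (res.table["t"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_constant_nonzero_paired_difference_flagged(self):
        A = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        res = roiwise_compare(A, A + 1.0, paired=True)
        assert res.table["degenerate"].iloc[0]
        assert np.isnan(res.table["p"].iloc[0])

    def test_planted_shift_power(self, rng):
        # 1-SD shift in 20 of 100 ROIs, n=40/group: BH-FDR should find most
        hits = 0
        total = 0
        for _ in range(100):
            A = rng.standard_normal((40, 100))
            B = rng.standard_normal((40, 100))
            B[:, :20] += 1.0
            res = roiwise_compare(A, B, paired=False, q=0.05)
            hits += int(res.table["reject"][:20].sum())
            total += 20
        assert hits / total >= 0.80

    def test_welch_matches_scipy_single_roi(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.5
        res = roiwise_compare(a[:, None], b[:, None], paired=False)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.table["t"].iloc[0] == pytest.approx(t)
        assert res.table["p"].iloc[0] == pytest.approx(p)

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            roiwise_compare(rng.standard_normal((2, 4)), rng.standard_normal((5, 4)))


class TestFdrBH:
    def test_worked_stepup_example(self):
        p_adj, reject = fdr_bh([0.01, 0.02, 0.04, 0.05], q=0.05)
        assert reject.all()  # p_(4) = .05 <= 4*.05/4

    def test_all_ones_rejects_none(self):
        _, reject = fdr_bh(np.ones(10), q=0.05)
        assert not reject.any()

    def test_adjusted_monotone_after_sorting(self, rng):
        p = rng.uniform(size=50)
        p_adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()
        assert (p_adj >= p - 1e-12).all()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 40))
            p_adj, reject = fdr_bh(p, q=0.05)
            adj_o, rej_o = bh_stepup(p, 0.05)
            np.testing.assert_allclose(p_adj, np.minimum(adj_o, 1.0), atol=1e-12)
            np.testing.assert_array_equal(reject, rej_o)

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            fdr_bh([0.2, 1.4])


class TestClassify:
    def test_perfect_separation(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"f": y * 10.0 + rng.normal(0, 1.0, n) * 0.1})
        rep = classify(X, y, n_folds=5, seed=0)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0

    def test_permuted_labels_near_chance(self, rng):
        # balanced design: chance accuracy is 0.5 with a binomial band
        n = 110
        X = pd.DataFrame(rng.standard_normal((n, 6)))
        accs = [
            classify(X, rng.permutation(np.repeat([0, 1], n // 2)),
                     n_folds=5, seed=s).accuracy
            for s in range(5)
        ]
        half_width = 1.96 * np.sqrt(0.25 / n)
        assert abs(np.mean(accs) - 0.5) < half_width

    def test_permuted_labels_auc_near_half_imbalanced(self, rng):
        # with a 34/76 imbalance chance accuracy is the majority rate,
        # so the chance-level check uses AUC, which is imbalance-free
        X = pd.DataFrame(rng.standard_normal((110, 6)))
        aucs = [
            classify(X, rng.permutation(np.repeat([0, 1], [34, 76])),
                     n_folds=5, seed=s).auc
            for s in range(10)
        ]
        # null AUC sd ~ sqrt((n1+n2+1)/(12 n1 n2)) = 0.06; mean of 10 draws
        assert abs(np.mean(aucs) - 0.5) < 2.58 * 0.06 / np.sqrt(10)

    def test_single_class_fold_raises(self, rng):
        X = pd.DataFrame(rng.standard_normal((8, 2)))
        y = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="folds"):
            classify(X, y, n_folds=5)

    def test_roc_points_monotone(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(rng.standard_normal((n, 3)) + y[:, None])
        rep = classify(X, y, n_folds=4, seed=1)
        assert (np.diff(rep.roc_points[:, 0]) >= 0).all()
        assert (np.diff(rep.roc_points[:, 1]) >= 0).all()


class TestDeltas:
    part = _partition({"a": "VIS", "b": "DMN"})

    def test_pre_equals_post_gives_zero(self, rng):
        gs = _gs([0.3, -0.7], ["a", "b"])
        d = delta_features(gs, gs.with_scores(gs.scores.copy()), self.part)
        assert (d == 0).all()

    def test_absolute_value_rule(self):
        pre = _gs([-0.4, -0.4], ["a", "b"])
        post = _gs([0.1, 0.1], ["a", "b"])
        d = delta_features(pre, post, self.part)
        assert d["VIS"] == pytest.approx(0.4 - 0.1)

    def test_delta_clinical(self):
        rec = SubjectRecord("p1", "patient", 60.0, 1, updrs3_pre=31.0, updrs3_post=28.0)
        assert delta_clinical(rec) == 3.0
        with pytest.raises(ValueError, match="missing"):
            delta_clinical(SubjectRecord("c1", "control", 60.0, 0))


class TestPartialCorrelation:
    def test_identity_gives_one(self, rng):
        x = rng.standard_normal(30)
        res = partial_correlation(x, x.copy())
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_equals_plain_pearson_without_covariates(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = partial_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p, rel=1e-6)

    def test_shared_age_effect_removed(self, rng):
        n = 500
        age = rng.uniform(40, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        x = 0.05 * age + rng.standard_normal(n)
        y = -0.03 * age + rng.standard_normal(n)
        res = partial_correlation(x, y, np.column_stack([age, sex]))
        assert abs(res.r) < 0.1

    def test_planted_residual_correlation_recovered(self, rng):
        # r = 0.5 planted on top of covariate effects, n = 76 per replicate
        rs = []
        for _ in range(10):
            n = 76
            age = rng.uniform(40, 80, n)
            sex = rng.integers(0, 2, n).astype(float)
            u = rng.standard_normal(n)
            v = rng.standard_normal(n)
            x = 0.02 * age + u
            y = 0.5 * sex + 0.5 * u + np.sqrt(0.75) * v  # corr(u, .5u+.866v) = 0.5
            rs.append(partial_correlation(x, y, np.column_stack([age, sex])).r)
        assert abs(np.mean(rs) - 0.5) < 0.15

    def test_rank_deficient_raises(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        cov = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, cov)
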