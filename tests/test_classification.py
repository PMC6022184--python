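import math

import numpy as np
import pytest

from svhiston import (
    SubjectRecord,
    confusion_metrics,
    fit_pca,
    make_splits,
    mcnemar_compare,
    metrics_from_predictions,
    run_split_protocol,
    train_svm,
    voxel_baseline,
)
from svhiston.classification import select_scree


def _cohort(n_ad, n_cn, seed=0):
    rng = np.random.default_rng(seed)
    subjects = []
    for cls, count in (("AD", n_ad), ("CN", n_cn)):
        for i in range(count):
            subjects.append(
                SubjectRecord(f"{cls}{i}", cls, float(rng.integers(60, 91)),
                              "M" if i % 2 == 0 else "F")
            )
    return subjects


class TestMakeSplits:
    def test_balanced_cohort_test_counts(self):
        subjects = _cohort(50, 50)
        plan = make_splits(subjects, n_splits=10, test_frac=0.2, seed=1)
        labels = np.array([s.label for s in subjects])
        for train, test in plan.splits:
            assert len(test) == 20
            n_ad = int(np.sum(labels[test] == "AD"))
            assert abs(n_ad - 10) <= 1
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 100

    def test_deterministic_given_seed(self):
        subjects = _cohort(20, 20)
        a = make_splits(subjects, seed=9)
        b = make_splits(subjects, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(te1, te2)

    @pytest.mark.parametrize("seed", range(20))
    def test_gender_proportions_preserved(self, seed):
        """On a 139-subject cohort, per-split gender counts in the test set
        stay within one subject of the globally proportional count."""
        rng = np.random.default_rng(seed)
        subjects = []
        for i in range(139):
            cls = "AD" if i < 60 else "CN"
            subjects.append(
                SubjectRecord(f"s{i}", cls, float(rng.integers(60, 91)),
                              "M" if rng.random() < 0.4 else "F")
            )
        plan = make_splits(subjects, n_splits=10, test_frac=0.2, seed=seed)
        genders = np.array([s.gender for s in subjects])
        labels = np.array([s.label for s in subjects])
        global_m_frac = np.mean(genders == "M")
        for _, test in plan.splits:
            n_m = int(np.sum(genders[test] == "M"))
            assert abs(n_m - global_m_frac * len(test)) <= 1 + 1e-9
            n_ad = int(np.sum(labels[test] == "AD"))
            assert abs(n_ad - (60 / 139) * len(test)) <= 1 + 1e-9

    def test_single_subject_stratum_collapses(self, caplog):
        subjects = _cohort(6, 6)
        subjects[0] = SubjectRecord("odd", "AD", 60.0, "F")  # lone (AD,F,60s)?
        plan = make_splits(subjects, n_splits=2, seed=0)  # must not raise
        assert len(plan.splits) == 2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_splits(_cohort(4, 4))


class TestPca:
    def test_planar_data_two_components_explain_everything(self, rng):
        basis = rng.normal(size=(2, 768))
        coords = rng.normal(size=(30, 2)) * [5, 2]
        X = coords @ basis + 3.0
        model = fit_pca(X, n_components=2)
        total = model.explained_variance.sum()
        # project and reconstruct variance: first 2 PCs carry all variance
        full = fit_pca(X, n_components=min(29, 768))
        np.testing.assert_allclose(total, full.explained_variance.sum(), rtol=1e-8)
        assert full.explained_variance[2:].max() < 1e-16 * total

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(20, 50))
        model = fit_pca(X, n_components=5)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_total_variance_conserved(self, rng):
        X = rng.normal(size=(25, 40))
        model = fit_pca(X, n_components=24)
        Z = (X[:, model.keep] - model.mean) / model.scale
        total_var = (Z**2).sum() / X.shape[0]
        np.testing.assert_allclose(model.explained_variance.sum(), total_var,
                                   rtol=1e-10)

    def test_duplicate_columns_variance_unchanged(self, rng):
        X = rng.normal(size=(20, 10))
        X_dup = np.concatenate([X, X[:, :3]], axis=1)
        a = fit_pca(X, n_components=9)
        b = fit_pca(X_dup, n_components=13)
        # standardized duplicate columns double their variance contribution;
        # eigenvalue ordering is preserved and nothing is lost or invented
        assert b.explained_variance[0] >= a.explained_variance[0]
        assert (b.explained_variance >= -1e-12).all()
        np.testing.assert_allclose(
            b.explained_variance.sum(), 13.0, rtol=1e-10
        )  # 13 standardized columns -> total variance 13

    def test_scree_selection_finds_elbow(self):
        ev = np.array([10.0, 8.0, 6.0, 1.0, 0.9, 0.8, 0.7, 0.6])
        # differences: 2,2,5,.1,.1,.1,.1 -> biggest flattening after comp 3
        assert select_scree(ev) == 3
        assert select_scree(np.ones(2)) == 2  # degenerate: fallback clamped

    def test_fewer_than_three_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(2, 10)))


class TestSvm:
    def test_separable_toy_set_zero_training_errors(self):
        X = np.array([[0, 0], [0, 1], [5, 5], [5, 6]], dtype=float)
        y = np.array(["CN", "CN", "AD", "AD"])
        clf = train_svm(X, y, kernel="linear", cost=1.0)
        assert (clf.predict(X) == y).all()

    def test_deterministic_decision_values(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.where(rng.random(30) < 0.5, "AD", "CN")
        if len(set(y)) < 2:
            y[0] = "AD" if y[0] == "CN" else "CN"
        a = train_svm(X, y).decision_function(X)
        b = train_svm(X, y).decision_function(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_svm(rng.normal(size=(5, 2)), ["AD"] * 5)

    @pytest.mark.parametrize("kernel", ["linear", "polynomial", "radial"])
    def test_all_three_kernels_run(self, kernel, rng):
        X = rng.normal(size=(20, 4))
        y = np.array(["AD", "CN"] * 10)
        clf = train_svm(X, y, kernel=kernel)
        assert set(clf.predict(X)) <= {"AD", "CN"}


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,expected",
        [
            # all correct
            (10, 10, 0, 0, dict(Acc=1, Bacc=1, NPV=1, PPV=1, Sen=1, Spe=1, Fscore=1)),
            # worked example: Sen=.8, Spe=.7
            (8, 7, 3, 2, dict(Acc=0.75, Bacc=0.75, NPV=7/9, PPV=8/11,
                              Sen=0.8, Spe=0.7, Fscore=2*(0.8*8/11)/(0.8+8/11))),
            # all wrong
            (0, 0, 10, 10, dict(Acc=0, Bacc=0, Sen=0, Spe=0)),
            # perfectly specific, insensitive
            (0, 10, 0, 10, dict(Acc=0.5, Sen=0, Spe=1, Bacc=0.5, NPV=0.5)),
            # perfectly sensitive, unspecific
            (10, 0, 10, 0, dict(Acc=0.5, Sen=1, Spe=0, Bacc=0.5, PPV=0.5)),
            (5, 5, 5, 5, dict(Acc=0.5, Bacc=0.5, Sen=0.5, Spe=0.5)),
            (9, 1, 9, 1, dict(Acc=0.5, Sen=0.9, Spe=0.1, Bacc=0.5, PPV=0.5)),
            (1, 99, 1, 9, dict(Sen=0.1, Spe=0.99, PPV=0.5, Acc=100/110)),
            (3, 2, 1, 0, dict(Sen=1.0, Spe=2/3, PPV=0.75, NPV=1.0, Acc=5/6)),
            (0, 12, 4, 0, dict(Sen=math.nan, Spe=0.75)),  # no positives in test
        ],
    )
    def test_formulas_match_hand_computation(self, tp, tn, fp, fn, expected):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rep = confusion_metrics(tp, tn, fp, fn)
        for name, val in expected.items():
            got = getattr(rep, name)
            if isinstance(val, float) and math.isnan(val):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(val), name

    def test_zero_denominator_flagged_not_zero(self):
        with pytest.warns(UserWarning, match="PPV undefined"):
            rep = confusion_metrics(0, 10, 0, 5)
        assert math.isnan(rep.PPV)

    def test_bacc_is_mean_of_sen_spe(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 20, 4)
            rep = confusion_metrics(int(tp), int(tn), int(fp), int(fn))
            assert rep.Bacc == pytest.approx((rep.Sen + rep.Spe) / 2)
            assert min(rep.Sen, rep.Spe) <= rep.Acc <= max(rep.Sen, rep.Spe)


class TestMcNemar:
    def test_closed_form_balanced_discordance(self):
        truth = np.array(["AD"] * 20)
        pred_a = truth.copy(); pred_b = truth.copy()
        pred_b[:5] = "CN"   # a correct, b wrong: b=5
        pred_a[5:10] = "CN"  # a wrong, b correct: c=5
        out = mcnemar_compare(pred_a, pred_b, truth)
        assert out["b"] == 5 and out["c"] == 5
        assert out["statistic"] == pytest.approx((abs(0) - 1) ** 2 / 10)  # 0.1

    def test_closed_form_one_sided_discordance(self):
        truth = np.array(["AD"] * 12)
        pred_a = truth.copy()
        pred_b = truth.copy(); pred_b[:10] = "CN"  # b=10, c=0
        out = mcnemar_compare(pred_a, pred_b, truth)
        assert out["statistic"] == pytest.approx(8.1)

    def test_no_discordance_p_one(self):
        truth = np.array(["AD", "CN"] * 3)
        out = mcnemar_compare(truth, truth, truth)
        assert out["p_value"] == 1.0

    def test_matches_statsmodels_continuity_corrected(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        truth = np.where(rng.random(60) < 0.5, "AD", "CN")
        pred_a = np.where(rng.random(60) < 0.2, "CN", truth)
        pred_b = np.where(rng.random(60) < 0.3, "AD", truth)
        out = mcnemar_compare(pred_a, pred_b, truth)
        a_ok = pred_a == truth
        b_ok = pred_b == truth
        table = [
            [int(np.sum(a_ok & b_ok)), int(np.sum(a_ok & ~b_ok))],
            [int(np.sum(~a_ok & b_ok)), int(np.sum(~a_ok & ~b_ok))],
        ]
        ref = sm_mcnemar(table, exact=False, correction=True)
        assert out["statistic"] == pytest.approx(ref.statistic)
        assert out["p_value"] == pytest.approx(ref.pvalue)

    def test_exact_mode_matches_binomial(self):
        truth = np.array(["AD"] * 10)
        pred_a = truth.copy()
        pred_b = truth.copy(); pred_b[:3] = "CN"
        out = mcnemar_compare(pred_a, pred_b, truth, exact=True)
        from scipy import stats
        assert out["p_value"] == pytest.approx(stats.binomtest(0, 3, 0.5).pvalue)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_compare(["AD"], ["AD", "CN"], ["AD", "CN"])


class TestNoLeakage:
    def test_perturbing_test_rows_leaves_fitted_model_unchanged(self, rng):
        """Scaling, PCA and SVM must depend on training rows only."""
        X = rng.normal(size=(40, 30))
        labels = np.array(["AD", "CN"] * 20)
        subjects = _cohort(20, 20)
        plan = make_splits(subjects, n_splits=3, seed=4)
        X2 = X.copy()
        # perturb rows that are in the test set of the first split
        first_test = plan.splits[0][1]
        X2[first_test] += rng.normal(size=(len(first_test), 30)) * 100
        pca1 = fit_pca(X[plan.splits[0][0]], n_components=4)
        pca2 = fit_pca(X2[plan.splits[0][0]], n_components=4)
        np.testing.assert_array_equal(pca1.components, pca2.components)
        clf1 = train_svm(pca1.transform(X[plan.splits[0][0]]),
                         labels[plan.splits[0][0]])
        clf2 = train_svm(pca2.transform(X2[plan.splits[0][0]]),
                         labels[plan.splits[0][0]])
        np.testing.assert_array_equal(clf1.dual_coef_, clf2.dual_coef_)


class TestVoxelBaseline:
    def test_separable_cohort_above_chance(self, rng):
        n = 40
        X = rng.normal(size=(n, 100))
        labels = np.array(["AD", "CN"] * 20)
        X[labels == "AD"] += 1.0  # class shift
        out = voxel_baseline(X[:30], labels[:30], X[30:], labels[30:], seed=0)
        assert out["report"].Bacc > 0.5

    def test_leakage_guard_identical_subject(self, rng):
        X = rng.normal(size=(20, 10))
        labels = np.array(["AD", "CN"] * 10)
        with pytest.raises(ValueError, match="identical"):
            voxel_baseline(X, labels, X[:2], labels[:2], seed=0)

    def test_tie_goes_to_smallest_cost(self, rng):
        """On trivially separable data every cost achieves Bacc 1; the grid
        search must return the smallest cost."""
        X = np.vstack([rng.normal(size=(15, 3)) + 10,
                       rng.normal(size=(15, 3)) - 10])
        labels = np.array(["AD"] * 15 + ["CN"] * 15)
        test_X = np.vstack([rng.normal(size=(2, 3)) + 10,
                            rng.normal(size=(2, 3)) - 10])
        out = voxel_baseline(X, labels, test_X, ["AD", "AD", "CN", "CN"], seed=1)
        assert out["cost"] == 2.0**-5
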