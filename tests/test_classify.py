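import numpy as np
import pytest

from eegsq.classify import (
    CVReport,
    GaussianLDA,
    OvOSVM,
    SVMSpec,
    anova_accuracy,
    cross_validate,
    lda_fit_predict,
    svm_ovo_fit,
    svm_ovo_predict,
)
from eegsq.containers import FeatureDescriptor, FeatureMatrix


def _fm(X, y):
    n, p = X.shape
    descs = [FeatureDescriptor("DASM", ("F3", "F4"), "alpha", f"b{j}") for j in range(p)]
    return FeatureMatrix(
        values=X, descriptors=descs, labels=y, order=np.arange(n), block=np.arange(n) // 5
    )


def _three_blobs(rng, n_per=60, sep=4.0, dim=2):
    centers = sep * np.array([[1, 0], [-0.5, 0.87], [-0.5, -0.87]])
    X = np.vstack([c + rng.standard_normal((n_per, 2)) for c in centers])
    if dim > 2:
        X = np.hstack([X, rng.standard_normal((3 * n_per, dim - 2))])
    y = np.repeat([-1, 0, 1], n_per)
    return X, y


class TestGaussianLDA:
    def test_well_separated_gaussians_near_perfect(self, rng):
        Xtr = np.concatenate([rng.normal(-5, 1, 400), rng.normal(5, 1, 400)])[:, None]
        ytr = np.repeat([-1, 1], 400)
        Xte = np.concatenate([rng.normal(-5, 1, 200), rng.normal(5, 1, 200)])[:, None]
        yte = np.repeat([-1, 1], 200)
        acc = np.mean(lda_fit_predict(Xtr, ytr, Xte) == yte)
        assert acc > 0.99  # ~5 sigma separation; binomial bound

    def test_equidistant_tie_goes_to_lowest_label(self, rng):
        Xtr = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        ytr = np.array([0, 0, 1, 1])
        pred = lda_fit_predict(Xtr, ytr, np.array([[0.0]]))
        assert pred[0] == 0

    def test_matches_density_oracle_1d(self, rng):
        Xtr = np.concatenate([rng.normal(-1, 1, 300), rng.normal(2, 1, 300)])[:, None]
        ytr = np.repeat([-1, 1], 300)
        model = GaussianLDA().fit(Xtr, ytr)
        Xte = rng.uniform(-4, 5, 200)[:, None]
        # oracle: explicit Gaussian densities with the pooled variance
        var = np.concatenate(
            [Xtr[ytr == -1] - Xtr[ytr == -1].mean(), Xtr[ytr == 1] - Xtr[ytr == 1].mean()]
        ).var(ddof=2)
        mu = {c: Xtr[ytr == c].mean() for c in (-1, 1)}
        ll = {
            c: -0.5 * (Xte[:, 0] - mu[c]) ** 2 / var + np.log(0.5) for c in (-1, 1)
        }
        oracle = np.where(ll[-1] >= ll[1], -1, 1)
        assert np.mean(model.predict(Xte) == oracle) > 0.995

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            GaussianLDA().fit(rng.standard_normal((10, 2)), np.zeros(10))


class TestOvOSVM:
    def test_three_classes_three_machines(self, rng):
        X, y = _three_blobs(rng)
        model = svm_ovo_fit(X, y)
        assert model.n_machines == 3
        assert set(model.machines_) == {(-1, 0), (-1, 1), (0, 1)}

    def test_separable_toy_training_accuracy_100(self, rng):
        X, y = _three_blobs(rng, sep=30.0)
        model = svm_ovo_fit(X, y, SVMSpec(C=10.0, gamma=0.1))
        assert np.mean(svm_ovo_predict(model, X) == y) == 1.0

    def test_deep_interior_point_wins_all_contests(self, rng):
        X, y = _three_blobs(rng, sep=10.0)
        model = svm_ovo_fit(X, y, SVMSpec(C=10.0, gamma=0.5))
        x = X[y == 1].mean(axis=0, keepdims=True)
        dec = model.decision_values(x)
        assert dec[(-1, 1)][0] > 0  # favors 1
        assert dec[(0, 1)][0] > 0  # favors 1
        assert svm_ovo_predict(model, x)[0] == 1

    def test_agreement_with_per_pair_oracle(self, rng):
        X, y = _three_blobs(rng, sep=2.0, dim=4)
        model = svm_ovo_fit(X, y, SVMSpec(C=1.0, gamma=0.2))
        Xte = rng.standard_normal((30, 4)) * 3
        dec = model.decision_values(Xte)
        # oracle: independent vote count + summed decision values
        classes = [-1, 0, 1]
        preds = []
        for i in range(30):
            votes = {c: 0 for c in classes}
            score = {c: 0.0 for c in classes}
            for (a, b), d in dec.items():
                winner = b if d[i] > 0 else a
                votes[winner] += 1
                score[a] -= d[i]
                score[b] += d[i]
            preds.append(max(classes, key=lambda c: (votes[c], score[c], -c)))
        assert np.array_equal(svm_ovo_predict(model, Xte), np.array(preds))

    def test_feature_count_mismatch_rejected(self, rng):
        X, y = _three_blobs(rng)
        model = svm_ovo_fit(X, y)
        with pytest.raises(ValueError, match="feature count"):
            svm_ovo_predict(model, rng.standard_normal((5, 3)))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            svm_ovo_fit(rng.standard_normal((10, 2)), np.ones(10))

    def test_rbf_kernel_unit_at_zero_distance(self, rng):
        # K(x, x) = exp(0) = 1: a support vector evaluated at itself
        from sklearn.metrics.pairwise import rbf_kernel

        x = rng.standard_normal((1, 4))
        assert rbf_kernel(x, x, gamma=0.37)[0, 0] == pytest.approx(1.0)


class TestCrossValidate:
    def test_shuffled_labels_at_chance(self, rng):
        X, y = _three_blobs(rng, n_per=100, sep=4.0)
        y_shuffled = rng.permutation(y)
        rep = cross_validate(_fm(X, y_shuffled), "svm", SVMSpec(C=1.0, gamma=0.1), seed=0)
        n = len(y)
        half_width = 1.96 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(rep.mean_accuracy / 100 - 1 / 3) < half_width + 0.05

    def test_folds_preserve_class_proportions(self, rng):
        X, y = _three_blobs(rng, n_per=50)
        rep = cross_validate(_fm(X, y), "lda", seed=1)
        # confusion row sums = per-class totals; 5 folds of 30 -> 10 per class
        assert rep.confusion.sum() == 150
        assert list(rep.confusion.sum(axis=1)) == [50, 50, 50]

    def test_same_seed_identical_report(self, rng):
        X, y = _three_blobs(rng, sep=1.5)
        a = cross_validate(_fm(X, y), "svm", SVMSpec(C=1.0, gamma=0.1), seed=3)
        b = cross_validate(_fm(X, y), "svm", SVMSpec(C=1.0, gamma=0.1), seed=3)
        assert a.fold_accuracies == b.fold_accuracies
        assert np.array_equal(a.confusion, b.confusion)

    def test_mean_is_average_of_folds(self, rng):
        X, y = _three_blobs(rng)
        rep = cross_validate(_fm(X, y), "lda", seed=0)
        assert rep.mean_accuracy == pytest.approx(100 * np.mean(rep.fold_accuracies))

    def test_small_class_rejected(self, rng):
        X = rng.standard_normal((13, 2))
        y = np.array([-1] * 4 + [0] * 4 + [1] * 5)
        with pytest.raises(ValueError, match="fewer than 5"):
            cross_validate(_fm(X, y), "lda", seed=0)

    def test_grid_search_selects_from_grid(self, rng):
        X, y = _three_blobs(rng, n_per=30)
        grid = ((0.5, 8.0), (0.05, 0.5))
        rep = cross_validate(_fm(X, y), "svm", SVMSpec(grid=grid), seed=0)
        for spec in rep.chosen_params:
            assert spec.C in grid[0]
            assert spec.gamma in grid[1]


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.5
        from scipy import stats

        f, p = anova_accuracy([a, b])
        t, pt = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_hand_computed_toy_table(self):
        # groups {1,2,3}, {2,3,4}: grand mean 2.5, SSB = 3/2, SSW = 4
        f, p = anova_accuracy([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        ssb, ssw, df_b, df_w = 1.5, 4.0, 1, 4
        assert f == pytest.approx((ssb / df_b) / (ssw / df_w), rel=1e-12)

    def test_degenerate_all_equal(self):
        assert anova_accuracy([[1.0, 1.0], [1.0, 1.0]]) == (0.0, 1.0)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_accuracy([[1.0, 2.0]])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 values"):
            anova_accuracy([[1.0], [2.0, 3.0]])
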