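"""LS-SVM training, kernels, multiclass coding, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hoseeg as h


GAUSS = h.KernelSpec(kind="gaussian_rbf", sigma=0.5)


class TestKernels:
    def test_gaussian_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 3.0])
        assert h.kernel_eval(GAUSS, x, x) == pytest.approx(1.0)

    def test_polynomial_degree_one_offset_zero_is_inner_product(self):
        spec = h.KernelSpec(kind="polynomial", degree=1, offset=0.0)
        x, z = np.array([1.0, 2.0]), np.array([3.0, -1.0])
        assert h.kernel_eval(spec, x, z) == pytest.approx(x @ z)

    def test_gaussian_gram_matrix_is_psd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (10, 4))
        K = h.kernel_eval(h.KernelSpec(kind="gaussian_rbf", sigma=1.3), X, X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            h.kernel_eval(GAUSS, np.ones(3), np.ones(4))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            h.KernelSpec(kind="gaussian_rbf", sigma=0.0)
        with pytest.raises(ValueError):
            h.KernelSpec(kind="polynomial", degree=0)


class TestLSSVMTrain:
    def test_two_separable_points(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = h.lssvm_train(X, y, gamma=10.0, kernel=GAUSS)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_xor_matches_independent_dense_solve(self):
        """Oracle: assemble and solve the 5×5 dual system explicitly."""
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        gamma, sigma = 100.0, 0.5
        model = h.lssvm_train(X, y, gamma=gamma,
                              kernel=h.KernelSpec(kind="gaussian_rbf", sigma=sigma))
        # independent construction
        K = np.array([[np.exp(-np.sum((a - b) ** 2) / sigma**2) for b in X] for a in X])
        A = np.zeros((5, 5))
        A[0, 1:], A[1:, 0] = y, y
        A[1:, 1:] = np.outer(y, y) * K + np.eye(4) / gamma
        sol = np.linalg.solve(A, np.array([0.0, 1, 1, 1, 1]))
        assert model.bias == pytest.approx(sol[0], abs=1e-10)
        np.testing.assert_allclose(model.alpha, sol[1:], atol=1e-10)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_dual_residual_small(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 3))
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        y[0], y[1] = 1.0, -1.0  # both classes present
        model = h.lssvm_train(X, y, gamma=50.0, kernel=GAUSS)
        K = h.kernel_eval(GAUSS, X, X)
        A = np.zeros((31, 31))
        A[0, 1:], A[1:, 0] = y, y
        A[1:, 1:] = np.outer(y, y) * K + np.eye(30) / 50.0
        sol = np.concatenate([[model.bias], model.alpha])
        rhs = np.concatenate([[0.0], np.ones(30)])
        rel = np.linalg.norm(A @ sol - rhs) / np.linalg.norm(rhs)
        assert rel <= 1e-8

    def test_conflicting_duplicate_gets_zero_decision(self):
        X = np.array([[0.0], [0.0]])
        y = np.array([1.0, -1.0])
        model = h.lssvm_train(X, y, gamma=0.01, kernel=GAUSS)
        assert model.decision_values(np.array([[0.0]]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_high_gamma_fits_separable_data_perfectly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([-1.0] * 20 + [1.0] * 20)
        model = h.lssvm_train(X, y, gamma=1e4,
                              kernel=h.KernelSpec(kind="gaussian_rbf", sigma=2.0))
        assert (model.predict(X) == y).all()

    def test_label_validation(self):
        with pytest.raises(ValueError, match="±1"):
            h.lssvm_train(np.ones((2, 1)), [0.0, 1.0], 1.0, GAUSS)
        with pytest.raises(ValueError, match="each class"):
            h.lssvm_train(np.ones((2, 1)), [1.0, 1.0], 1.0, GAUSS)


def blobs(rng, centers, n=20, sd=0.3):
    X = np.vstack([rng.normal(c, sd, (n, 2)) for c in centers])
    y = np.repeat([f"c{k}" for k in range(len(centers))], n)
    return X, y


class TestMulticlass:
    def test_k2_ovo_identical_to_binary_machine(self):
        rng = np.random.default_rng(3)
        X, y = blobs(rng, [(-2, 0), (2, 0)])
        kernel = h.KernelSpec(kind="gaussian_rbf", sigma=2.0)
        coding = h.ovo_scheme(("c0", "c1"))
        assert coding.n_machines == 1
        clf = h.MulticlassLSSVM(coding=coding, kernel=kernel, gamma=10.0).fit(X, y)
        binary = h.lssvm_train(X, np.where(y == "c0", 1.0, -1.0), 10.0, kernel)
        Xt = rng.normal(0, 2.5, (50, 2))
        ovo_pred = clf.predict(Xt)
        bin_pred = np.where(binary.predict(Xt) == 1, "c0", "c1")
        np.testing.assert_array_equal(ovo_pred, bin_pred)

    def test_k2_ecoc_identical_to_binary_machine(self):
        rng = np.random.default_rng(4)
        X, y = blobs(rng, [(-2, 0), (2, 0)])
        kernel = h.KernelSpec(kind="gaussian_rbf", sigma=2.0)
        clf = h.MulticlassLSSVM(coding=h.ecoc_scheme(("c0", "c1")),
                                kernel=kernel, gamma=10.0).fit(X, y)
        binary = h.lssvm_train(X, np.where(y == "c0", 1.0, -1.0), 10.0, kernel)
        Xt = rng.normal(0, 2.5, (50, 2))
        np.testing.assert_array_equal(
            clf.predict(Xt), np.where(binary.predict(Xt) == 1, "c0", "c1"))

    @pytest.mark.parametrize("make_coding", [h.ovo_scheme, h.ecoc_scheme])
    def test_three_separated_blobs_fully_classified(self, make_coding):
        rng = np.random.default_rng(5)
        X, y = blobs(rng, [(-4, 0), (4, 0), (0, 6)])
        Xt, yt = blobs(np.random.default_rng(6), [(-4, 0), (4, 0), (0, 6)])
        pred = h.multiclass_train_predict(
            X, y, Xt, make_coding(("c0", "c1", "c2")),
            h.KernelSpec(kind="gaussian_rbf", sigma=2.0), gamma=100.0)
        assert (pred == yt).all()

    def test_one_vs_all_style_identity_code_builds_three_machines(self):
        cm = np.array([[1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        coding = h.CodingScheme(kind="ECOC", classes=("a", "b", "c"),
                                code_matrix=cm)
        rng = np.random.default_rng(7)
        X, y = blobs(rng, [(-4, 0), (4, 0), (0, 6)])
        y = np.array(["a", "b", "c"])[np.searchsorted(["c0", "c1", "c2"], y)]
        clf = h.MulticlassLSSVM(coding=coding,
                                kernel=h.KernelSpec(kind="gaussian_rbf", sigma=2.0),
                                gamma=10.0).fit(X, y)
        assert len(clf.machines) == 3

    def test_exhaustive_ecoc_for_three_classes(self):
        coding = h.ecoc_scheme(("a", "b", "c"))
        assert coding.code_matrix.shape == (3, 3)  # 2^(3-1) - 1 columns
        rows = {tuple(r) for r in coding.code_matrix}
        assert len(rows) == 3

    def test_duplicate_code_rows_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            h.CodingScheme(kind="ECOC", classes=("a", "b"),
                           code_matrix=np.array([[1, 1], [1, 1]]))


class TestMetrics:
    def test_reference_confusion_arithmetic(self):
        m = h.compute_metrics(h.ConfusionCounts(tp=50, fn=0, tn=45, fp=5))
        assert m.sensitivity["positive"] == pytest.approx(100.0)
        assert m.specificity["positive"] == pytest.approx(90.0)
        assert m.total_accuracy == pytest.approx(95.0)

    def test_perfect_predictions_all_hundred(self):
        y = ["a"] * 5 + ["b"] * 5
        r = h.metrics_report(y, y)
        assert r.total_accuracy == 100.0
        assert all(v == 100.0 for v in r.sensitivity.values())
        assert all(v == 100.0 for v in r.specificity.values())

    def test_all_wrong_on_balanced_data_gives_zero_accuracy(self):
        y_true = ["a"] * 5 + ["b"] * 5
        y_pred = ["b"] * 5 + ["a"] * 5
        assert h.metrics_report(y_true, y_pred).total_accuracy == 0.0

    def test_undefined_ratio_reported_as_none(self):
        # no true positives for class "b" anywhere: sensitivity undefined
        r = h.metrics_report(["a", "a"], ["a", "a"], classes=("a", "b"))
        assert r.sensitivity["b"] is None

    @given(perm_seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        y_true = np.array(["a", "b", "a", "b", "b", "a", "a", "b"])
        y_pred = np.array(["a", "a", "a", "b", "b", "b", "a", "b"])
        p = rng.permutation(len(y_true))
        base = h.metrics_report(y_true, y_pred)
        perm = h.metrics_report(y_true[p], y_pred[p])
        assert base.total_accuracy == perm.total_accuracy
        assert base.sensitivity == perm.sensitivity

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            h.ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)
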