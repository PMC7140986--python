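import numpy as np
import pytest

from elmgrade.kernel_elm import (
    default_gamma,
    elm_classify,
    elm_grade,
    elm_scores,
    elm_train,
    gaussian_kernel,
    kernel_matrix,
    label_matrix,
    load_model,
    save_model,
)


def brute_force_predict(X, Y, gamma, C, queries):
    """Independent linear-algebra oracle: explicit solve, double-loop kernels."""
    n = X.shape[0]
    omega = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = X[i] - X[j]
            omega[i, j] = np.exp(-(d @ d) / gamma)
    coef = np.linalg.solve(omega + np.eye(n) / C, Y)
    out = np.empty((queries.shape[0], 2))
    for q in range(queries.shape[0]):
        k = np.array([np.exp(-((queries[q] - X[i]) @ (queries[q] - X[i])) / gamma)
                      for i in range(n)])
        out[q] = k @ coef
    return out


# ------------------------------------------------------------------ kernel


def test_gaussian_kernel_analytic_values():
    u = np.array([0.0, 0.0])
    assert gaussian_kernel(u, u, 5.0) == pytest.approx(1.0)
    v = np.array([1.0, 1.0])  # squared distance 2 == gamma
    assert gaussian_kernel(u, v, 2.0) == pytest.approx(np.exp(-1.0))
    # squared distance 25, gamma 50
    assert gaussian_kernel([0, 0], [3, 4], 50.0) == pytest.approx(np.exp(-0.5))


def test_gaussian_kernel_contract():
    with pytest.raises(ValueError):
        gaussian_kernel([0.0], [1.0], 0.0)
    with pytest.raises(ValueError):
        gaussian_kernel([0.0, 1.0], [1.0], 2.0)


def test_kernel_matrix_matches_double_loop(rng):
    X = rng.standard_normal((4, 3))
    K = kernel_matrix(X, 7.0)
    for i in range(4):
        for j in range(4):
            assert K[i, j] == pytest.approx(
                gaussian_kernel(X[i], X[j], 7.0), abs=1e-12
            )
    assert np.array_equal(K, K.T)
    np.testing.assert_array_equal(np.diag(K), 1.0)


def test_kernel_matrix_degenerate_shapes():
    np.testing.assert_allclose(kernel_matrix(np.array([[1.0, 2.0]]), 3.0), [[1.0]])
    two = np.array([[1.0, 2.0], [1.0, 2.0]])
    np.testing.assert_array_equal(kernel_matrix(two, 3.0), np.ones((2, 2)))


def test_kernel_matrix_psd(rng):
    X = rng.standard_normal((15, 4))
    K = kernel_matrix(X, default_gamma(4))
    eig = np.linalg.eigvalsh(K)
    assert eig.min() > -1e-10
    C = 2.0
    eig_reg = np.linalg.eigvalsh(K + np.eye(15) / C)
    assert eig_reg.min() >= 1.0 / C - 1e-10


# ---------------------------------------------------------------- training


def test_label_matrix_rows_one_hot_signed():
    Y = label_matrix(np.array(["AD", "NC", "AD"]), ("AD", "NC"))
    np.testing.assert_array_equal(Y, [[1, -1], [-1, 1], [1, -1]])
    with pytest.raises(ValueError):
        label_matrix(np.array(["AD", "MCI"]), ("AD", "NC"))


def test_two_sample_model_matches_hand_inversion():
    """N=2: coef equals the 2x2 inverse [[2, k], [k, 2]]^-1 Y at C=1."""
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    gamma = 4.0
    k = np.exp(-2.0 / gamma)
    model = elm_train(X, np.array(["AD", "NC"]), C=1.0, gamma=gamma)
    A = np.array([[2.0, k], [k, 2.0]])
    Y = np.array([[1.0, -1.0], [-1.0, 1.0]])
    expected = np.linalg.inv(A) @ Y
    np.testing.assert_allclose(model.coef, expected, atol=1e-12)


def test_predictions_invariant_to_row_permutation(rng):
    X = rng.standard_normal((12, 3))
    labels = np.array(["AD"] * 6 + ["NC"] * 6)
    q = rng.standard_normal(3)
    m1 = elm_train(X, labels, class_order=("AD", "NC"))
    perm = rng.permutation(12)
    m2 = elm_train(X[perm], labels[perm], class_order=("AD", "NC"))
    assert elm_scores(m1, q) == pytest.approx(elm_scores(m2, q), abs=1e-10)


def test_duplicate_rows_equal_dedup_at_large_C(rng):
    X = rng.standard_normal((8, 2))
    labels = np.array(["AD"] * 4 + ["NC"] * 4)
    q = rng.standard_normal((5, 2))
    big_c = 1e8
    dup = elm_train(np.vstack([X, X]), np.concatenate([labels, labels]), C=big_c)
    ded = elm_train(X, labels, C=big_c)
    np.testing.assert_allclose(elm_grade(dup, q), elm_grade(ded, q), atol=1e-3)


def test_interpolation_limit_at_large_C(rng):
    """With negligible regularization the model interpolates its labels."""
    X = rng.standard_normal((6, 2)) * 3
    labels = np.array(["AD", "NC", "AD", "NC", "AD", "NC"])
    model = elm_train(X, labels, C=1e8, gamma=default_gamma(2))
    for i, lab in enumerate(labels):
        s1, s2 = elm_scores(model, X[i])
        want = (1.0, -1.0) if lab == "AD" else (-1.0, 1.0)
        assert (s1, s2) == pytest.approx(want, abs=1e-3)


def test_far_point_scores_vanish(rng):
    X = rng.standard_normal((6, 2))
    labels = np.array(["AD"] * 3 + ["NC"] * 3)
    model = elm_train(X, labels, gamma=1.0)
    s1, s2 = elm_scores(model, np.array([1e4, -1e4]))
    assert abs(s1) < 1e-12 and abs(s2) < 1e-12


def test_scores_match_brute_force_oracle(rng):
    X = rng.standard_normal((3, 2))
    labels = np.array(["AD", "NC", "AD"])
    gamma, C = 11.0, 0.7
    model = elm_train(X, labels, C=C, gamma=gamma, class_order=("AD", "NC"))
    Y = label_matrix(labels, ("AD", "NC"))
    q = rng.standard_normal((4, 2))
    expected = brute_force_predict(X, Y, gamma, C, q)
    got = np.array([elm_scores(model, qi) for qi in q])
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_shrinkage_limit_small_C(rng):
    X = rng.standard_normal((10, 2))
    labels = np.array(["AD"] * 5 + ["NC"] * 5)
    model = elm_train(X, labels, C=1e-10)
    g = elm_grade(model, rng.standard_normal((20, 2)))
    assert np.all(np.abs(g) < 1e-6)


def test_training_is_bitwise_deterministic(rng):
    X = rng.standard_normal((10, 3))
    labels = np.array(["AD"] * 5 + ["NC"] * 5)
    m1 = elm_train(X, labels)
    m2 = elm_train(X, labels)
    assert np.array_equal(m1.coef, m2.coef)


# ------------------------------------------------------- grade / classify


def test_grade_is_channel_difference(rng):
    X = rng.standard_normal((8, 2))
    labels = np.array(["AD"] * 4 + ["NC"] * 4)
    model = elm_train(X, labels)
    q = rng.standard_normal(2)
    s1, s2 = elm_scores(model, q)
    assert elm_grade(model, q) == pytest.approx(s1 - s2, abs=1e-14)


def test_symmetric_two_point_grade_is_zero():
    X = np.array([[-1.0], [1.0]])
    model = elm_train(X, np.array(["AD", "NC"]), class_order=("AD", "NC"))
    assert elm_grade(model, np.array([0.0])) == pytest.approx(0.0, abs=1e-14)


def test_grading_separates_training_classes(rng):
    """Mean grade of the AD training points exceeds that of the NC points."""
    X = np.vstack([rng.normal(1.0, 1, (20, 4)), rng.normal(-1.0, 1, (20, 4))])
    labels = np.array(["AD"] * 20 + ["NC"] * 20)
    model = elm_train(X, labels, C=1.0, class_order=("AD", "NC"))
    g = elm_grade(model, X)
    assert g[:20].mean() > g[20:].mean()


def test_classify_is_sign_thresholded_grade(rng):
    X = rng.standard_normal((10, 2))
    labels = np.array(["AD"] * 5 + ["NC"] * 5)
    model = elm_train(X, labels, class_order=("AD", "NC"))
    q = rng.standard_normal((100, 2))
    g = elm_grade(model, q)
    pred = elm_classify(model, q)
    np.testing.assert_array_equal(pred, np.where(g > 0, "AD", "NC"))


def test_exact_tie_goes_to_reference_class():
    X = np.array([[-1.0], [1.0]])
    model = elm_train(X, np.array(["AD", "NC"]), class_order=("AD", "NC"))
    assert elm_classify(model, np.array([0.0])) == "NC"


# ------------------------------------------------------------ persistence


def test_kernel_ridge_equivalence_per_channel(rng):
    """Each output channel equals kernel ridge regression with ridge 1/C."""
    from sklearn.kernel_ridge import KernelRidge

    X = rng.standard_normal((15, 3))
    labels = np.array(["AD"] * 7 + ["NC"] * 8)
    gamma, C = default_gamma(3), 2.5
    model = elm_train(X, labels, C=C, gamma=gamma, class_order=("AD", "NC"))
    Y = label_matrix(labels, ("AD", "NC"))
    q = rng.standard_normal((6, 3))
    got = np.array([elm_scores(model, qi) for qi in q])
    for ch in range(2):
        kr = KernelRidge(alpha=1.0 / C, kernel="rbf", gamma=1.0 / gamma)
        kr.fit(X, Y[:, ch])
        np.testing.assert_allclose(got[:, ch], kr.predict(q), atol=1e-8)


def test_model_round_trips_losslessly(tmp_path, rng):
    X = rng.standard_normal((9, 4))
    labels = np.array(["pMCI"] * 4 + ["sMCI"] * 5)
    model = elm_train(X, labels, C=3.0, class_order=("pMCI", "sMCI"))
    path = str(tmp_path / "model.elm")
    save_model(model, path)
    loaded = load_model(path)
    assert np.array_equal(loaded.train_X, model.train_X)
    assert np.array_equal(loaded.coef, model.coef)
    assert loaded.gamma == model.gamma
    assert loaded.C == model.C
    assert loaded.class_order == model.class_order
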