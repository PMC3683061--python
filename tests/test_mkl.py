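"""Unit and property tests for the SVM/MKL core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from pmfusion.errors import (
    KernelShapeError,
    NonFiniteInputError,
    NotPositiveSemidefiniteError,
    SingleClassError,
    ViewMismatchError,
)
from pmfusion.mkl import (
    KernelMatrix,
    MKLModel,
    combine_kernels,
    decision_function,
    linear_gram,
    load_model,
    predict,
    save_model,
    svm_objectives,
    train_mkl,
    train_svm,
)
from pmfusion.types import FeatureView


def qp_dual_oracle(K, y, C):
    """Independent dual solve by SLSQP; returns the optimal objective
    value (maximization form)."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K + 1e-10 * np.eye(n)
    fun = lambda a: 0.5 * a @ Q @ a - a.sum()
    jac = lambda a: Q @ a - 1.0
    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}]
    res = minimize(
        fun, np.zeros(n), jac=jac, bounds=[(0, C)] * n, constraints=cons,
        method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
    )
    return -res.fun


def random_problem(rng, n_max=30, p=4):
    n = int(rng.integers(6, n_max + 1))
    X = rng.normal(size=(n, p))
    y = np.where(rng.random(n) < 0.5, 1, -1)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return X, y


# ---------------------------------------------------------------- kernels


def test_linear_gram_orthonormal_and_single_row():
    v = FeatureView("a", ["s1", "s2"], np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert np.array_equal(linear_gram(v).values, np.eye(2))
    single = FeatureView("a", ["s1"], np.array([[2.0, 3.0]]))
    assert linear_gram(single).values[0, 0] == pytest.approx(13.0)


def test_linear_gram_matches_loop_oracle():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 4))
    K = linear_gram(FeatureView("a", list("abcde"), X)).values
    for i in range(5):
        for j in range(5):
            expect = sum(X[i, t] * X[j, t] for t in range(4))
            assert K[i, j] == pytest.approx(expect, abs=1e-12)


def test_linear_gram_rejects_nonfinite():
    X = np.array([[1.0, np.nan]])
    with pytest.raises(NonFiniteInputError):
        linear_gram(FeatureView("a", ["s"], X))


def test_kernel_matrix_invariants():
    with pytest.raises(KernelShapeError):
        KernelMatrix(np.array([[0.0, 1.0], [0.0, 0.0]]))  # asymmetric
    with pytest.raises(NotPositiveSemidefiniteError):
        KernelMatrix(np.array([[0.0, 1.0], [1.0, 0.0]])).check_psd()


def test_combine_kernels_identity_convexity_and_oracle():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(6, 6))
    K1 = KernelMatrix(A @ A.T, "a")
    assert np.array_equal(combine_kernels([K1], [1.0]).values, K1.values)

    K1b = KernelMatrix(K1.values.copy(), "b")
    mix = combine_kernels([K1, K1b], [0.3, 0.7])
    assert np.allclose(mix.values, K1.values)

    B = rng.normal(size=(6, 6))
    K2 = KernelMatrix(B @ B.T, "c")
    out = combine_kernels([K1, K2], [0.3, 0.7]).values
    for i in range(6):
        for j in range(6):
            assert out[i, j] == pytest.approx(
                0.3 * K1.values[i, j] + 0.7 * K2.values[i, j], abs=1e-12
            )
    with pytest.raises(ValueError):
        combine_kernels([K1, K2], [0.5, 0.6])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(2, 8),
    w=st.floats(0.0, 1.0),
)
def test_convex_combination_preserves_psd(seed, n, w):
    """Any convex combination of PSD kernels stays PSD."""
    rng = np.random.default_rng(seed)
    A, B = rng.normal(size=(n, n)), rng.normal(size=(n, n))
    mix = combine_kernels(
        [KernelMatrix(A @ A.T, "a"), KernelMatrix(B @ B.T, "b")],
        [w, 1.0 - w],
    )
    mix.check_psd()  # raises if indefinite beyond tolerance


# ------------------------------------------------------------------- SVM


def test_svm_symmetric_separable_pair():
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1, 1])
    model = train_svm(linear_gram(FeatureView("a", ["s1", "s2"], X)), y, C=100.0)
    assert model.bias == pytest.approx(0.0, abs=1e-9)
    assert set(model.support_indices) == {0, 1}
    scores = model.decision_values(X @ X.T)
    assert np.array_equal(predict(scores), y)


def test_svm_matches_qp_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        X, y = random_problem(rng)
        K = linear_gram(FeatureView("a", list(range(len(y))), X))
        model = train_svm(K, y, C=1.0, tol=1e-6)
        a = model.dual_coefficients
        assert a.min() >= -1e-12 and a.max() <= 1.0 + 1e-12
        assert abs(a @ y) < 1e-6
        _, dual, gap = svm_objectives(K, model)
        assert gap <= 1e-4
        oracle = qp_dual_oracle(K.values, y, 1.0)
        assert dual == pytest.approx(oracle, rel=1e-4, abs=1e-6)


def test_svm_xor_hits_box_bound():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    model = train_svm(linear_gram(FeatureView("a", list("abcd"), X)), y, C=1.0)
    assert model.dual_coefficients.max() >= 1.0 - 1e-8  # slack active


def test_svm_named_errors():
    K = KernelMatrix(np.eye(3))
    with pytest.raises(SingleClassError):
        train_svm(K, np.array([1, 1, 1]), C=1.0)
    bad = KernelMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(NotPositiveSemidefiniteError):
        train_svm(bad, np.array([1, -1]), C=1.0)
    with pytest.raises(ValueError):
        train_svm(KernelMatrix(np.eye(2)), np.array([1, -1]), C=0.0)


def test_svm_permutation_equivariance():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(15, 25))  # p > n: strictly PD Gram, unique duals
    y = np.where(rng.random(15) < 0.5, 1, -1)
    y[:2] = [1, -1]
    Xt = rng.normal(size=(6, 25))
    model = train_svm(linear_gram(FeatureView("a", list(range(15)), X)), y,
                      C=1.0, tol=1e-10)
    perm = rng.permutation(15)
    model_p = train_svm(
        linear_gram(FeatureView("a", list(range(15)), X[perm])), y[perm],
        C=1.0, tol=1e-10,
    )
    assert model_p.dual_coefficients == pytest.approx(
        model.dual_coefficients[perm], abs=1e-6
    )
    s = model.decision_values(Xt @ X.T)
    s_p = model_p.decision_values(Xt @ X[perm].T)
    assert s_p == pytest.approx(s, abs=1e-9)


# ------------------------------------------------------------------- MKL


def test_mkl_single_view_equals_svm():
    rng = np.random.default_rng(2)
    for _ in range(20):
        X, y = random_problem(rng, n_max=20)
        v = FeatureView("a", list(range(len(y))), X)
        mkl = train_mkl([v], y, C=1.0)
        assert mkl.kernel_weights == pytest.approx([1.0], abs=1e-12)
        svm = train_svm(linear_gram(v), y, C=1.0, tol=1e-7)
        s_mkl = decision_function(mkl, [v], [v])
        s_svm = svm.decision_values(X @ X.T)
        assert s_mkl == pytest.approx(s_svm, abs=1e-6)


def test_mkl_duplicated_view_equals_single():
    rng = np.random.default_rng(3)
    X, y = random_problem(rng, n_max=25)
    n = len(y)
    Xt = rng.normal(size=(8, X.shape[1]))
    v1 = FeatureView("a", list(range(n)), X)
    v2 = FeatureView("b", list(range(n)), X.copy())
    mkl = train_mkl([v1, v2], y, C=1.0)
    svm = train_svm(linear_gram(v1), y, C=1.0, tol=1e-7)
    t1 = FeatureView("a", list(range(8)), Xt)
    t2 = FeatureView("b", list(range(8)), Xt.copy())
    assert decision_function(mkl, [v1, v2], [t1, t2]) == pytest.approx(
        svm.decision_values(Xt @ X.T), abs=1e-4
    )


def test_mkl_weights_on_simplex_and_objective_monotone():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = 40
        y = np.where(rng.random(n) < 0.5, 1, -1)
        y[:2] = [1, -1]
        views = [
            FeatureView(t, list(range(n)), rng.normal(size=(n, p)))
            for t, p in (("a", 3), ("b", 5), ("c", 2))
        ]
        views[0].matrix[y == 1] += 0.8
        mkl = train_mkl(views, y, C=1.0)
        w = mkl.kernel_weights
        assert w.min() >= 0 and abs(w.sum() - 1.0) <= 1e-9
        trace = np.array(mkl.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)


def test_mkl_suppresses_noise_view():
    weights = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, p = 200, 5
        y = np.where(rng.random(n) < 0.5, 1, -1)
        info = rng.normal(size=(n, p))
        info[y == 1] += 2.0 / np.sqrt(p)  # 2 within-class SDs apart
        noise = rng.normal(size=(n, p))
        mkl = train_mkl(
            [FeatureView("info", list(range(n)), info),
             FeatureView("noise", list(range(n)), noise)],
            y, C=1.0,
        )
        weights.append(mkl.kernel_weights[1])
    assert np.mean(weights) < 0.2


def test_mkl_mismatched_subject_counts():
    v1 = FeatureView("a", ["s1", "s2"], np.zeros((2, 2)))
    v2 = FeatureView("b", ["s1", "s2", "s3"], np.zeros((3, 2)))
    with pytest.raises(ViewMismatchError):
        train_mkl([v1, v2], np.array([1, -1]))


# ------------------------------------------------------------- decisions


def test_decision_function_matches_loop_expansion():
    rng = np.random.default_rng(5)
    n, nt = 12, 5
    y = np.where(rng.random(n) < 0.5, 1, -1)
    y[:2] = [1, -1]
    views = [FeatureView(t, list(range(n)), rng.normal(size=(n, p)))
             for t, p in (("a", 3), ("b", 4))]
    tests = [FeatureView(t, list(range(nt)), rng.normal(size=(nt, p)))
             for t, p in (("a", 3), ("b", 4))]
    mkl = train_mkl(views, y, C=1.0)
    scores = decision_function(mkl, views, tests)
    a, b_, beta = mkl.svm.dual_coefficients, mkl.svm.bias, mkl.kernel_weights
    for t in range(nt):
        s = b_
        for i in range(n):
            k = sum(
                beta[m] * float(views[m].matrix[i] @ tests[m].matrix[t])
                for m in range(2)
            )
            s += a[i] * y[i] * k
        assert scores[t] == pytest.approx(s, abs=1e-10)


def test_decision_tie_resolves_negative():
    svm_like = train_svm(
        KernelMatrix(np.eye(2)), np.array([1, -1]), C=1.0
    )
    svm_like.bias = 0.0
    model = MKLModel(kernel_weights=np.array([1.0]), svm=svm_like,
                     source_ids=["a"])
    train = [FeatureView("a", ["s1", "s2"], np.array([[1.0], [-1.0]]))]
    test = [FeatureView("a", ["t"], np.array([[0.0]]))]
    scores = decision_function(model, train, test)
    assert scores[0] == 0.0
    assert predict(scores)[0] == -1


def test_decision_modality_mismatch():
    svm = train_svm(KernelMatrix(np.eye(2)), np.array([1, -1]), C=1.0)
    model = MKLModel(np.array([1.0]), svm, ["a"])
    train = [FeatureView("a", ["s1", "s2"], np.zeros((2, 1)))]
    test = [FeatureView("b", ["t"], np.zeros((1, 1)))]
    with pytest.raises(ViewMismatchError):
        decision_function(model, train, test)


def test_separable_training_signs_recovered():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(20, 2))
    y = np.where(rng.random(20) < 0.5, 1, -1)
    y[:2] = [1, -1]
    X[y == 1] += 6.0  # widely separated
    v = FeatureView("a", list(range(20)), X)
    mkl = train_mkl([v], y, C=10.0)
    assert np.array_equal(predict(decision_function(mkl, [v], [v])), y)


def test_model_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    X, y = random_problem(rng)
    n = len(y)
    v = FeatureView("a", list(range(n)), X)
    mkl = train_mkl([v], y, C=1.0)
    mkl.metadata = {"seed": 8}
    path = tmp_path / "model.json"
    save_model(path, mkl, scalers={"a": (X.min(axis=0), X.max(axis=0))})
    loaded, scalers = load_model(path)
    assert loaded.source_ids == ["a"]
    assert loaded.metadata == {"seed": 8}
    assert np.allclose(scalers["a"][0], X.min(axis=0))
    assert decision_function(loaded, [v], [v]) == pytest.approx(
        decision_function(mkl, [v], [v]), abs=1e-12
    )
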