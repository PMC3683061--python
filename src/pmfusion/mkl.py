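"""Soft-margin SVM and multiple kernel learning (MKL) on linear kernels.

The classifier at the heart of the fusion framework.  A single modality is
classified by a soft-margin SVM on its linear Gram matrix; several
modalities are fused by learning a convex combination of per-modality basis
kernels

    K(x, x') = sum_m beta_m K_m(x, x'),   beta_m >= 0,  sum_m beta_m = 1,

so the learned weights report the relative discriminative power of each
data source.  The dual SVM problem is solved by SMO-style pairwise
coordinate ascent with maximal-violating-pair selection; the kernel
weights by the closed-form L1-norm update beta_m <- ||w_m|| / sum_k ||w_k||
(block coordinate descent on the group-lasso primal), alternated with SVM
re-solves until the objective stalls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    KernelShapeError,
    NonFiniteInputError,
    NotPositiveSemidefiniteError,
    SingleClassError,
    ViewMismatchError,
)
from .types import FeatureView, as_labels

__all__ = [
    "KernelMatrix",
    "SVMModel",
    "MKLModel",
    "linear_gram",
    "train_svm",
    "combine_kernels",
    "train_mkl",
    "decision_function",
    "predict",
    "svm_objectives",
    "save_model",
    "load_model",
]

_SYM_TOL = 1e-9
_PSD_TOL = 1e-8


@dataclass
class KernelMatrix:
    """Symmetric PSD Gram matrix over training subjects for one modality."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise KernelShapeError("kernel matrix must be square")
        if not np.isfinite(self.values).all():
            raise NonFiniteInputError("kernel matrix has non-finite entries")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        scale = max(1.0, np.abs(self.values).max(initial=0.0))
        if asym > _SYM_TOL * scale:
            raise KernelShapeError(f"kernel asymmetric (max deviation {asym:g})")
        # enforce exact symmetry for the solver
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self):
        """Raise unless all eigenvalues exceed -1e-8 (scaled by magnitude)."""
        w = np.linalg.eigvalsh(self.values)
        tol = _PSD_TOL * max(1.0, np.abs(self.values).max(initial=0.0))
        if w[0] < -tol:
            raise NotPositiveSemidefiniteError(
                f"kernel has eigenvalue {w[0]:g} below -{tol:g}"
            )


@dataclass
class SVMModel:
    """Trained soft-margin SVM in dual form.

    ``dual_coefficients`` are the alphas of the box-constrained dual
    (0 <= alpha_i <= C, sum alpha_i y_i = 0); the decision value of a point
    with kernel row k is sum_i alpha_i y_i k_i + bias.
    """

    dual_coefficients: np.ndarray
    bias: float
    C: float
    labels: np.ndarray
    converged: bool = True

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.dual_coefficients > 1e-8 * self.C)

    def decision_values(self, kernel_rows: np.ndarray) -> np.ndarray:
        """Scores for test points given their kernel rows against training."""
        coef = self.dual_coefficients * self.labels
        return np.asarray(kernel_rows) @ coef + self.bias


@dataclass
class MKLModel:
    """Fused classifier: simplex kernel weights plus the inner SVM."""

    kernel_weights: np.ndarray
    svm: SVMModel
    source_ids: list
    objective_trace: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.kernel_weights, dtype=float)
        if w.min(initial=0.0) < -1e-12:
            raise ValueError("kernel weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")
        self.kernel_weights = w


def linear_gram(view: FeatureView | np.ndarray, source_id: str = "") -> KernelMatrix:
    """Linear-kernel Gram matrix: entry (i, j) = <x_i, x_j>."""
    if isinstance(view, FeatureView):
        X = view.matrix
        source_id = source_id or view.source_id
    else:
        X = np.asarray(view, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D feature matrix")
    if not np.isfinite(X).all():
        raise NonFiniteInputError("feature matrix has non-finite entries")
    return KernelMatrix(X @ X.T, source_id=source_id)


def _smo_solve(K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int):
    """Pairwise coordinate ascent on the dual with maximal-violating-pair
    selection; returns (alpha, bias, converged)."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * K
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of 0.5 a'Qa - e'a at alpha = 0
    tau = 1e-12

    yG = None
    converged = False
    for _ in range(max_iter):
        yG = -y * G
        up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y < 0) & (alpha < C - 1e-12)) | ((y > 0) & (alpha > 1e-12))
        if not up.any() or not low.any():
            converged = True
            break
        i = np.flatnonzero(up)[np.argmax(yG[up])]
        j = np.flatnonzero(low)[np.argmin(yG[low])]
        if yG[i] - yG[j] < tol:
            converged = True
            break

        ai_old, aj_old = alpha[i], alpha[j]
        if y[i] != y[j]:
            quad = Q[i, i] + Q[j, j] + 2.0 * Q[i, j]
            quad = quad if quad > tau else tau
            delta = (-G[i] - G[j]) / quad
            diff = ai_old - aj_old
            ai, aj = ai_old + delta, aj_old + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
                if ai > C:
                    ai, aj = C, C - diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
                if aj > C:
                    aj, ai = C, C + diff
        else:
            quad = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
            quad = quad if quad > tau else tau
            delta = (G[i] - G[j]) / quad
            total = ai_old + aj_old
            ai, aj = ai_old - delta, aj_old + delta
            if total > C:
                if ai > C:
                    ai, aj = C, total - C
                if aj > C:
                    aj, ai = C, total - C
            else:
                if aj < 0:
                    aj, ai = 0.0, total
                if ai < 0:
                    ai, aj = 0.0, total

        dai, daj = ai - ai_old, aj - aj_old
        if dai == 0.0 and daj == 0.0:
            converged = True
            break
        alpha[i], alpha[j] = ai, aj
        G += Q[:, i] * dai + Q[:, j] * daj

    # bias from the KKT conditions: average -y_i G_i over free vectors,
    # else the midpoint of the feasible interval
    yG = -y * G
    free = (alpha > 1e-12) & (alpha < C - 1e-12)
    if free.any():
        b = float(np.mean(yG[free]))
    else:
        up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y < 0) & (alpha < C - 1e-12)) | ((y > 0) & (alpha > 1e-12))
        hi = yG[up].max() if up.any() else 0.0
        lo = yG[low].min() if low.any() else 0.0
        b = float(0.5 * (hi + lo))
    return alpha, b, converged


def train_svm(
    K: KernelMatrix | np.ndarray,
    y,
    C: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 200_000,
    check_psd: bool = True,
) -> SVMModel:
    """Solve the soft-margin SVM dual on a precomputed kernel.

    Parameters
    ----------
    K : KernelMatrix
        Training Gram matrix.
    y : array-like of +1/-1
        Class labels; both classes must be present.
    C : float
        Box penalty on the slack variables.
    tol : float
        Stop when the maximal KKT violation drops below ``tol``.
    """
    if not isinstance(K, KernelMatrix):
        K = KernelMatrix(K)
    y = as_labels(y)
    if K.n != len(y):
        raise KernelShapeError(
            f"kernel dimension {K.n} != label count {len(y)}"
        )
    if C <= 0:
        raise ValueError("C must be positive")
    if check_psd:
        K.check_psd()
    alpha, b, converged = _smo_solve(K.values, y, float(C), tol, max_iter)
    # snap round-off residue onto the box
    alpha = np.clip(alpha, 0.0, C)
    return SVMModel(
        dual_coefficients=alpha, bias=b, C=float(C), labels=y, converged=converged
    )


def svm_objectives(K: KernelMatrix, model: SVMModel):
    """(primal, dual, relative gap) of a trained SVM; the gap certifies
    solution quality."""
    a = model.dual_coefficients
    y = model.labels
    v = a * y
    Kv = K.values @ v
    dual = a.sum() - 0.5 * float(v @ Kv)
    f = Kv + model.bias
    xi = np.maximum(0.0, 1.0 - y * f)
    primal = 0.5 * float(v @ Kv) + model.C * xi.sum()
    gap = (primal - dual) / max(1.0, abs(primal))
    return primal, dual, gap


def combine_kernels(kernels: list, weights) -> KernelMatrix:
    """Convex combination sum_m beta_m K_m of same-size basis kernels."""
    if len(kernels) == 0:
        raise KernelShapeError("need at least one kernel")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(kernels):
        raise KernelShapeError("one weight per kernel required")
    if w.min(initial=0.0) < -1e-12 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must lie on the probability simplex")
    n = kernels[0].n
    if any(k.n != n for k in kernels):
        raise KernelShapeError("kernels differ in dimension")
    out = np.zeros((n, n))
    for wk, k in zip(w, kernels):
        out += wk * k.values
    return KernelMatrix(out, source_id="+".join(k.source_id for k in kernels))


def _mkl_primal(beta, grams, model):
    """Group-lasso primal 0.5*sum_m ||w_m||^2/beta_m + C*sum xi at the
    current (alpha, beta); equals the combined-kernel SVM primal."""
    v = model.dual_coefficients * model.labels
    Kc = sum(b * G for b, G in zip(beta, grams))
    Kv = Kc @ v
    xi = np.maximum(0.0, 1.0 - model.labels * (Kv + model.bias))
    return 0.5 * float(v @ Kv) + model.C * xi.sum()


def train_mkl(
    views: list,
    y,
    C: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    inner_tol: float = 1e-9,
) -> MKLModel:
    """Alternating optimization of kernel weights and SVM duals.

    Each view contributes one linear basis kernel.  Starting from uniform
    weights, the SVM is solved on the combined kernel, then each weight is
    reset proportional to the norm of that kernel's implicit weight vector,
    ||w_m||^2 = beta_m^2 * (alpha y)' K_m (alpha y).  The tracked objective
    (the group-lasso primal) is non-increasing; iteration stops when its
    relative decrease falls below ``tol``.
    """
    if len(views) == 0:
        raise ViewMismatchError("at least one view required")
    y = as_labels(y)
    n = len(y)
    for v in views:
        if v.n_subjects != n:
            raise ViewMismatchError(
                f"view {v.source_id!r} has {v.n_subjects} subjects, expected {n}"
            )
    kernels = [linear_gram(v) for v in views]
    for k in kernels:
        k.check_psd()
    grams = [k.values for k in kernels]
    M = len(views)
    beta = np.full(M, 1.0 / M)

    trace = []
    model = None
    for _ in range(max_iter):
        Kc = KernelMatrix(
            sum(b * G for b, G in zip(beta, grams)), source_id="combined"
        )
        model = train_svm(Kc, y, C=C, tol=inner_tol, check_psd=False)
        obj = _mkl_primal(beta, grams, model)
        if trace and trace[-1] - obj < tol * max(1.0, abs(trace[-1])):
            trace.append(obj)
            break
        trace.append(obj)
        v = model.dual_coefficients * model.labels
        norms = beta * np.sqrt(np.maximum(0.0, np.array([v @ G @ v for G in grams])))
        total = norms.sum()
        if total <= 0:  # degenerate: no support anywhere, keep weights
            break
        beta = norms / total

    return MKLModel(
        kernel_weights=beta,
        svm=model,
        source_ids=[v.source_id for v in views],
        objective_trace=trace,
    )


def decision_function(
    model: MKLModel, train_views: list, test_views: list
) -> np.ndarray:
    """Fused decision scores for test subjects.

    score_t = sum_i alpha_i y_i sum_m beta_m <x_i^m, x_t^m> + b.  Both view
    lists must follow the modality ordering the model was trained with, and
    test views must be scaled with the training scalers.
    """
    train_ids = [v.source_id for v in train_views]
    test_ids = [v.source_id for v in test_views]
    if train_ids != model.source_ids or test_ids != model.source_ids:
        raise ViewMismatchError(
            f"modality mismatch: model {model.source_ids}, "
            f"train {train_ids}, test {test_ids}"
        )
    n_test = test_views[0].n_subjects
    rows = np.zeros((n_test, train_views[0].n_subjects))
    for b, tr, te in zip(model.kernel_weights, train_views, test_views):
        if te.n_subjects != n_test:
            raise ViewMismatchError("test views differ in subject count")
        rows += b * (te.matrix @ tr.matrix.T)
    return model.svm.decision_values(rows)


def predict(scores: np.ndarray) -> np.ndarray:
    """Class labels from scores: positive score -> +1, ties resolve to -1."""
    return np.where(np.asarray(scores) > 0, 1, -1)


def save_model(path, model: MKLModel, scalers: dict | None = None) -> None:
    """Serialize an MKL model (weights, duals, bias, C, scalers, modality
    order and any metadata such as the codebook reference or training seed)
    to a single JSON document."""
    doc = {
        "kernel_weights": model.kernel_weights.tolist(),
        "source_ids": list(model.source_ids),
        "dual_coefficients": model.svm.dual_coefficients.tolist(),
        "bias": model.svm.bias,
        "C": model.svm.C,
        "labels": model.svm.labels.tolist(),
        "objective_trace": list(model.objective_trace),
        "metadata": model.metadata,
        "scalers": {
            tag: {"min": np.asarray(lo).tolist(), "max": np.asarray(hi).tolist()}
            for tag, (lo, hi) in (scalers or {}).items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> tuple[MKLModel, dict]:
    """Inverse of :func:`save_model`; returns (model, scalers)."""
    with open(path) as fh:
        doc = json.load(fh)
    svm = SVMModel(
        dual_coefficients=np.array(doc["dual_coefficients"]),
        bias=float(doc["bias"]),
        C=float(doc["C"]),
        labels=np.array(doc["labels"], dtype=int),
    )
    model = MKLModel(
        kernel_weights=np.array(doc["kernel_weights"]),
        svm=svm,
        source_ids=list(doc["source_ids"]),
        objective_trace=list(doc["objective_trace"]),
        metadata=doc.get("metadata", {}),
    )
    scalers = {
        tag: (np.array(d["min"]), np.array(d["max"]))
        for tag, d in doc.get("scalers", {}).items()
    }
    return model, scalers
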