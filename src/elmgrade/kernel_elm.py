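"""Kernel extreme learning machine with a Gaussian kernel.

The kernel ELM is a closed-form two-channel classifier.  Training data
X (N x M) with binary class labels is encoded as a label matrix Y (N x 2)
whose rows are (+1, -1) for the first class and (-1, +1) for the second.
With the Gaussian kernel

    K(u, v) = exp(-||u - v||^2 / gamma)

and its N x N training kernel matrix Omega, the model solves

    (Omega + I/C) coef = Y

once (a symmetric positive-definite solve; no random hidden weights, so
training is deterministic), and predicts a new point x as

    f(x) = [K(x, x_1) ... K(x, x_N)] coef  =  (s1, s2).

Classification compares s1 with s2; the *grading score* s = s1 - s2 turns
the classifier into a continuous similarity scale: positive values lean
toward the first (positive) class, negative toward the second.

C is the regularization coefficient (default 1); gamma defaults to 10 times
the feature count of the training block, so the kernel bandwidth tracks the
input dimensionality across pipeline stages.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass
from io import BytesIO

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

DEFAULT_C = 1.0
GAMMA_PER_FEATURE = 10.0


def default_gamma(n_features: int) -> float:
    """Kernel width rule gamma = 10 * M for an M-feature input."""
    return GAMMA_PER_FEATURE * n_features


def gaussian_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """K(u, v) = exp(-||u-v||^2 / gamma); symmetric, in (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    d = u - v
    return float(np.exp(-(d @ d) / gamma))


def kernel_matrix(
    X: np.ndarray, gamma: float, Z: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian kernel matrix. ``Z`` rows vs ``X`` rows; ``Z=None`` gives
    the symmetric unit-diagonal training matrix Omega."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Z is None:
        sq = cdist(X, X, metric="sqeuclidean")
        K = np.exp(-sq / gamma)
        np.fill_diagonal(K, 1.0)  # exact unit diagonal
        return K
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != X.shape[1]:
        raise ValueError(
            f"dimension mismatch: query has {Z.shape[1]} features, "
            f"training has {X.shape[1]}"
        )
    return np.exp(-cdist(Z, X, metric="sqeuclidean") / gamma)


def label_matrix(labels: np.ndarray, class_order: tuple[str, str]) -> np.ndarray:
    """Two-channel +1/-1 encoding: the channel of the true class is +1."""
    labels = np.asarray(labels)
    pos, neg = class_order
    seen = set(np.unique(labels).tolist())
    if not seen <= {pos, neg}:
        raise ValueError(f"labels {sorted(seen)} not within class_order {class_order}")
    Y = np.where((labels == pos)[:, None], [1.0, -1.0], [-1.0, 1.0])
    return Y


@dataclass
class ElmModel:
    """Trained kernel ELM: stored training features and solved coefficients.

    ``coef`` is the N x 2 solution of (Omega + I/C) coef = Y.
    ``class_order`` is (positive class, negative class).
    """

    train_X: np.ndarray
    gamma: float
    C: float
    coef: np.ndarray
    class_order: tuple[str, str]

    def __post_init__(self) -> None:
        self.train_X = np.atleast_2d(np.asarray(self.train_X, dtype=float))
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (self.train_X.shape[0], 2):
            raise ValueError("coef must be N x 2 with N = training rows")
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be positive")
        self.class_order = (str(self.class_order[0]), str(self.class_order[1]))


def elm_train(
    X: np.ndarray,
    labels: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float | None = None,
    class_order: tuple[str, str] | None = None,
) -> ElmModel:
    """Closed-form training: solve (Omega + I/C) coef = Y.

    ``class_order`` fixes which class maps to the first (positive) output
    channel; if omitted, the lexicographically smaller label is positive
    (AD before NC, pMCI before sMCI).  ``gamma`` defaults to 10 * M.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    if C <= 0:
        raise ValueError("C must be positive")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes in training labels, got {classes}")
    if class_order is None:
        class_order = (str(classes[0]), str(classes[1]))
    if gamma is None:
        gamma = default_gamma(X.shape[1])
    Y = label_matrix(labels, class_order)
    omega = kernel_matrix(X, gamma)
    A = omega + np.eye(X.shape[0]) / C
    try:
        cf = scipy.linalg.cho_factor(A, lower=True)
        coef = scipy.linalg.cho_solve(cf, Y)
    except scipy.linalg.LinAlgError:
        # Omega is PSD and I/C > 0, so this should not trigger; tiny jitter
        # guards against pathological rounding only.
        warnings.warn(
            "Cholesky factorization failed; retrying with 1e-10 jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        cf = scipy.linalg.cho_factor(A + 1e-10 * np.eye(A.shape[0]), lower=True)
        coef = scipy.linalg.cho_solve(cf, Y)
    return ElmModel(train_X=X, gamma=gamma, C=C, coef=coef, class_order=class_order)


def _score_matrix(model: ElmModel, X: np.ndarray) -> np.ndarray:
    K = kernel_matrix(model.train_X, model.gamma, Z=X)
    return K @ model.coef


def elm_scores(model: ElmModel, x: np.ndarray) -> tuple[float, float]:
    """Two-channel output f(x) = (s1, s2) for a single feature vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("elm_scores takes a single feature vector")
    s = _score_matrix(model, x[None, :])[0]
    return float(s[0]), float(s[1])


def elm_grade(model: ElmModel, x: np.ndarray) -> float | np.ndarray:
    """Grading score s = s1 - s2 (vector input -> scalar, matrix -> array).

    Positive s means the point resembles the positive class
    (``class_order[0]``), negative the reference class.
    """
    x = np.asarray(x, dtype=float)
    s = _score_matrix(model, np.atleast_2d(x))
    g = s[:, 0] - s[:, 1]
    return float(g[0]) if x.ndim == 1 else g


def elm_classify(model: ElmModel, x: np.ndarray) -> str | np.ndarray:
    """Hard classification by comparing the channels.

    Returns ``class_order[0]`` when s1 > s2, else ``class_order[1]``; the
    exact tie s1 == s2 goes to the negative/reference class (a documented
    convention — the model itself defines no tie behavior).
    """
    x = np.asarray(x, dtype=float)
    g = elm_grade(model, np.atleast_2d(x))
    out = np.where(g > 0, model.class_order[0], model.class_order[1])
    return str(out[0]) if x.ndim == 1 else out.astype(str)


def save_model(model: ElmModel, path: str) -> None:
    """Serialize a model to a single ``.npz``-style archive (lossless)."""
    buf = BytesIO()
    np.savez(
        buf,
        train_X=model.train_X,
        coef=model.coef,
        gamma=np.array(model.gamma),
        C=np.array(model.C),
    )
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr(
            "meta.json", json.dumps({"class_order": list(model.class_order)})
        )


def load_model(path: str) -> ElmModel:
    with zipfile.ZipFile(path) as zf:
        with zf.open("arrays.npz") as fh:
            arrays = np.load(BytesIO(fh.read()))
            data = {k: arrays[k] for k in arrays.files}
        meta = json.loads(zf.read("meta.json"))
    return ElmModel(
        train_X=data["train_X"],
        gamma=float(data["gamma"]),
        C=float(data["C"]),
        coef=data["coef"],
        class_order=tuple(meta["class_order"]),
    )
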