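"""L1-penalized least squares for AD-discriminative feature selection.

The objective solved here is the unscaled form

    min_a  0.5 * ||y - D a||^2  +  lam * ||a||_1

with no intercept and no 1/N factor (features are assumed zero-mean on the
AD+NC reference set, and the class coding is symmetric +1/-1, so an
intercept is unnecessary).  Many library solvers divide the quadratic term
by the sample count; ``lambda_scale="per_sample"`` rescales the penalty to
match that convention (effective penalty = lam * N).

The solver is cyclic coordinate descent with exact soft-threshold updates,
which for this objective is simple, robust and easy to verify against the
KKT conditions:

    |d_m' (y - D a)| <= lam           for every m,
    d_m' (y - D a) = lam * sign(a_m)  whenever a_m != 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from elmgrade.cohort_io import FeatureBlock

DEFAULT_LAMBDA = 0.015
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000
ZERO_TOL = 1e-8


@dataclass
class LassoProblem:
    """Design matrix ``D`` (N x M), response ``y`` (length N), penalty ``lam``."""

    D: np.ndarray
    y: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.D.ndim != 2:
            raise ValueError("D must be a 2-D matrix")
        if self.D.shape[0] != self.y.size:
            raise ValueError(
                f"D has {self.D.shape[0]} rows but y has {self.y.size} entries"
            )
        if not (np.all(np.isfinite(self.D)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite entries in D or y")
        if self.lam < 0:
            raise ValueError("penalty must be nonnegative")


@dataclass
class LassoResult:
    alpha: np.ndarray
    selected: np.ndarray  # indices with |alpha| > zero_tol, ascending
    lambda_used: float
    iterations: int
    converged: bool

    def objective(self, D: np.ndarray, y: np.ndarray) -> float:
        r = y - D @ self.alpha
        return 0.5 * float(r @ r) + self.lambda_used * float(
            np.abs(self.alpha).sum()
        )


def lambda_max(D: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty for which the solution is identically zero.

    Equals ``max_m |d_m' y|`` under the unscaled objective: at a = 0 the
    KKT conditions hold iff every coordinate of the gradient of the
    quadratic term is dominated by the penalty.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if D.size == 0:
        raise ValueError("empty design matrix")
    return float(np.max(np.abs(D.T @ y)))


def lasso_fit(
    problem: LassoProblem,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    lambda_scale: str = "literal",
    zero_tol: float = ZERO_TOL,
) -> LassoResult:
    """Solve the L1 problem by cyclic coordinate descent.

    Parameters
    ----------
    problem
        Design, response and penalty.
    tol
        Convergence threshold on the maximum coefficient change per sweep.
    max_iter
        Maximum number of full sweeps; non-convergence returns a result with
        ``converged=False`` and emits a warning, never fails silently.
    lambda_scale
        ``"literal"`` uses the penalty as given against 0.5||y-Da||^2;
        ``"per_sample"`` multiplies it by N, matching solvers that minimise
        (1/2N)||y-Da||^2 + lam||a||_1.
    """
    if lambda_scale not in ("literal", "per_sample"):
        raise ValueError("lambda_scale must be 'literal' or 'per_sample'")
    D, y = problem.D, problem.y
    n, m = D.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    lam = problem.lam * (n if lambda_scale == "per_sample" else 1.0)

    col_sq = np.einsum("ij,ij->j", D, D)
    alpha = np.zeros(m)
    resid = y.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(m):
            if col_sq[j] == 0.0:
                continue
            a_old = alpha[j]
            rho = D[:, j] @ resid + col_sq[j] * a_old
            a_new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if a_new != a_old:
                resid += D[:, j] * (a_old - a_new)
                alpha[j] = a_new
                max_delta = max(max_delta, abs(a_new - a_old))
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(last max coefficient change above {tol:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    selected = np.flatnonzero(np.abs(alpha) > zero_tol)
    return LassoResult(
        alpha=alpha,
        selected=selected,
        lambda_used=lam,
        iterations=it,
        converged=converged,
    )


def select_features(block: FeatureBlock, result: LassoResult) -> FeatureBlock:
    """Keep only the columns with non-zero coefficients, order preserved.

    The same selection is applied to the AD/NC training block and the MCI
    block so both live in the identical reduced feature space.
    """
    if result.alpha.size != block.n_features:
        raise ValueError(
            f"selection was computed on {result.alpha.size} features, "
            f"block {block.modality_name!r} has {block.n_features}"
        )
    if result.selected.size == 0:
        raise ValueError(
            "no feature survived the L1 penalty; decrease the penalty "
            "(lasso.lambda) to retain features"
        )
    idx = np.asarray(result.selected, dtype=int)
    return FeatureBlock(
        modality_name=block.modality_name,
        feature_names=[block.feature_names[i] for i in idx],
        values=block.values[:, idx],
    )
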