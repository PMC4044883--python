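"""Two-class linear dimensionality reduction (LDR).

Estimates per-class Gaussian statistics and computes projections that
maximize one of three class-separability criteria:

* FDA — Fisher's discriminant: the Mahalanobis distance between the
  projected class means, solved by a generalized eigenproblem.
* HDA — heteroscedastic discriminant: augments the between-class scatter
  with a matrix-logarithm term so that differences in class covariances
  also contribute, solved by the same eigenproblem machinery.
* CDA — Chernoff discriminant: the Chernoff distance between the two
  projected Gaussians, maximized iteratively by gradient ascent.

All three reduce an n-dimensional feature vector x to y = A x with A of
shape (d, n). With two classes the between-class scatter has rank one, so
d = 1 is the natural default; HDA/CDA can still benefit from d > 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "ClassGaussian",
    "ScatterPair",
    "Projection",
    "CDAOptions",
    "estimate_class_gaussians",
    "scatter_matrices",
    "criterion_value",
    "fit_fda",
    "fit_hda",
    "fit_cda",
    "matrix_function",
    "regularize_covariance",
]

_CRITERIA = ("fda", "hda", "cda")

#: default ridge scale for covariance regularization (lambda * trace(S)/n * I)
DEFAULT_REG = 1e-6

#: eigenvalue floor used inside matrix functions
DEFAULT_FLOOR = 1e-12


@dataclass(frozen=True)
class ClassGaussian:
    """Gaussian model of one class: mean vector, covariance matrix, prior."""

    mean: np.ndarray
    covariance: np.ndarray
    prior: float

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.ndim != 1:
            raise ValueError("mean must be a 1-D vector")
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape does not match mean dimension")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must lie in (0, 1)")
        w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
        if w.min() < -1e-10 * max(1.0, abs(w.max())):
            raise ValueError("covariance must be positive semi-definite")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class ScatterPair:
    """Within-class (S_W) and between-class (S_E) scatter matrices."""

    within: np.ndarray
    between: np.ndarray

    @property
    def dim(self) -> int:
        return self.within.shape[0]


@dataclass
class Projection:
    """A d x n linear transformation with its criterion and objective value."""

    matrix: np.ndarray
    criterion: str
    objective_value: float
    converged: bool = True
    objective_trace: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CDAOptions:
    """Settings for the iterative Chernoff-criterion optimizer."""

    max_iterations: int = 500
    tolerance: float = 1e-8
    step_init: float = 1.0
    seed: int = 0
    n_restarts: int = 4  # FDA init + (n_restarts - 1) random orthonormal inits
    grad_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.step_init <= 0:
            raise ValueError("step_init must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def estimate_class_gaussians(
    samples: np.ndarray,
    labels: np.ndarray,
    prior_mode: str = "empirical",
    bias: bool = True,
) -> tuple[ClassGaussian, ClassGaussian]:
    """Per-class sample means/covariances and priors for a binary problem.

    Returns ``(positive, negative)`` — the class labelled 1 first.  The
    covariance estimator is biased (1/N) by default, matching the
    distributional class model; pass ``bias=False`` for 1/(N-1).
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("samples contain non-finite values")
    if y.shape != (X.shape[0],):
        raise ValueError("labels length must match sample count")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    if prior_mode not in ("empirical", "equal"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")

    out = {}
    n_total = X.shape[0]
    for lab in (1, 0):
        Xc = X[y == lab]
        if Xc.shape[0] < 2:
            raise ValueError(
                f"class {lab} is degenerate: {Xc.shape[0]} sample(s), need >= 2"
            )
        m = Xc.mean(axis=0)
        D = Xc - m
        denom = Xc.shape[0] if bias else Xc.shape[0] - 1
        S = (D.T @ D) / denom
        S = 0.5 * (S + S.T)
        prior = Xc.shape[0] / n_total if prior_mode == "empirical" else 0.5
        out[lab] = ClassGaussian(mean=m, covariance=S, prior=prior)
    return out[1], out[0]


def scatter_matrices(c1: ClassGaussian, c2: ClassGaussian) -> ScatterPair:
    """S_W = p1 S1 + p2 S2 and S_E = (m1 - m2)(m1 - m2)^t."""
    if c1.dim != c2.dim:
        raise ValueError("class dimensions do not match")
    within = c1.prior * c1.covariance + c2.prior * c2.covariance
    diff = c1.mean - c2.mean
    between = np.outer(diff, diff)
    return ScatterPair(within=0.5 * (within + within.T), between=between)


def regularize_covariance(S: np.ndarray, lam: float = DEFAULT_REG) -> np.ndarray:
    """Add a scaled ridge lam * trace(S)/n * I; keeps near-singular mapped
    covariances (collinear cosine features) invertible."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    scale = np.trace(S) / n
    if scale <= 0:
        scale = 1.0
    return S + lam * scale * np.eye(n)


def matrix_function(
    M: np.ndarray, kind: str, floor: float = DEFAULT_FLOOR
) -> np.ndarray:
    """Apply sqrt / inv_sqrt / log to a symmetric matrix spectrally.

    Eigenvalues are clipped at ``floor`` before the scalar function is
    applied; the result is re-symmetrized.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be a square matrix")
    if np.max(np.abs(M - M.T)) > 1e-8:
        raise ValueError("input matrix is not symmetric")
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    w = np.clip(w, floor, None)
    if kind == "sqrt":
        fw = np.sqrt(w)
    elif kind == "inv_sqrt":
        fw = 1.0 / np.sqrt(w)
    elif kind == "log":
        fw = np.log(w)
    else:
        raise ValueError(f"unknown matrix function {kind!r}")
    out = (V * fw) @ V.T
    return 0.5 * (out + out.T)


def _logdet_spd(M: np.ndarray, floor: float = DEFAULT_FLOOR) -> float:
    w = np.linalg.eigvalsh(0.5 * (M + M.T))
    return float(np.sum(np.log(np.clip(w, floor, None))))


def _project(A: np.ndarray, S: np.ndarray) -> np.ndarray:
    P = A @ S @ A.T
    return 0.5 * (P + P.T)


def criterion_value(
    A: np.ndarray,
    c1: ClassGaussian,
    c2: ClassGaussian,
    criterion: str,
    reg: float = DEFAULT_REG,
) -> float:
    """Evaluate J_FDA, J_HDA, or J_CDA for a projection matrix A (d x n)."""
    criterion = criterion.lower()
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    S1 = regularize_covariance(c1.covariance, reg)
    S2 = regularize_covariance(c2.covariance, reg)
    p1, p2 = c1.prior, c2.prior
    SW = p1 * S1 + p2 * S2
    diff = c1.mean - c2.mean
    SE = np.outer(diff, diff)

    AWA = _project(A, SW)
    cond = np.linalg.cond(AWA)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "projected within-class matrix A S_W A^t is numerically singular"
        )

    if criterion == "fda":
        return float(np.trace(np.linalg.solve(AWA, _project(A, SE))))

    if criterion == "hda":
        M = _hda_between(S1, S2, p1, p2, SE)
        return float(np.trace(np.linalg.solve(AWA, _project(A, M))))

    # CDA: p1 p2 tr{(A S_W A^t)^-1 A S_E A^t}
    #      + log|A S_W A^t| - p1 log|A S1 A^t| - p2 log|A S2 A^t|
    j = p1 * p2 * float(np.trace(np.linalg.solve(AWA, _project(A, SE))))
    j += _logdet_spd(AWA)
    j -= p1 * _logdet_spd(_project(A, S1))
    j -= p2 * _logdet_spd(_project(A, S2))
    return j


def _hda_between(
    S1: np.ndarray, S2: np.ndarray, p1: float, p2: float, SE: np.ndarray
) -> np.ndarray:
    """Heteroscedastic between-class matrix:

    S_E - S_W^{1/2} [ (p1 log(Sb1) + p2 log(Sb2)) / (p1 p2) ] S_W^{1/2},
    where Sbi = S_W^{-1/2} Si S_W^{-1/2}.  By concavity of log the bracketed
    term is negative semi-definite, so the correction only adds separability.
    """
    SW = p1 * S1 + p2 * S2
    W_half = matrix_function(SW, "sqrt")
    W_inv_half = matrix_function(SW, "inv_sqrt")
    log1 = matrix_function(W_inv_half @ S1 @ W_inv_half, "log")
    log2 = matrix_function(W_inv_half @ S2 @ W_inv_half, "log")
    corr = W_half @ ((p1 * log1 + p2 * log2) / (p1 * p2)) @ W_half
    M = SE - corr
    return 0.5 * (M + M.T)


def _top_eigvecs(M: np.ndarray, SW: np.ndarray, d: int) -> np.ndarray:
    """Rows = d leading eigenvectors of S_W^{-1} M via the symmetric
    generalized eigenproblem M v = w S_W v; descending eigenvalues, stable
    tie order, sign fixed so the largest-magnitude component is positive."""
    w, V = scipy.linalg.eigh(0.5 * (M + M.T), 0.5 * (SW + SW.T))
    order = np.argsort(-w, kind="stable")
    A = V[:, order[:d]].T.copy()
    for row in A:
        k = np.argmax(np.abs(row))
        if row[k] < 0:
            row *= -1
    return A


def fit_fda(scatter: ScatterPair, d: int, reg: float = DEFAULT_REG) -> Projection:
    """Fisher projection: d leading eigenvectors of S_W^{-1} S_E."""
    n = scatter.dim
    if not (1 <= d <= n):
        raise ValueError(f"d must be in [1, {n}], got {d}")
    SW = regularize_covariance(scatter.within, reg)
    A = _top_eigvecs(scatter.between, SW, d)
    obj = float(np.trace(np.linalg.solve(_project(A, SW), _project(A, scatter.between))))
    return Projection(matrix=A, criterion="fda", objective_value=obj)


def fit_hda(
    c1: ClassGaussian, c2: ClassGaussian, d: int, reg: float = DEFAULT_REG
) -> Projection:
    """Heteroscedastic projection: d leading eigenvectors of the
    log-corrected between-class matrix, whitened by S_W."""
    n = c1.dim
    if not (1 <= d <= n):
        raise ValueError(f"d must be in [1, {n}], got {d}")
    S1 = regularize_covariance(c1.covariance, reg)
    S2 = regularize_covariance(c2.covariance, reg)
    p1, p2 = c1.prior, c2.prior
    SW = p1 * S1 + p2 * S2
    diff = c1.mean - c2.mean
    M = _hda_between(S1, S2, p1, p2, np.outer(diff, diff))
    A = _top_eigvecs(M, SW, d)
    obj = criterion_value(A, c1, c2, "hda", reg)
    return Projection(matrix=A, criterion="hda", objective_value=obj)


def _orthonormal_rows(A: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(A.T)
    return Q.T


def _cda_ascent(
    A0: np.ndarray,
    c1: ClassGaussian,
    c2: ClassGaussian,
    opts: CDAOptions,
    reg: float,
) -> tuple[np.ndarray, float, list[float], bool]:
    """Gradient ascent on J_CDA with central-difference gradients and a
    backtracking (step-halving) line search; the objective trace is
    non-decreasing by construction."""

    def J(A: np.ndarray) -> float:
        try:
            return criterion_value(A, c1, c2, "cda", reg)
        except np.linalg.LinAlgError:
            return -np.inf

    A = _orthonormal_rows(np.array(A0, dtype=float))
    d, n = A.shape
    h = opts.grad_eps
    trace = [J(A)]
    converged = False
    for _ in range(opts.max_iterations):
        grad = np.empty_like(A)
        for i in range(d):
            for j in range(n):
                Ap = A.copy(); Ap[i, j] += h
                Am = A.copy(); Am[i, j] -= h
                grad[i, j] = (J(Ap) - J(Am)) / (2.0 * h)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0 or not np.isfinite(gnorm):
            converged = True
            break
        step = opts.step_init / gnorm
        improved = False
        while step > 1e-14:
            cand = _orthonormal_rows(A + step * grad)
            jc = J(cand)
            if jc > trace[-1]:
                A, improved = cand, True
                trace.append(jc)
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        if trace[-1] - trace[-2] < opts.tolerance:
            converged = True
            break
    return A, trace[-1], trace, converged


def fit_cda(
    c1: ClassGaussian,
    c2: ClassGaussian,
    d: int,
    opts: CDAOptions | None = None,
    reg: float = DEFAULT_REG,
) -> Projection:
    """Chernoff projection: iterative ascent of J_CDA, initialized at the
    FDA solution (plus optional seeded random restarts); returns the best
    iterate found.  Non-convergence is flagged, never raised."""
    opts = opts or CDAOptions()
    n = c1.dim
    if not (1 <= d <= n):
        raise ValueError(f"d must be in [1, {n}], got {d}")
    inits = [fit_fda(scatter_matrices(c1, c2), d, reg).matrix]
    rng = np.random.default_rng(opts.seed)
    for _ in range(opts.n_restarts - 1):
        inits.append(_orthonormal_rows(rng.standard_normal((d, n))))

    best = None
    for A0 in inits:
        A, obj, trace, conv = _cda_ascent(A0, c1, c2, opts, reg)
        if best is None or obj > best[1]:
            best = (A, obj, trace, conv)
    A, obj, trace, conv = best
    return Projection(
        matrix=A,
        criterion="cda",
        objective_value=obj,
        converged=conv,
        objective_trace=np.asarray(trace),
    )
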