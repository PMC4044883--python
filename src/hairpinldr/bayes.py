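"""Gaussian-Bayes classification in the reduced space.

After projection to d dimensions each class is modelled as a Gaussian;
the decision rule is the maximum a-posteriori label.  Two mechanisms:

* ``linear`` — a single pooled covariance p1 S1 + p2 S2 (linear boundary);
* ``quadratic`` — per-class covariances (quadratic boundary).

Ties break to the negative (majority) class, which is conservative with
respect to false positives on an imbalanced problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ldr import estimate_class_gaussians, regularize_covariance, DEFAULT_REG

__all__ = ["ReducedGaussianModel", "fit_bayes", "predict"]


@dataclass
class ReducedGaussianModel:
    """Two-class Gaussian discriminant in d dimensions.

    ``means[i]``, ``covariances[i]`` and ``priors[i]`` refer to label i
    (0 = negative, 1 = positive).  In linear mode both covariance slots
    hold the pooled matrix.
    """

    means: np.ndarray        # (2, d)
    covariances: np.ndarray  # (2, d, d)
    priors: np.ndarray       # (2,), sums to 1
    mode: str                # "linear" | "quadratic"

    @property
    def d(self) -> int:
        return self.means.shape[1]


def fit_bayes(
    Y: np.ndarray,
    labels: np.ndarray,
    mode: str = "quadratic",
    prior_mode: str = "empirical",
    reg: float = DEFAULT_REG,
) -> ReducedGaussianModel:
    """Fit the reduced-space Gaussian classifier."""
    if mode not in ("linear", "quadratic"):
        raise ValueError(f"unknown classifier mode {mode!r}")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] == 1 and np.asarray(labels).size > 1:
        Y = Y.T
    pos, neg = estimate_class_gaussians(Y, labels, prior_mode=prior_mode)
    S_neg = regularize_covariance(neg.covariance, reg)
    S_pos = regularize_covariance(pos.covariance, reg)
    if mode == "linear":
        pooled = pos.prior * S_pos + neg.prior * S_neg
        covs = np.stack([pooled, pooled])
    else:
        covs = np.stack([S_neg, S_pos])
    for S in covs:
        if np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError(
                "class covariance is singular after regularization"
            )
    return ReducedGaussianModel(
        means=np.stack([neg.mean, pos.mean]),
        covariances=covs,
        priors=np.array([neg.prior, pos.prior]),
        mode=mode,
    )


def _log_gauss(Y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mean.size
    L = np.linalg.cholesky(cov)
    diff = Y - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def predict(
    model: ReducedGaussianModel, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MAP labels and the (N, 2) matrix of unnormalized log-posteriors
    log p_i + log N(y | m_i, S_i); column i corresponds to label i.

    A strict inequality is required to predict the positive class, so exact
    ties go to the negative class.
    """
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1 and model.d == Y.size
    Y = np.atleast_2d(Y)
    if Y.shape[1] != model.d:
        if Y.shape[0] == model.d:
            Y = Y.T
        else:
            raise ValueError(f"samples have dimension {Y.shape[1]}, model is {model.d}-D")
    if not np.all(np.isfinite(Y)):
        raise ValueError("samples contain non-finite values")
    lp = np.column_stack(
        [
            np.log(model.priors[i]) + _log_gauss(Y, model.means[i], model.covariances[i])
            for i in (0, 1)
        ]
    )
    labels = (lp[:, 1] > lp[:, 0]).astype(int)
    if single:
        return int(labels[0]), lp[0]
    return labels, lp
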