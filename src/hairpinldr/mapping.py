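"""Explicit non-linear feature maps.

Instead of the kernel trick, feature vectors are mapped explicitly to a
higher-dimensional space and the linear discriminant machinery runs on the
mapped data.  Two maps are provided:

* the exact degree-2 polynomial expansion
  phi(x) = [1, x1..xn, x1^2..xn^2, x1 x2, ..., x_{n-1} x_n],
  of dimension C(n+2, 2);
* a randomized Fourier (cosine) feature map whose inner products
  approximate the Gaussian RBF kernel exp(-gamma * ||x - y||^2) in
  expectation, with target dimension m (default m = n + 15, gamma = 1.5).

The polynomial expansion is written without the sqrt(2) factors of the
exact kernel factorization; inner products then equal (1 + x.y)^2 only up
to a fixed diagonal rescaling, which is immaterial for discriminant
criteria (they are invariant to invertible diagonal feature scalings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PolyMapSpec",
    "RBFFeatureMap",
    "poly_map",
    "poly_dim",
    "rbf_fit",
    "rbf_transform",
    "default_m",
    "DEFAULT_GAMMA",
]

#: default RBF kernel width
DEFAULT_GAMMA = 1.5


@dataclass(frozen=True)
class PolyMapSpec:
    """Polynomial kernel parameters (gamma x.y + r)^degree.

    Only degree 2 has an implemented explicit map; the map itself is the
    simplified monomial expansion (corresponding to gamma = r = 1).
    """

    degree: int = 2
    r: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclass(frozen=True)
class RBFFeatureMap:
    """Frozen randomized cosine map: z(x) = sqrt(2/m) cos(W x + b)."""

    gamma: float
    m: int
    frequencies: np.ndarray  # (m, n), entries i.i.d. N(0, 2*gamma)
    phases: np.ndarray       # (m,), uniform on [0, 2*pi)
    seed: int

    @property
    def n(self) -> int:
        return self.frequencies.shape[1]


def poly_dim(n: int, degree: int) -> int:
    """Dimension C(n + degree, degree) of the degree-d polynomial map."""
    if n < 1 or degree < 1:
        raise ValueError("n and degree must be >= 1")
    return math.comb(n + degree, degree)


def poly_map(x: np.ndarray, spec: PolyMapSpec = PolyMapSpec()) -> np.ndarray:
    """Explicit degree-2 expansion of a single vector (or rows of a matrix).

    Output order: constant 1, linear terms, squares, then cross terms
    x_i x_j for i < j in lexicographic order.
    """
    if spec.degree != 2:
        raise NotImplementedError("only the degree-2 explicit map is implemented")
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] < 1:
        raise ValueError("input vectors must be non-empty")
    N, n = X.shape
    iu, ju = np.triu_indices(n, k=1)
    out = np.empty((N, poly_dim(n, 2)), dtype=float)
    out[:, 0] = 1.0
    out[:, 1 : n + 1] = X
    out[:, n + 1 : 2 * n + 1] = X**2
    out[:, 2 * n + 1 :] = X[:, iu] * X[:, ju]
    return out[0] if single else out


def default_m(n: int) -> int:
    """Default randomized-map dimension: n + 15."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n + 15


def rbf_fit(
    n: int, gamma: float = DEFAULT_GAMMA, m: int | None = None, seed: int = 0
) -> RBFFeatureMap:
    """Draw a frozen random cosine map for n-dimensional inputs.

    Frequencies are sampled i.i.d. N(0, 2*gamma) per entry and phases
    uniformly on [0, 2*pi), so E[z(x).z(y)] = exp(-gamma ||x-y||^2).
    Fully reproducible given ``seed``.
    """
    if m is None:
        m = default_m(n)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frequencies = rng.normal(0.0, math.sqrt(2.0 * gamma), size=(m, n))
    phases = rng.uniform(0.0, 2.0 * math.pi, size=m)
    return RBFFeatureMap(
        gamma=float(gamma), m=int(m), frequencies=frequencies, phases=phases,
        seed=int(seed),
    )


def rbf_transform(fmap: RBFFeatureMap, X: np.ndarray) -> np.ndarray:
    """Apply the frozen map: rows of sqrt(2/m) cos(W x + b)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != fmap.n:
        raise ValueError(
            f"input has {X.shape[1]} columns, map expects {fmap.n}"
        )
    Z = math.sqrt(2.0 / fmap.m) * np.cos(X @ fmap.frequencies.T + fmap.phases)
    return Z[0] if single else Z
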