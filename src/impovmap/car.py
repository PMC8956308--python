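"""Leroux conditional autoregressive (LCAR) prior over district effects.

The LCAR prior on the vector u of J district random effects is the
Gaussian Markov random field u ~ MVN(0, Omega^-1) with precision

    Omega = tau2 * ( diag(1 - lambda + lambda * w_j+) - lambda * W )

where W is the binary contiguity matrix, w_j+ the neighbour counts,
lambda in [0, 1) the spatial mixing parameter and tau2 > 0 the
conditional precision scale. Equivalently each full conditional is

    u_j | u_-j ~ N( lambda * sum_{i ~ j} u_i / (1 - lambda + lambda w_j+),
                    1 / (tau2 * (1 - lambda + lambda w_j+)) ).

lambda = 0 gives independent N(0, 1/tau2) effects; lambda -> 1
approaches the intrinsic CAR. Islands (w_j+ = 0) keep a proper
conditional precision tau2*(1 - lambda) and need no special handling.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .weights import SpatialWeights

__all__ = [
    "lcar_structure",
    "lcar_precision",
    "lcar_logdet_structure",
    "laplacian_eigvals",
    "sample_lcar_field",
    "conditional_moments",
]


def _check(lam: float, tau2: float) -> None:
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"lambda must lie in [0, 1); got {lam}")
    if tau2 <= 0.0:
        raise ValueError(f"tau2 must be positive; got {tau2}")


def lcar_structure(lam: float, weights: SpatialWeights) -> np.ndarray:
    """R(lambda) = diag(1 - lambda + lambda*w_j+) - lambda*W (unit tau2)."""
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"lambda must lie in [0, 1); got {lam}")
    W = weights.matrix
    return np.diag(1.0 - lam + lam * weights.neighbor_counts) - lam * W


def lcar_precision(lam: float, tau2: float, weights: SpatialWeights) -> np.ndarray:
    """Joint precision tau2 * R(lambda); positive definite for lambda in [0,1)."""
    _check(lam, tau2)
    omega = tau2 * lcar_structure(lam, weights)
    cholesky(omega, lower=True)  # PD guard; raises LinAlgError otherwise
    return omega


def laplacian_eigvals(weights: SpatialWeights) -> np.ndarray:
    """Eigenvalues of the graph Laplacian D - W.

    R(lambda) = (1-lambda)*I + lambda*(D - W) shares the Laplacian's
    eigenvectors, so log|R(lambda)| = sum log(1 - lambda + lambda*mu_k).
    """
    L = np.diag(weights.neighbor_counts) - weights.matrix
    return np.linalg.eigvalsh(L)


def lcar_logdet_structure(lam: float, eigvals: np.ndarray) -> float:
    """log|R(lambda)| from precomputed Laplacian eigenvalues."""
    return float(np.sum(np.log(1.0 - lam + lam * eigvals)))


def sample_lcar_field(
    lam: float,
    tau2: float,
    weights: SpatialWeights,
    seed: int | np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Exact MVN(0, Omega^-1) draw(s) via Cholesky of the precision.

    With Omega = L L', u = L'^{-1} z for z ~ N(0, I) has covariance
    Omega^{-1}. Returns shape (J,) or (size, J).
    """
    omega = lcar_precision(lam, tau2, weights)
    L = cholesky(omega, lower=True)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    J = weights.n_districts
    z = rng.standard_normal((J, size if size else 1))
    u = solve_triangular(L.T, z, lower=False)
    return u[:, 0] if size is None else u.T


def conditional_moments(
    u: np.ndarray, j: int, lam: float, tau2: float, weights: SpatialWeights
) -> tuple[float, float]:
    """Full-conditional mean and variance of u_j given u_-j under the LCAR."""
    _check(lam, tau2)
    wj = weights.neighbor_counts[j]
    d = 1.0 - lam + lam * wj
    mean = lam * float(weights.matrix[j] @ u) / d
    var = 1.0 / (tau2 * d)
    return mean, var
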