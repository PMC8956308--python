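"""Exact Pólya-Gamma PG(1, z) sampling.

The PG(1, z) law is the latent-variable distribution that renders a
Bernoulli-logit likelihood conditionally Gaussian: if omega ~ PG(1, psi)
then the logistic likelihood contribution at linear predictor psi is
proportional to exp(kappa*psi - omega*psi^2/2) with kappa = y - 1/2.
Sampling uses the Devroye alternating-series rejection scheme on the
tilted Jacobi-theta representation J*(1, z/2)/4, which is exact (no
series truncation) and has uniformly bounded expected cost.

The inner loop is numba-jitted and driven by numba's internal NumPy
legacy RNG; call :func:`seed_polya_gamma` before a stream of draws to
make it reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series changeover point t of the Devroye scheme

__all__ = ["polya_gamma", "seed_polya_gamma", "pg_mean", "pg_var"]


@njit(cache=False)
def _log_norm_cdf(x):
    return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))


@njit(cache=False)
def _mass_texpon(z):
    # probability that the two-piece proposal falls in the exponential tail x > t
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=False)
def _rtigauss(z):
    # inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]; valid at z = 0
    t = _TRUNC
    x = t + 1.0
    if z > 1.0 / t:  # mu < t: sample IG and reject until inside
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    else:  # mu >= t (including z == 0): one-sided chi rejection on (0, t]
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    return x


@njit(cache=False)
def _a_coef(n, x):
    if x > _TRUNC:
        return (
            math.pi
            * (n + 0.5)
            * math.exp(-((n + 0.5) * (n + 0.5)) * math.pi * math.pi * x / 2.0)
        )
    return (
        (2.0 / (math.pi * x)) ** 1.5
        * math.pi
        * (n + 0.5)
        * math.exp(-2.0 * (n + 0.5) * (n + 0.5) / x)
    )


@njit(cache=False)
def _pg1(psi):
    z = 0.5 * abs(psi)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        # squeeze accept/reject via the alternating partial sums a_0 - a_1 + ...
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=False)
def _pg1_array(psi, out):
    for i in range(psi.shape[0]):
        out[i] = _pg1(psi[i])


@njit(cache=False)
def _np_seed(seed):
    np.random.seed(seed)


def seed_polya_gamma(seed: int) -> None:
    """Seed the jitted sampler's RNG stream (32-bit nonnegative int)."""
    _np_seed(int(seed) % (2**32 - 1))


def polya_gamma(psi: np.ndarray) -> np.ndarray:
    """Draw omega_i ~ PG(1, psi_i) for each entry of ``psi``."""
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    out = np.empty_like(psi)
    _pg1_array(psi, out)
    return out


def pg_mean(c: float) -> float:
    """E[PG(1, c)] = tanh(c/2) / (2c), with the c -> 0 limit 1/4."""
    if abs(c) < 1e-8:
        return 0.25
    return math.tanh(c / 2.0) / (2.0 * c)


def pg_var(c: float) -> float:
    """Var[PG(1, c)]; the c -> 0 limit is 1/24."""
    if abs(c) < 1e-4:
        return 1.0 / 24.0
    sech2 = 1.0 / math.cosh(c / 2.0) ** 2
    return (math.sinh(c) - c) * sech2 / (4.0 * c**3)
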