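"""Exact fractional Brownian motion sampling.

A molecule center undergoing anomalous diffusion with ensemble MSD
``6 * D * t**alpha`` (3D) is modelled as three independent fractional
Brownian motions, one per Cartesian coordinate, each with variance
``2 * D * t**alpha`` (Hurst exponent ``H = alpha / 2``).  Increments over a
uniform time grid form stationary fractional Gaussian noise whose Toeplitz
covariance is factorized once by Cholesky decomposition, giving samples with
the exact target autocovariance at any trajectory length for which the
factorization is tractable (thousands of frames).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, toeplitz


def fgn_autocovariance(n_steps: int, alpha: float, d_alpha: float,
                       dt: float) -> np.ndarray:
    """Autocovariance of per-coordinate fGn increments at lags 0..n_steps-1.

    ``gamma(k) = D * dt**alpha * (|k+1|**alpha - 2|k|**alpha + |k-1|**alpha)``,
    so the summed process has per-coordinate variance ``2 D t**alpha``.
    """
    if not 0 < alpha <= 2:
        raise ValueError("alpha must lie in (0, 2]")
    if d_alpha < 0:
        raise ValueError("D must be non-negative")
    k = np.arange(n_steps, dtype=float)
    g = (np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha
         + np.abs(k - 1) ** alpha)
    return d_alpha * dt ** alpha * g


def fgn_cholesky(n_steps: int, alpha: float, d_alpha: float,
                 dt: float) -> np.ndarray:
    """Lower Cholesky factor of the fGn increment covariance."""
    gamma = fgn_autocovariance(n_steps, alpha, d_alpha, dt)
    cov = toeplitz(gamma)
    jitter = 0.0
    scale = max(gamma[0], 1e-300)
    for _ in range(6):
        try:
            return cholesky(cov + jitter * np.eye(n_steps), lower=True)
        except np.linalg.LinAlgError:
            jitter = scale * 1e-12 if jitter == 0.0 else jitter * 100
    raise np.linalg.LinAlgError("fGn covariance not factorizable")


def sample_fbm_paths(n_paths: int, n_steps: int, alpha: float, d_alpha: float,
                     dt: float, rng: np.random.Generator,
                     chol: np.ndarray | None = None) -> np.ndarray:
    """Sample fBm paths starting at 0; shape ``(n_steps + 1, n_paths)``.

    Each column is one coordinate of one molecule; the ensemble-expected
    squared value at time ``m*dt`` is ``2 * D * (m*dt)**alpha``.  Pass a
    precomputed ``chol`` factor to amortize the factorization across
    ensembles with identical ``(n_steps, alpha, D, dt)``.
    """
    out = np.zeros((n_steps + 1, n_paths))
    if n_steps == 0 or n_paths == 0 or d_alpha == 0:
        return out
    if chol is None:
        chol = fgn_cholesky(n_steps, alpha, d_alpha, dt)
    z = rng.standard_normal((n_steps, n_paths))
    np.cumsum(chol @ z, axis=0, out=out[1:])
    return out
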