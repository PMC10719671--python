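"""Bivariate/multivariate normal kernels for liability-threshold likelihoods.

The binary-trait twin models in this package all reduce to rectangle
probabilities of a correlated multivariate normal liability:

* 2-D probabilities (tetrachoric tables, univariate ACE cells) use the
  closed-form expression of the bivariate normal CDF in terms of Owen's T
  function, which is fast, vectorized, and accurate to ~1e-15.
* 4-D joint cell probabilities for a twin pair measured on two traits use a
  conditioning decomposition: given the pair-shared liability components the
  two twins are independent, so a 16-cell table reduces to a 2-D
  Gauss-Hermite quadrature over the shared factor with bivariate-normal
  quadrant probabilities inside.
* A generic 4-D rectangle routine (`mvn_orthant`) wraps scipy's Genz
  quasi-Monte-Carlo integrator with a fixed integration seed so likelihood
  values are reproducible; it serves as an independent cross-check of the
  quadrature kernel.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import multivariate_normal

__all__ = [
    "norm_cdf",
    "norm_ppf",
    "bvn_cdf",
    "same_trait_cell_probs",
    "joint_cell_probs",
    "mvn_orthant",
]

# Fixed seed for the quasi-Monte-Carlo integrator: likelihoods must be
# deterministic across calls and processes.
_INTEGRATION_SEED = 20230912

# |z| beyond this carries < 1e-17 of normal mass; clipping keeps Owen's T
# arguments finite without measurable error.
_ZMAX = 8.5

norm_cdf = ndtr
norm_ppf = ndtri


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) at correlation rho.

    Vectorized over all three arguments (broadcasting applies).  ``rho`` of
    exactly +/-1 is handled as the comonotone/countermonotone limit.
    Absolute accuracy is ~1e-15 away from the |rho| -> 1 boundary.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.isnan(h)) or np.any(np.isnan(k)) or np.any(np.isnan(rho)):
        raise ValueError("NaN input to bvn_cdf")
    if np.any(np.abs(rho) > 1):
        raise ValueError("rho must lie in [-1, 1]")

    h, k, rho = np.broadcast_arrays(h, k, rho)
    h = np.clip(h, -_ZMAX, _ZMAX)
    k = np.clip(k, -_ZMAX, _ZMAX)

    out = np.empty(h.shape, dtype=float)

    hi = rho >= 1.0 - 1e-12
    lo = rho <= -1.0 + 1e-12
    mid = ~(hi | lo)

    if np.any(hi):
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if np.any(lo):
        out[lo] = np.maximum(0.0, ndtr(h[lo]) + ndtr(k[lo]) - 1.0)
    if np.any(mid):
        hm, km, rm = h[mid], k[mid], rho[mid]
        # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,ah) - T(k,ak) - delta.
        # An epsilon shift off h==0 / k==0 keeps the T arguments finite; the
        # expression is continuous so the error is below 1e-15.
        hm = np.where(hm == 0.0, 1e-15, hm)
        km = np.where(km == 0.0, 1e-15, km)
        denom = np.sqrt(1.0 - rm * rm)
        ah = (km - rm * hm) / (hm * denom)
        ak = (hm - rm * km) / (km * denom)
        delta = np.where(hm * km > 0, 0.0, 0.5)
        val = 0.5 * (ndtr(hm) + ndtr(km)) - owens_t(hm, ah) - owens_t(km, ak) - delta
        out[mid] = np.clip(val, 0.0, 1.0)

    if out.ndim == 0:
        return float(out)
    return out


def same_trait_cell_probs(rho: float, tau_row: float, tau_col: float) -> np.ndarray:
    """2x2 cell probabilities (p11, p10, p01, p00) for dichotomized BVN.

    ``1`` means the liability exceeds its threshold.  Row indexes twin 1
    (threshold ``tau_row``), column twin 2 (``tau_col``).
    """
    p00 = bvn_cdf(tau_row, tau_col, rho)
    pr = ndtr(tau_row)  # P(twin1 negative)
    pc = ndtr(tau_col)
    p10 = pc - p00
    p01 = pr - p00
    p11 = 1.0 - pr - pc + p00
    return np.clip(np.array([p11, p10, p01, p00]), 0.0, 1.0)


def _gh_nodes(n_nodes: int):
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)
    return z, w


def joint_cell_probs(
    within: np.ndarray,
    cross: np.ndarray,
    tau: np.ndarray,
    n_nodes: int = 24,
) -> np.ndarray:
    """16 joint cell probabilities for a twin pair on two dichotomized traits.

    The 4-variate liability (T1_in, T1_out, T2_in, T2_out) has block
    covariance [[W, B], [B, W]] with ``within`` = W (unit diagonal) and
    ``cross`` = B (symmetric, the pair-shared part).  Writing L_j = S + U_j
    with Cov(S) = B and Cov(U_j) = W - B, the twins are independent given S,
    so each cell probability is a 2-D Gauss-Hermite integral over S of a
    product of two bivariate-normal quadrant probabilities.

    Returns an array of shape (2, 2, 2, 2) indexed [in1, out1, in2, out2]
    with 1 = above threshold.  Requires B PSD and W - B positive definite
    (true whenever the ACE component matrices are PSD); raises ValueError
    otherwise.
    """
    W = np.asarray(within, dtype=float)
    B = np.asarray(cross, dtype=float)
    tau = np.asarray(tau, dtype=float)

    evals, evecs = np.linalg.eigh(B)
    if evals.min() < -1e-9:
        raise ValueError("cross-twin covariance block is not PSD")
    evals = np.clip(evals, 0.0, None)

    R = W - B
    d = np.diag(R)
    if np.any(d <= 1e-12):
        raise ValueError("within-twin residual covariance is not positive definite")
    sd = np.sqrt(d)
    r = R[0, 1] / (sd[0] * sd[1])
    if abs(r) > 1.0:
        raise ValueError("within-twin residual covariance is not positive definite")
    r = float(np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12))

    z, w = _gh_nodes(n_nodes)
    z1, z2 = np.meshgrid(z, z, indexing="ij")
    wts = np.outer(w, w).ravel()
    zs = np.column_stack([z1.ravel(), z2.ravel()])
    # shared factor samples S = V sqrt(lambda) z
    S = zs @ (evecs * np.sqrt(evals)).T  # (M, 2)

    # standardized conditional thresholds per trait
    b = (tau[None, :] - S) / sd[None, :]  # (M, 2)
    q00 = bvn_cdf(b[:, 0], b[:, 1], r)  # both below
    p0_in = ndtr(b[:, 0])
    p0_out = ndtr(b[:, 1])
    # quadrant probs per twin, indexed [in, out] with 1 = above threshold
    q = np.empty((b.shape[0], 2, 2))
    q[:, 0, 0] = q00
    q[:, 0, 1] = p0_in - q00
    q[:, 1, 0] = p0_out - q00
    q[:, 1, 1] = 1.0 - p0_in - p0_out + q00
    q = np.clip(q, 0.0, 1.0)

    # P[cell] = sum_m w_m * q_m[i1,o1] * q_m[i2,o2]
    probs = np.einsum("m,mab,mcd->abcd", wts, q, q)
    return np.clip(probs, 0.0, 1.0)


def mvn_orthant(
    lower: np.ndarray,
    upper: np.ndarray,
    corr: np.ndarray,
    abseps: float = 1e-6,
    maxpts: int | None = None,
) -> float:
    """Rectangle probability P(lower <= X <= upper) for X ~ N(0, corr).

    Uses scipy's Genz quasi-Monte-Carlo integrator with a fixed internal
    seed, so repeated calls return identical values.  ``corr`` must be a
    valid (PSD, unit-diagonal) correlation matrix.
    """
    corr = np.asarray(corr, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(np.linalg.eigvalsh(corr) < -1e-10):
        raise ValueError("correlation matrix is not positive semi-definite")
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    dim = corr.shape[0]
    if maxpts is None:
        maxpts = 1_000_000 * dim
    p = multivariate_normal.cdf(
        upper,
        mean=np.zeros(dim),
        cov=corr,
        allow_singular=True,
        lower_limit=lower,
        maxpts=maxpts,
        abseps=abseps,
        releps=0.0,
        rng=np.random.default_rng(_INTEGRATION_SEED),
    )
    return float(np.clip(p, 0.0, 1.0))
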