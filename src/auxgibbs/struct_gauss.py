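"""Exact samplers for structured zero-mean Gaussian distributions.

The auxiliary-variable Gibbs samplers in this package repeatedly need exact
draws from N(0, C) where the covariance has one of a few special forms built
from a step size and an operator Gram matrix, typically

    C = (1/lam) I - H^T H,        lam * ||H^T H||_S < 1.

Because H is circulant, an orthonormal frame, or a composition of such maps,
C has a known orthogonal eigenbasis and a real symmetric square root can be
applied exactly — no Cholesky factorization or iterative solver is involved.
A dense Cholesky sampler is also provided; it is the brute-force oracle used
throughout the test suite and is capped at a configurable dimension.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .linops import DiagonalMap, LinearMap

__all__ = [
    "sample_dense_cholesky",
    "sample_shifted_operator",
    "sample_tight_frame",
    "sample_composite",
    "sample_aux_three_step",
    "PreconditionError",
]

DENSE_ORACLE_MAX_DIM = 4096


class PreconditionError(ValueError):
    """A positive-definiteness or step-size constraint is violated."""


def sample_dense_cholesky(
    mean: np.ndarray,
    precision: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Exact draw(s) from N(mean, precision^{-1}) via Cholesky.

    With precision G = L L^T (lower Cholesky), x = mean + L^{-T} n has
    covariance G^{-1}.  ``size`` draws rows of an (size, dim) array.
    """
    mean = np.asarray(mean, dtype=float).ravel()
    precision = np.asarray(precision, dtype=float)
    dim = mean.size
    if precision.shape != (dim, dim):
        raise ValueError("precision/mean dimension mismatch")
    if dim > DENSE_ORACLE_MAX_DIM:
        raise ValueError(
            f"dense sampler capped at dimension {DENSE_ORACLE_MAX_DIM}"
        )
    try:
        chol = scipy.linalg.cholesky(precision, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise PreconditionError("precision matrix is not SPD") from exc
    n = rng.standard_normal(dim if size is None else (size, dim))
    # solve L^T x = n  =>  x ~ N(0, G^{-1})
    x = scipy.linalg.solve_triangular(chol, n.T, lower=True, trans="T").T
    return mean + x


def sample_shifted_operator(
    H: LinearMap,
    lam: float,
    rng: np.random.Generator,
    check: bool = True,
) -> np.ndarray:
    """Exact draw from N(0, (1/lam) I - H^T H).

    Requires H^T H to have a known orthogonal eigenbasis (the operator's
    ``gram_function_apply``).  The draw applies the real symmetric square
    root sqrt((1/lam) I - H^T H) to white noise.
    """
    if lam <= 0:
        raise PreconditionError("lam must be positive")
    if check:
        gram_norm = H.spectral_norm() ** 2
        if lam * gram_norm >= 1.0:
            raise PreconditionError(
                f"lam*||H^T H||_S = {lam * gram_norm:.6g} >= 1; "
                "covariance not positive definite"
            )

    def sqrt_cov(t):
        var = 1.0 / lam - t
        if np.any(np.asarray(var) <= 0):
            raise PreconditionError("nonpositive variance in eigenbasis")
        return np.sqrt(var)

    w = rng.standard_normal(H.in_dim)
    return H.gram_function_apply(sqrt_cov, w)


def sample_tight_frame(
    H: LinearMap,
    lam: float,
    nu: float,
    rng: np.random.Generator,
    check: bool = True,
    tol: float = 1e-8,
) -> np.ndarray:
    """Exact draw from N(0, (1/lam) I - H^T H) when H H^T = nu I.

    Uses the tight-frame splitting of the covariance:

        (1/lam) I - H^T H
            = ((1/sqrt(lam)) I - sqrt(lam) H^T H)^2 + (1 - lam*nu) H^T H,

    so with independent standard normal y1 (length Q) and y2 (length N),

        y = ((1/sqrt(lam)) I - sqrt(lam) H^T H) y1 + sqrt(1 - lam*nu) H^T y2

    has exactly the target covariance.
    """
    if lam <= 0 or nu <= 0:
        raise PreconditionError("lam and nu must be positive")
    if lam * nu >= 1.0:
        raise PreconditionError(f"lam*nu = {lam * nu:.6g} must be < 1")
    if check:
        probe = rng.standard_normal(H.out_dim)
        resid = H.apply(H.adjoint(probe)) - nu * probe
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(probe) * nu):
            raise PreconditionError("H H^T != nu I: not a tight frame")
    y1 = rng.standard_normal(H.in_dim)
    y2 = rng.standard_normal(H.out_dim)
    s = np.sqrt(lam)
    part1 = y1 / s - s * H.adjoint(H.apply(y1))
    part2 = np.sqrt(1.0 - lam * nu) * H.adjoint(y2)
    return part1 + part2


def sample_composite(
    M: LinearMap,
    P: LinearMap,
    lam: float,
    lam_tilde: float,
    rng: np.random.Generator,
    sample_inner_P=None,
    sample_inner_M=None,
) -> np.ndarray:
    """Exact draw from N(0, (1/lam) I - H^T H) with H = M P.

    Requires the ordering  lam ||P||^2 < lam_tilde < 1/||M||^2, under which

        (1/lam) I - H^T H
            = (1/lam_tilde) [ (lam_tilde/lam) I - P^T P ]
              + P^T [ (1/lam_tilde) I - M^T M ] P

    and  y = (1/sqrt(lam_tilde)) y1 + P^T y2  with
    y1 ~ N(0, (lam_tilde/lam) I - P^T P), y2 ~ N(0, (1/lam_tilde) I - M^T M)
    has the target covariance.  The two sub-draws default to the shifted
    operator rule and may be overridden (e.g., with the tight-frame rule).
    """
    norm_P2 = P.spectral_norm() ** 2
    norm_M2 = M.spectral_norm() ** 2
    if not (lam * norm_P2 < lam_tilde < (np.inf if norm_M2 == 0 else 1.0 / norm_M2)):
        raise PreconditionError(
            f"ordering lam*||P||^2 < lam_tilde < 1/||M||^2 violated: "
            f"{lam * norm_P2:.6g} < {lam_tilde:.6g} < "
            f"{np.inf if norm_M2 == 0 else 1.0 / norm_M2:.6g}"
        )
    if sample_inner_P is None:
        sample_inner_P = lambda r: sample_shifted_operator(P, lam / lam_tilde, r, check=False)
    if sample_inner_M is None:
        sample_inner_M = lambda r: sample_shifted_operator(M, lam_tilde, r, check=False)
    y1 = sample_inner_P(rng)
    y2 = sample_inner_M(rng)
    return y1 / np.sqrt(lam_tilde) + P.adjoint(y2)


def sample_aux_three_step(
    x: np.ndarray,
    mu: float,
    beta: float,
    H: LinearMap,
    Lambda: DiagonalMap,
    rng: np.random.Generator,
    check: bool = True,
) -> np.ndarray:
    """Exact draw from N(((1/mu) I - H^T Lambda H) x, (1/mu) I - H^T Lambda H).

    Implements the three-step splitting of the auxiliary covariance

        (1/mu) I - H^T Lambda H
            = (1/beta) [ (beta/mu) I - H^T H ] + H^T [ (1/beta) I - Lambda ] H

    valid when  mu ||H||_S^2 < beta < 1/||Lambda||_S:

        (1) n ~ N(0, (1/beta) I - Lambda)       (coordinatewise, Lambda diag)
        (2) y ~ N(0, (1/lam) I - H^T H),  lam = mu/beta
        (3) v = ((1/mu) I - H^T Lambda H) x + beta^{-1/2} y + H^T n.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not isinstance(Lambda, DiagonalMap):
        raise TypeError("Lambda must be a DiagonalMap")
    if check:
        h_norm2 = H.spectral_norm() ** 2
        lam_norm = Lambda.spectral_norm()
        if not mu * h_norm2 < beta:
            raise PreconditionError(
                f"mu*||H||_S^2 = {mu * h_norm2:.6g} must be < beta = {beta:.6g}"
            )
        if not (lam_norm == 0.0 or beta < 1.0 / lam_norm):
            raise PreconditionError(
                f"beta = {beta:.6g} must be < 1/||Lambda||_S = {1.0 / lam_norm:.6g}"
            )
    lam = mu / beta
    var_n = 1.0 / beta - Lambda.diag
    if np.any(var_n <= 0):
        raise PreconditionError("(1/beta) I - Lambda not positive definite")
    n = np.sqrt(var_n) * rng.standard_normal(H.out_dim)
    y = sample_shifted_operator(H, lam, rng, check=False)
    mean = x / mu - H.adjoint(Lambda.apply(H.apply(x)))
    return mean + y / np.sqrt(beta) + H.adjoint(n)
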